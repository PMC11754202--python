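"""End-to-end orchestration: read -> deduplicate -> normalize ->
assemble -> contingency -> signals -> flags -> descriptives -> subgroups.

Everything is written to an output directory as delimited text plus a
machine-readable JSON run log; results never go to stdout, so runs
compose cleanly.  Identical inputs and configuration give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import io as fio
from .cleaning import AssemblyLog, DrugDictionary, assemble_reports, deduplicate
from .contingency import build_all_tables
from .descriptives import (concomitant_frequency, subgroup_signals, summarize,
                           top_events_by_outcome)
from .io import PtSocMap, QuarterData, write_signal_table
from .signals import BcpnnPriors, Thresholds, compute_all_signals, rank_signals

logger = logging.getLogger("faersignal")


@dataclass
class RunConfig:
    """One pipeline run: where the data comes from and what to compute."""

    drug: str
    out_dir: Path
    paths: Optional[Mapping[str, Sequence[str]]] = None   # table -> file paths
    pt_soc_map_path: Optional[str] = None
    dictionary_path: Optional[str] = None
    levels: tuple[str, ...] = ("PT", "SOC")
    thresholds: Thresholds = field(default_factory=Thresholds)
    priors: BcpnnPriors = field(default_factory=BcpnnPriors)
    stratifiers: tuple[str, ...] = ("age_coarse", "sex", "weight")
    comparator: str = "non_ps"
    top_k: int = 10

    def __post_init__(self) -> None:
        if not self.drug:
            raise ValueError("target drug must be non-empty")
        self.out_dir = Path(self.out_dir)


def load_thresholds(path: str | Path) -> Thresholds:
    """Read threshold overrides from a flat key: value YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(Thresholds)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return Thresholds(**raw)


def run_pipeline(cfg: RunConfig,
                 data: Optional[QuarterData] = None,
                 pt_soc_map: Optional[PtSocMap] = None,
                 dictionary: Optional[DrugDictionary] = None) -> dict:
    """Execute the full pipeline; returns the run log (also written to
    ``out_dir/run_log.json``).

    ``data``/``pt_soc_map``/``dictionary`` may be passed in-memory
    (e.g. a synthetic corpus); otherwise they are read from the paths
    in ``cfg``.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"drug": cfg.drug, "stages": {}}

    # --- read ------------------------------------------------------------
    if data is None:
        if cfg.paths is None:
            raise ValueError("RunConfig.paths required when no data is given")
        logger.info("reading tables")
        data = fio.read_quarter(cfg.paths)
    if pt_soc_map is None:
        if cfg.pt_soc_map_path is None:
            raise ValueError("pt_soc_map_path required when no map is given")
        pt_soc_map = fio.read_pt_soc_map(cfg.pt_soc_map_path)
    if dictionary is None:
        if cfg.dictionary_path is None:
            raise ValueError("dictionary_path required when no dictionary is given")
        dictionary = fio.read_drug_dictionary(cfg.dictionary_path)
    log["stages"]["read"] = {
        "rows": {t: len(getattr(data, t)) for t in
                 ("demo", "drug", "reac", "outc", "ther")},
        "issues": {t: i.counts for t, i in data.issues.items()},
    }

    # --- deduplicate + assemble ------------------------------------------
    demos = deduplicate(data.demo)
    log["stages"]["deduplicate"] = {
        "input_reports": len(data.demo),
        "unique_cases": len(demos),
        "duplicates_removed": len(data.demo) - len(demos),
    }
    reports, asm = assemble_reports(data, pt_soc_map, dictionary, demos=demos)
    log["stages"]["assemble"] = _assembly_log_dict(asm, len(reports))

    drug_cases = sum(1 for r in reports if r.is_primary_suspect(cfg.drug))
    log["drug_ps_cases"] = drug_cases
    if drug_cases == 0:
        logger.warning("target drug %r has no primary-suspect cases", cfg.drug)

    # --- signals ----------------------------------------------------------
    soc_of: dict[str, str] = {}
    for r in reports:
        for pt, soc in r.pts:
            soc_of.setdefault(pt, soc)
    log["stages"]["signals"] = {}
    for level in cfg.levels:
        tables = build_all_tables(reports, cfg.drug, level,  # type: ignore[arg-type]
                                  comparator=cfg.comparator)
        rows = compute_all_signals(tables, level,  # type: ignore[arg-type]
                                   soc_of=soc_of if level == "PT" else None,
                                   priors=cfg.priors, thresholds=cfg.thresholds)
        ranked = rank_signals(rows, by="n")
        name = f"{level.lower()}_signals"
        write_signal_table(ranked, out / f"{name}.tsv")
        write_signal_table(rank_signals(rows, by="ebgm"),
                           out / f"{name}_human.tsv", human=True)
        log["stages"]["signals"][level] = {
            "events": len(rows),
            "flagged_all4": sum(1 for r in rows if r.flag_all4),
        }

    # --- descriptives -----------------------------------------------------
    summary = summarize(reports, cfg.drug)
    summary.to_csv(out / "demographics.tsv", sep="\t", index=False)
    with open(out / "top_events.tsv", "w") as fh:
        fh.write("outcome\tpt\tcases\n")
        for outcome in ("death", "hospitalization"):
            for pt, count in top_events_by_outcome(reports, cfg.drug, outcome,
                                                   k=cfg.top_k):
                fh.write(f"{outcome}\t{pt}\t{count}\n")
    with open(out / "concomitant.tsv", "w") as fh:
        fh.write("drug\tcases\n")
        for name, count in concomitant_frequency(reports, cfg.drug):
            fh.write(f"{name}\t{count}\n")
    log["stages"]["descriptives"] = {
        "summary_rows": len(summary),
    }

    # --- subgroups ---------------------------------------------------------
    log["stages"]["subgroups"] = {}
    for strat in cfg.stratifiers:
        per_stratum = subgroup_signals(reports, cfg.drug, strat, "PT",  # type: ignore[arg-type]
                                       thresholds=cfg.thresholds,
                                       priors=cfg.priors)
        for stratum, rows in per_stratum.items():
            safe = stratum.replace("<", "lt").replace(">=", "ge").replace(" ", "_")
            write_signal_table(rows, out / f"subgroup_{strat}_{safe}.tsv")
        log["stages"]["subgroups"][strat] = {
            s: len(rows) for s, rows in per_stratum.items()}

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return log


def _assembly_log_dict(asm: AssemblyLog, n_reports: int) -> dict:
    return {
        "case_reports": n_reports,
        "orphan_rows": {
            "drug": asm.orphan_drug_rows, "reac": asm.orphan_reac_rows,
            "outc": asm.orphan_outc_rows, "ther": asm.orphan_ther_rows,
        },
        "unmapped_pt_reports": sum(asm.unmapped_pts.values()),
        "unmapped_drug_reports": sum(asm.unmapped_drugs.values()),
    }
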