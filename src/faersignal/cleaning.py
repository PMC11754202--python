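"""Report deduplication, drug-name normalization, case assembly.

FAERS distributes every revision of a case as a separate report
version; analyses must count each *case* once.  Following the FDA
cleaning guidance, versions sharing a CASEID are collapsed to the one
with the most recent FDA_DT, ties broken by the highest (numeric)
PRIMARYID.  Deduplication happens before any counting, so `n` in every
downstream contingency table is a count of unique cases.

Drug names in spontaneous reports are free text ("SAMSCA", "TOLVAPTAN
15MG", "tolvaptan."); they are mapped to canonical generic names by
dictionary lookup after stripping punctuation and dose/form tokens.
Names the dictionary does not know are flagged ("unmapped:<name>")
rather than silently kept, so they can be audited.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .dates import PartialDate
from .io import (DemoRecord, DrugRecord, PtSocMap, QuarterData, normalize_pt)

#: tokens that carry dose / formulation rather than identity
_DOSE_FORM_TOKENS = {
    "mg", "mcg", "ug", "g", "gram", "grams", "ml", "l", "iu",
    "tablet", "tablets", "tab", "tabs", "capsule", "capsules", "cap",
    "caps", "oral", "solution", "injection", "iv", "po", "od", "bid",
    "qd", "daily", "unknown", "unk", "nos",
}
_NUM_DOSE_RE = re.compile(r"^\d+(\.\d+)?(mg|mcg|ug|g|ml|l|iu)?$")
_PUNCT_RE = re.compile(r"[^\w\s]")


def _name_key(raw: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return " ".join(_PUNCT_RE.sub(" ", raw.lower()).split())


def _strip_dose_tokens(key: str) -> str:
    kept = [tok for tok in key.split()
            if tok not in _DOSE_FORM_TOKENS and not _NUM_DOSE_RE.match(tok)]
    return " ".join(kept)


class DrugDictionary:
    """Raw drug name -> canonical generic name synonym dictionary.

    A testable stand-in for NLP-based medication-name standardization:
    lookup is case/whitespace/punctuation-insensitive and ignores
    dose/formulation tokens, so "TOLVAPTAN 15MG", "Samsca" and
    "tolvaptan." all resolve to "tolvaptan" once the dictionary says so.
    """

    def __init__(self, synonyms: Mapping[str, str]):
        self._map: dict[str, str] = {}
        self._canonical: set[str] = set()
        for raw, canonical in synonyms.items():
            canonical = canonical.strip().lower()
            self._map[_name_key(raw)] = canonical
            self._canonical.add(canonical)

    def __len__(self) -> int:
        return len(self._map)

    def lookup(self, raw: str) -> Optional[str]:
        key = _name_key(raw)
        if key in self._map:
            return self._map[key]
        stripped = _strip_dose_tokens(key)
        if stripped in self._map:
            return self._map[stripped]
        if stripped in self._canonical:
            return stripped
        return None


def normalize_drug(raw: str, dictionary: DrugDictionary) -> str:
    """Map a raw drug name to its canonical generic name.

    Unmapped names return ``"unmapped:<normalized raw>"`` so they stay
    visible downstream instead of vanishing into the comparator pool.
    """
    canonical = dictionary.lookup(raw)
    if canonical is not None:
        return canonical
    fallback = _strip_dose_tokens(_name_key(raw)) or _name_key(raw)
    return f"unmapped:{fallback}"


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def deduplicate(demos: Iterable[DemoRecord]) -> list[DemoRecord]:
    """One DEMO record per caseid: latest FDA_DT, then highest PRIMARYID.

    Idempotent and order-independent; output sorted by caseid.  A tie
    on FDA_DT between non-numeric primaryids cannot be broken by the
    FDA rule and raises.
    """
    by_case: dict[str, DemoRecord] = {}
    for rec in demos:
        cur = by_case.get(rec.caseid)
        if cur is None:
            by_case[rec.caseid] = rec
            continue
        new_key, cur_key = rec.fda_dt.sort_key(), cur.fda_dt.sort_key()
        if new_key > cur_key:
            by_case[rec.caseid] = rec
        elif new_key == cur_key:
            try:
                if int(rec.primaryid) > int(cur.primaryid):
                    by_case[rec.caseid] = rec
            except ValueError:
                raise ValueError(
                    f"caseid {rec.caseid}: FDA_DT tie between non-numeric "
                    f"primaryids {cur.primaryid!r} and {rec.primaryid!r}"
                ) from None
    return [by_case[cid] for cid in sorted(by_case)]


# ---------------------------------------------------------------------------
# Unit conversion (Table-3-style bins are in years and kg)
# ---------------------------------------------------------------------------

_AGE_FACTOR = {"decade": 10.0, "year": 1.0, "month": 1 / 12.0,
               "week": 1 / 52.18, "day": 1 / 365.25, "hour": 1 / (24 * 365.25)}

LBS_PER_KG = 0.45359237


def age_in_years(value: Optional[float], unit: str) -> Optional[float]:
    if value is None or unit not in _AGE_FACTOR:
        return None
    return value * _AGE_FACTOR[unit]


def weight_in_kg(value: Optional[float], unit: str) -> Optional[float]:
    if value is None:
        return None
    if unit == "kg":
        return value
    if unit == "lbs":
        return value * LBS_PER_KG
    return None


# ---------------------------------------------------------------------------
# Case assembly
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class CaseDrug:
    """A drug row inside an assembled case, with the normalized name."""

    drug_seq: int
    name: str           # canonical or "unmapped:<raw>"
    raw_name: str
    role: str


@dataclass(slots=True)
class CaseReport:
    """One analysis-ready case: demographics + drugs + events + outcomes."""

    primaryid: str
    caseid: str
    demo: DemoRecord
    drugs: list[CaseDrug]
    pts: list[tuple[str, str]]            # (preferred term, soc), deduplicated
    outcomes: set[str]
    therapy_starts: dict[int, PartialDate]  # drug_seq -> start date

    @property
    def age_years(self) -> Optional[float]:
        return age_in_years(self.demo.age_value, self.demo.age_unit)

    @property
    def weight_kg(self) -> Optional[float]:
        return weight_in_kg(self.demo.weight_value, self.demo.weight_unit)

    def has_drug(self, name: str, roles: Optional[set[str]] = None) -> bool:
        return any(d.name == name and (roles is None or d.role in roles)
                   for d in self.drugs)

    def is_primary_suspect(self, name: str) -> bool:
        return self.has_drug(name, {"PS"})

    def pt_names(self) -> list[str]:
        return [pt for pt, _ in self.pts]

    def socs(self) -> set[str]:
        return {soc for _, soc in self.pts}


@dataclass
class AssemblyLog:
    """Bookkeeping from assemble_reports: nothing is dropped silently."""

    orphan_drug_rows: int = 0
    orphan_reac_rows: int = 0
    orphan_outc_rows: int = 0
    orphan_ther_rows: int = 0
    unmapped_pts: dict[str, int] = field(default_factory=dict)
    unmapped_drugs: dict[str, int] = field(default_factory=dict)


def assemble_reports(data: QuarterData, pt_soc_map: PtSocMap,
                     dictionary: DrugDictionary,
                     demos: Optional[list[DemoRecord]] = None,
                     ) -> tuple[list[CaseReport], AssemblyLog]:
    """Join deduplicated DEMO records with their DRUG/REAC/OUTC/THER rows.

    ``demos`` defaults to ``deduplicate(data.demo)``.  Rows whose
    primaryid has no surviving DEMO record are dropped and counted as
    orphans; within-report duplicate PTs collapse to one occurrence;
    PTs the map does not know get SOC "unmapped" and are tallied.
    """
    if demos is None:
        demos = deduplicate(data.demo)
    log = AssemblyLog()
    surviving = {d.primaryid for d in demos}

    drugs_by_pid: dict[str, list[DrugRecord]] = {}
    for rec in data.drug:
        if rec.primaryid not in surviving:
            log.orphan_drug_rows += 1
            continue
        drugs_by_pid.setdefault(rec.primaryid, []).append(rec)

    reacs_by_pid: dict[str, list[str]] = {}
    for rec in data.reac:
        if rec.primaryid not in surviving:
            log.orphan_reac_rows += 1
            continue
        reacs_by_pid.setdefault(rec.primaryid, []).append(rec.pt)

    outc_by_pid: dict[str, set[str]] = {}
    for rec in data.outc:
        if rec.primaryid not in surviving:
            log.orphan_outc_rows += 1
            continue
        outc_by_pid.setdefault(rec.primaryid, set()).add(rec.outcome)

    ther_by_pid: dict[str, dict[int, PartialDate]] = {}
    for rec in data.ther:
        if rec.primaryid not in surviving:
            log.orphan_ther_rows += 1
            continue
        if rec.start_dt is not None:
            ther_by_pid.setdefault(rec.primaryid, {})[rec.drug_seq] = rec.start_dt

    reports: list[CaseReport] = []
    for demo in demos:
        pid = demo.primaryid
        case_drugs: list[CaseDrug] = []
        for d in sorted(drugs_by_pid.get(pid, []), key=lambda r: r.drug_seq):
            name = normalize_drug(d.drugname, dictionary)
            if name.startswith("unmapped:"):
                log.unmapped_drugs[name[9:]] = log.unmapped_drugs.get(name[9:], 0) + 1
            case_drugs.append(CaseDrug(drug_seq=d.drug_seq, name=name,
                                       raw_name=d.drugname, role=d.role))
        pts: list[tuple[str, str]] = []
        seen_pts: set[str] = set()
        for raw_pt in reacs_by_pid.get(pid, []):
            pt = normalize_pt(raw_pt)
            if pt in seen_pts:
                continue
            seen_pts.add(pt)
            soc = pt_soc_map.get(pt)
            if soc == "unmapped" and pt not in pt_soc_map:
                log.unmapped_pts[pt] = log.unmapped_pts.get(pt, 0) + 1
            pts.append((pt, soc))
        reports.append(CaseReport(
            primaryid=pid, caseid=demo.caseid, demo=demo, drugs=case_drugs,
            pts=pts, outcomes=outc_by_pid.get(pid, set()),
            therapy_starts=ther_by_pid.get(pid, {}),
        ))
    return reports, log
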