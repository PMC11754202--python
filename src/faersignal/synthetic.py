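"""FAERS-shaped synthetic corpora with known ground truth.

Real spontaneous-report quarters are multi-gigabyte downloads; the
generator emulates their *structure* — per-report demographics with
unit codes and missingness, one-or-more drug rows with role codes,
MedDRA-like preferred terms mapped to organ classes, outcome codes,
therapy dates, and duplicate report versions sharing a case id — at
desk scale, with configurable true drug-event relative risks so every
pipeline stage can be validated against a known answer.

Generative model, per case:

1. one primary-suspect (PS) drug is drawn from ``drug_vocab``;
2. the number of distinct preferred terms is drawn from
   ``pts_per_case``, and that many PTs are drawn *without replacement*
   with probability proportional to ``baseline(pt) * true_rr(drug, pt)``
   (renormalized — so ``true_rr`` multiplies the per-draw reporting
   probability, with a small attenuation at large risks);
3. demographics, outcomes, a therapy start date and an event date
   (start + a delay drawn from ``onset_model``) are attached, each field
   subject to its configured missingness;
4. zero or more concomitant drug rows (roles SS/C/I) are added;
5. a configurable fraction of cases is re-emitted as an extra report
   version with a higher primaryid and a later FDA receipt date —
   duplicates the cleaning stage must collapse.

Identical config + seed gives byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .dates import PartialDate
from .io import (DemoRecord, DrugRecord, OutcRecord, PtSocMap, QuarterData,
                 ReacRecord, TherRecord, write_quarter)

# ---------------------------------------------------------------------------
# Default vocabularies: a tolvaptan-like study world
# ---------------------------------------------------------------------------

#: canonical drug -> marginal probability of being the PS drug of a case
DEFAULT_DRUGS: dict[str, float] = {
    "tolvaptan": 0.15,
    "furosemide": 0.17,
    "spironolactone": 0.12,
    "amlodipine": 0.11,
    "aspirin": 0.10,
    "carvedilol": 0.09,
    "metformin": 0.09,
    "lisinopril": 0.09,
    "omeprazole": 0.08,
}

#: raw spelling variants the generator emits, with weights; the shipped
#: synonym dictionary must resolve all of them
DRUG_VARIANTS: dict[str, list[tuple[str, float]]] = {
    "tolvaptan": [("TOLVAPTAN", 0.50), ("Tolvaptan", 0.15), ("SAMSCA", 0.15),
                  ("JYNARQUE", 0.08), ("TOLVAPTAN 15MG", 0.07),
                  ("tolvaptan.", 0.05)],
}

#: preferred term -> (baseline per-draw weight, system organ class)
DEFAULT_PTS: dict[str, tuple[float, str]] = {
    # common background events
    "nausea": (0.080, "gastrointestinal disorders"),
    "headache": (0.065, "nervous system disorders"),
    "diarrhoea": (0.060, "gastrointestinal disorders"),
    "dizziness": (0.055, "nervous system disorders"),
    "fatigue": (0.055, "general disorders and administration site conditions"),
    "vomiting": (0.050, "gastrointestinal disorders"),
    "drug ineffective": (0.050, "general disorders and administration site conditions"),
    "rash": (0.045, "skin and subcutaneous tissue disorders"),
    "pyrexia": (0.040, "general disorders and administration site conditions"),
    "dyspnoea": (0.040, "respiratory, thoracic and mediastinal disorders"),
    "insomnia": (0.035, "psychiatric disorders"),
    "pruritus": (0.030, "skin and subcutaneous tissue disorders"),
    "constipation": (0.030, "gastrointestinal disorders"),
    "anaemia": (0.030, "blood and lymphatic system disorders"),
    "hypertension": (0.030, "vascular disorders"),
    "cough": (0.030, "respiratory, thoracic and mediastinal disorders"),
    "oedema peripheral": (0.030, "general disorders and administration site conditions"),
    "arthralgia": (0.030, "musculoskeletal and connective tissue disorders"),
    "malaise": (0.030, "general disorders and administration site conditions"),
    "decreased appetite": (0.025, "metabolism and nutrition disorders"),
    # tolvaptan-characteristic events (low background)
    "cardiac failure": (0.0150, "cardiac disorders"),
    "renal impairment": (0.0120, "renal and urinary disorders"),
    "dehydration": (0.0100, "metabolism and nutrition disorders"),
    "hyponatraemia": (0.0100, "metabolism and nutrition disorders"),
    "blood creatinine increased": (0.0100, "investigations"),
    "hepatic function abnormal": (0.0080, "hepatobiliary disorders"),
    "alanine aminotransferase increased": (0.0080, "investigations"),
    "blood sodium decreased": (0.0050, "investigations"),
    "thirst": (0.0040, "general disorders and administration site conditions"),
    "pollakiuria": (0.0040, "renal and urinary disorders"),
    "polyuria": (0.0030, "renal and urinary disorders"),
    "hypernatraemia": (0.0030, "metabolism and nutrition disorders"),
    "polydipsia": (0.0015, "metabolism and nutrition disorders"),
    "osmotic demyelination syndrome": (0.0008, "nervous system disorders"),
    "renal cyst ruptured": (0.0005, "renal and urinary disorders"),
}

#: Table-3-like marginal distributions of the study world
DEFAULT_SEX = {"female": 0.434, "male": 0.435, "unknown": 0.131}
DEFAULT_REPORTER = {"physician": 0.4355, "consumer": 0.2259,
                    "pharmacist": 0.2221, "other health-professional": 0.0846,
                    "unknown": 0.0311, "registered nurse": 0.0005,
                    "lawyer": 0.0003}
DEFAULT_COUNTRY = {"US": 0.4177, "JP": 0.3046, "other": 0.0895, "PH": 0.0410,
                   "GB": 0.0398, "CA": 0.0378, "DE": 0.0252, "CN": 0.0135,
                   "FR": 0.0123, "KR": 0.0095, "ES": 0.0091}
DEFAULT_YEARS = {2009: 0.0017, 2010: 0.0056, 2011: 0.0135, 2012: 0.0484,
                 2013: 0.0524, 2014: 0.0365, 2015: 0.0425, 2016: 0.0677,
                 2017: 0.0846, 2018: 0.0983, 2019: 0.1332, 2020: 0.0756,
                 2021: 0.0704, 2022: 0.0822, 2023: 0.0926, 2024: 0.0948}
DEFAULT_OUTCOMES = {"other serious": 0.495, "hospitalization": 0.2536,
                    "death": 0.2049, "life threatening": 0.0292,
                    "disability": 0.0155, "required intervention": 0.0013,
                    "congenital anomaly": 0.0006}
#: onset-delay bins with an explicit unknown mass (missing/partial dates)
DEFAULT_ONSET = {"<7": 0.1962, "7-28": 0.0752, "28-60": 0.0375,
                 ">=60": 0.1282, "unknown": 0.5628}


@dataclass
class SyntheticConfig:
    """Generative parameters; the defaults emulate a tolvaptan-like
    reporting world at desk scale."""

    n_cases: int = 200
    seed: int = 42
    drug_vocab: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRUGS))
    pt_vocab: dict[str, tuple[float, str]] = field(default_factory=lambda: dict(DEFAULT_PTS))
    true_rr: dict[tuple[str, str], float] = field(default_factory=dict)
    pts_per_case: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.30, 3: 0.25, 4: 0.15, 5: 0.05})
    duplicate_rate: float = 0.05
    missing_age: float = 0.343
    missing_weight: float = 0.775
    sex_dist: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX))
    reporter_dist: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REPORTER))
    country_dist: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY))
    year_dist: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_YEARS))
    outcome_model: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOMES))
    onset_model: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ONSET))
    age_mean: float = 62.0
    age_sd: float = 18.0
    weight_mean_kg: float = 70.0
    weight_sd_kg: float = 18.0
    lbs_fraction: float = 0.3          # weights recorded in pounds
    concomitant_mean: float = 1.2      # Poisson mean of extra drug rows
    concomitant_roles: dict[str, float] = field(
        default_factory=lambda: {"SS": 0.2, "C": 0.7, "I": 0.1})

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if not (0 <= self.duplicate_rate < 1):
            raise ValueError("duplicate_rate must be in [0, 1)")
        for (drug, pt), rr in self.true_rr.items():
            if rr <= 0:
                raise ValueError(f"true_rr[{drug!r},{pt!r}] must be > 0")
            if drug not in self.drug_vocab or pt not in self.pt_vocab:
                raise ValueError(f"true_rr pair ({drug!r}, {pt!r}) not in vocab")

    def pt_soc_map(self) -> PtSocMap:
        return PtSocMap({pt: soc for pt, (_, soc) in self.pt_vocab.items()})

    def elevated_pairs(self) -> dict[tuple[str, str], float]:
        return {pair: rr for pair, rr in self.true_rr.items() if rr != 1.0}


def tolvaptan_study_config(n_cases: int = 200, seed: int = 42,
                           **overrides) -> SyntheticConfig:
    """Study-emulation config: tolvaptan carries elevated risks for its
    characteristic events (thirst, hypernatraemia, polyuria, ...)."""
    true_rr = {
        ("tolvaptan", "thirst"): 45.0,
        ("tolvaptan", "hypernatraemia"): 55.0,
        ("tolvaptan", "polyuria"): 35.0,
        ("tolvaptan", "polydipsia"): 40.0,
        ("tolvaptan", "blood sodium decreased"): 25.0,
        ("tolvaptan", "osmotic demyelination syndrome"): 60.0,
        ("tolvaptan", "renal cyst ruptured"): 80.0,
        ("tolvaptan", "dehydration"): 6.0,
        ("tolvaptan", "renal impairment"): 9.0,
        ("tolvaptan", "hepatic function abnormal"): 11.0,
        ("tolvaptan", "blood creatinine increased"): 5.0,
        ("tolvaptan", "cardiac failure"): 5.0,
    }
    return SyntheticConfig(n_cases=n_cases, seed=seed, true_rr=true_rr,
                           **overrides)


def recovery_config(n_cases: int = 50_000, seed: int = 0, rr: float = 8.0,
                    expected_a: float = 50.0,
                    pair: tuple[str, str] = ("tolvaptan", "hypernatraemia"),
                    ) -> SyntheticConfig:
    """Config with a single elevated pair, its baseline calibrated so the
    expected target-cell count a is ``expected_a``."""
    cfg = SyntheticConfig(n_cases=n_cases, seed=seed)
    drug, pt = pair
    p_drug = cfg.drug_vocab[drug]
    mean_m = sum(k * p for k, p in cfg.pts_per_case.items())
    p_case = expected_a / (n_cases * p_drug)          # P(pt in a drug case)
    q = 1.0 - (1.0 - p_case) ** (1.0 / mean_m)        # per-draw probability
    total_w = sum(w for w, _ in cfg.pt_vocab.values())
    baseline = q * total_w / rr
    cfg.pt_vocab = dict(cfg.pt_vocab)
    cfg.pt_vocab[pt] = (baseline, cfg.pt_vocab[pt][1])
    cfg.true_rr = {pair: rr}
    return cfg


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator actually did: exported with every corpus."""

    true_rr: dict[tuple[str, str], float]
    cases: pd.DataFrame   # caseid, primaryid_original, primaryid_final, ps_drug, n_versions

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.cases.to_csv(out_dir / "ground_truth_cases.tsv", sep="\t", index=False)
        rr = pd.DataFrame(
            [(d, p, v) for (d, p), v in sorted(self.true_rr.items())],
            columns=["drug", "pt", "true_rr"])
        rr.to_csv(out_dir / "ground_truth_rr.tsv", sep="\t", index=False)


@dataclass
class SyntheticCorpus:
    data: QuarterData
    ground_truth: GroundTruth
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        paths = write_quarter(self.data, out_dir)
        self.ground_truth.write(out_dir)
        soc_rows = sorted((pt, soc) for pt, (_, soc) in self.config.pt_vocab.items())
        map_path = Path(out_dir) / "pt_soc_map.csv"
        map_path.write_text(
            "pt,soc\n" + "".join(f"{pt},{soc}\n" for pt, soc in soc_rows))
        paths["pt_soc_map"] = map_path
        return paths


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _choice(rng: np.random.Generator, dist: Mapping, size: int) -> np.ndarray:
    keys = list(dist.keys())
    p = np.asarray([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.asarray(keys, dtype=object)[idx]


def _sample_pts(rng: np.random.Generator, weights: np.ndarray,
                m: np.ndarray) -> list[np.ndarray]:
    """Weighted sampling without replacement per case via Gumbel keys.

    ``weights`` is (n_cases, V); row weights need not be normalized.
    """
    n, v = weights.shape
    if np.any(weights.sum(axis=1) <= 0):
        raise ValueError("degenerate PT probabilities: a row sums to zero")
    with np.errstate(divide="ignore"):
        logw = np.where(weights > 0, np.log(weights), -np.inf)
    keys = logw + rng.gumbel(size=(n, v))
    order = np.argsort(-keys, axis=1)
    return [order[i, : m[i]] for i in range(n)]


def _random_day(rng: np.random.Generator, year: int) -> PartialDate:
    return PartialDate(int(year), int(rng.integers(1, 13)),
                       int(rng.integers(1, 29)))


def generate(config: SyntheticConfig,
             out_dir: Optional[str | Path] = None) -> SyntheticCorpus:
    """Generate a corpus; deterministic for a given config + seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    drug_names = sorted(config.drug_vocab)
    drug_p = np.array([config.drug_vocab[d] for d in drug_names], dtype=float)
    drug_p /= drug_p.sum()
    ps_idx = rng.choice(len(drug_names), size=n, p=drug_p)

    pt_names = sorted(config.pt_vocab)
    base_w = np.array([config.pt_vocab[p][0] for p in pt_names], dtype=float)
    # per-drug weight vectors: baseline times the pair's relative risk
    w_by_drug = np.tile(base_w, (len(drug_names), 1))
    pt_index = {p: i for i, p in enumerate(pt_names)}
    drug_index = {d: i for i, d in enumerate(drug_names)}
    for (drug, pt), rr in config.true_rr.items():
        w_by_drug[drug_index[drug], pt_index[pt]] *= rr

    m = _choice(rng, config.pts_per_case, n).astype(int)
    case_pts = _sample_pts(rng, w_by_drug[ps_idx], m)

    sex = _choice(rng, config.sex_dist, n)
    reporter = _choice(rng, config.reporter_dist, n)
    country = _choice(rng, config.country_dist, n)
    years = _choice(rng, config.year_dist, n).astype(int)

    age_years = np.clip(rng.normal(config.age_mean, config.age_sd, n), 0.2, 105.0)
    age_missing = rng.random(n) < config.missing_age
    # a minority of ages arrive in non-year units to exercise conversion
    age_unit = _choice(rng, {"year": 0.90, "decade": 0.04, "month": 0.04,
                             "week": 0.01, "day": 0.01}, n)
    weight_kg = np.clip(rng.normal(config.weight_mean_kg, config.weight_sd_kg, n),
                        3.0, 250.0)
    weight_missing = rng.random(n) < config.missing_weight
    weight_lbs = rng.random(n) < config.lbs_fraction

    onset_cat = _choice(rng, config.onset_model, n)
    outcome_names = sorted(config.outcome_model)
    outcome_draws = {o: rng.random(n) < config.outcome_model[o]
                     for o in outcome_names}

    n_conc = np.minimum(rng.poisson(config.concomitant_mean, n), 4)
    role_names = sorted(config.concomitant_roles)
    role_p = np.array([config.concomitant_roles[r] for r in role_names])
    role_p /= role_p.sum()

    dup_mask = rng.random(n) < config.duplicate_rate

    data = QuarterData()
    gt_rows: list[tuple] = []
    onset_ranges = {"<7": (0, 7), "7-28": (7, 28), "28-60": (28, 60),
                    ">=60": (60, 366)}

    for i in range(n):
        caseid = str(1_000_000 + i)
        pid1 = caseid + "1"
        ps_drug = drug_names[ps_idx[i]]
        year = int(years[i])
        fda_dt = _random_day(rng, year)

        # therapy start and event date per the onset model
        cat = onset_cat[i]
        start_dt: Optional[PartialDate] = _random_day(rng, year)
        event_dt: Optional[PartialDate] = None
        if cat == "unknown":
            mech = int(rng.integers(0, 3))
            if mech == 0:
                event_dt = None
            elif mech == 1:
                start_dt = None
                event_dt = _random_day(rng, year)
            else:   # month-precision start defeats day arithmetic
                event_dt = _random_day(rng, year)
                start_dt = PartialDate(start_dt.year, start_dt.month)
        else:
            lo, hi = onset_ranges[cat]
            delay = int(rng.integers(lo, hi))
            ev = start_dt.to_date() + pd.Timedelta(days=delay)
            event_dt = PartialDate(ev.year, ev.month, ev.day)

        # age recorded in the sampled unit
        a_val: Optional[float] = None
        a_unit = "unknown"
        if not age_missing[i]:
            a_unit = str(age_unit[i])
            factor = {"year": 1.0, "decade": 0.1, "month": 12.0,
                      "week": 52.18, "day": 365.25}[a_unit]
            a_val = round(float(age_years[i]) * factor, 1)

        w_val: Optional[float] = None
        w_unit = "unknown"
        if not weight_missing[i]:
            if weight_lbs[i]:
                w_unit, w_val = "lbs", round(float(weight_kg[i]) / 0.45359237, 1)
            else:
                w_unit, w_val = "kg", round(float(weight_kg[i]), 1)

        demo = DemoRecord(
            primaryid=pid1, caseid=caseid, fda_dt=fda_dt, event_dt=event_dt,
            sex=str(sex[i]), age_value=a_val, age_unit=a_unit,
            weight_value=w_val, weight_unit=w_unit,
            reporter=str(reporter[i]), country=str(country[i]))
        data.demo.append(demo)

        # drug rows: PS first, then concomitants with distinct names
        def raw_name(canonical: str) -> str:
            variants = DRUG_VARIANTS.get(canonical)
            if variants:
                names = [v for v, _ in variants]
                probs = np.array([p for _, p in variants])
                return str(names[rng.choice(len(names), p=probs / probs.sum())])
            return canonical.upper() if rng.random() < 0.7 else canonical.capitalize()

        case_drug_rows = [DrugRecord(primaryid=pid1, drug_seq=1,
                                     drugname=raw_name(ps_drug), role="PS")]
        case_ther_rows = []
        if start_dt is not None:
            case_ther_rows.append(TherRecord(primaryid=pid1, drug_seq=1,
                                             start_dt=start_dt))
        others = [d for d in drug_names if d != ps_drug]
        k = min(int(n_conc[i]), len(others))
        if k > 0:
            chosen = rng.choice(len(others), size=k, replace=False)
            roles = rng.choice(len(role_names), size=k, p=role_p)
            for j, (oi, ri) in enumerate(zip(chosen, roles), start=2):
                case_drug_rows.append(DrugRecord(
                    primaryid=pid1, drug_seq=j,
                    drugname=raw_name(others[oi]), role=role_names[ri]))

        case_reac_rows = [ReacRecord(primaryid=pid1, pt=pt_names[pt_i])
                          for pt_i in case_pts[i]]
        case_outc_rows = [OutcRecord(primaryid=pid1, outcome=o)
                          for o in outcome_names if outcome_draws[o][i]]
        data.drug.extend(case_drug_rows)
        data.reac.extend(case_reac_rows)
        data.outc.extend(case_outc_rows)
        data.ther.extend(case_ther_rows)

        final_pid = pid1
        n_versions = 1
        if dup_mask[i]:
            pid2 = caseid + "2"
            final_pid, n_versions = pid2, 2
            lag = int(rng.integers(1, 91))
            f2 = fda_dt.to_date() + pd.Timedelta(days=lag)
            data.demo.append(dataclasses.replace(
                demo, primaryid=pid2,
                fda_dt=PartialDate(f2.year, f2.month, f2.day)))
            data.drug.extend(dataclasses.replace(r, primaryid=pid2)
                             for r in case_drug_rows)
            data.reac.extend(dataclasses.replace(r, primaryid=pid2)
                             for r in case_reac_rows)
            data.outc.extend(dataclasses.replace(r, primaryid=pid2)
                             for r in case_outc_rows)
            data.ther.extend(dataclasses.replace(r, primaryid=pid2)
                             for r in case_ther_rows)

        gt_rows.append((caseid, pid1, final_pid, ps_drug, n_versions))

    truth = GroundTruth(
        true_rr=dict(config.true_rr),
        cases=pd.DataFrame(gt_rows, columns=[
            "caseid", "primaryid_original", "primaryid_final",
            "ps_drug", "n_versions"]))
    corpus = SyntheticCorpus(data=data, ground_truth=truth, config=config)
    if out_dir is not None:
        corpus.write(out_dir)
    return corpus


# ---------------------------------------------------------------------------
# Validation harnesses
# ---------------------------------------------------------------------------

def default_drug_dictionary():
    """Synonym dictionary covering every raw variant the generator emits."""
    from .cleaning import DrugDictionary
    synonyms: dict[str, str] = {}
    for canonical in DEFAULT_DRUGS:
        synonyms[canonical] = canonical
        for variant, _ in DRUG_VARIANTS.get(canonical, []):
            synonyms[variant] = canonical
    synonyms["SAMSCA"] = "tolvaptan"
    synonyms["JYNARQUE"] = "tolvaptan"
    return DrugDictionary(synonyms)


def run_corpus(corpus: SyntheticCorpus, drug: str, event: str, level: str = "PT"):
    """generate -> clean -> contingency -> signals for one pair."""
    from .cleaning import assemble_reports, deduplicate
    from .contingency import build_table
    from .signals import compute_signal

    demos = deduplicate(corpus.data.demo)
    reports, _ = assemble_reports(corpus.data, corpus.config.pt_soc_map(),
                                  default_drug_dictionary(), demos=demos)
    t = build_table(reports, drug, event, level)  # type: ignore[arg-type]
    return compute_signal(event, level, t)        # type: ignore[arg-type]


def recovery_experiment(config: SyntheticConfig, replicates: int = 20,
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Replicate the full pipeline on corpora with one elevated pair.

    Returns one row per replicate with the pair's estimates and flags.
    ``seed`` (default: config.seed) spawns per-replicate seeds.
    """
    elevated = config.elevated_pairs()
    if len(elevated) != 1:
        raise ValueError(f"need exactly one elevated pair, got {len(elevated)}")
    (drug, pt), rr = next(iter(elevated.items()))
    base_seed = config.seed if seed is None else seed
    seeds = np.random.SeedSequence(base_seed).generate_state(replicates) % (2**31)
    rows = []
    for r in range(replicates):
        cfg = dataclasses.replace(config, seed=int(seeds[r]))
        stats = run_corpus(generate(cfg), drug, pt)
        rows.append({
            "replicate": r, "seed": int(seeds[r]), "true_rr": rr,
            "a": stats.table.a, "ror": stats.ror, "ln_ror": np.log(stats.ror),
            "prr": stats.prr, "ic": stats.ic, "ebgm": stats.ebgm,
            "ror_ci_low": stats.ror_ci_low,
            "flag_ror": stats.flag_ror, "flag_prr": stats.flag_prr,
            "flag_bcpnn": stats.flag_bcpnn, "flag_ebgm": stats.flag_ebgm,
            "flag_all4": stats.flag_all4,
        })
    return pd.DataFrame(rows)


def null_calibration(config: SyntheticConfig, drug: str = "tolvaptan",
                     level: str = "PT") -> pd.DataFrame:
    """All-null corpus (every true_rr = 1): per-event flags.

    The fraction of events flagged by all four criteria estimates the
    screen's false-positive rate under independence.
    """
    from .cleaning import assemble_reports, deduplicate
    from .contingency import build_all_tables
    from .signals import compute_all_signals

    cfg = dataclasses.replace(config, true_rr={})
    corpus = generate(cfg)
    demos = deduplicate(corpus.data.demo)
    reports, _ = assemble_reports(corpus.data, cfg.pt_soc_map(),
                                  default_drug_dictionary(), demos=demos)
    tables = build_all_tables(reports, drug, level)  # type: ignore[arg-type]
    rows = compute_all_signals(tables, level)        # type: ignore[arg-type]
    return pd.DataFrame([{
        "event": s.event, "n": s.n, "ror": s.ror, "ic025": s.ic025,
        "ebgm05": s.ebgm05, "flag_all4": s.flag_all4} for s in rows])
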