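"""Descriptive surfaces: demographics, onset time, outcome-linked
events, concomitant medication, and stratified subgroup signals.

These are the non-disproportionality views of a drug's safety profile:
who the reports concern (sex, age, weight, reporter, country, year),
how serious they were (the seven FAERS outcome categories, counted per
(case, outcome) pair because one case may carry several outcomes), how
soon after therapy start the event occurred (binned days, honest about
partial dates), which drugs were co-reported, and how the
disproportionality signals look inside demographic strata.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Literal, Optional

import pandas as pd

from .cleaning import CaseReport
from .contingency import Level, build_all_tables
from .io import OUTCOME_NAMES
from .signals import BcpnnPriors, SignalStats, Thresholds, compute_all_signals

AGE_BINS_FINE = ("<18", "18-45", "45-65", "65-75", ">=75", "unknown")
AGE_BINS_COARSE = ("<18", "18-65", ">=65", "unknown")
WEIGHT_BINS = ("<40", "40-60", "60-80", "80-100", ">=100", "unknown")
ONSET_BINS = ("<7", "7-28", "28-60", ">=60", "unknown")

OUTCOME_ORDER = ("death", "life threatening", "hospitalization", "disability",
                 "congenital anomaly", "required intervention", "other serious")


def age_bin(age_years: Optional[float], coarse: bool = False) -> str:
    """Half-open [low, high) age bins in years; 18 falls in 18-45."""
    if age_years is None:
        return "unknown"
    if coarse:
        if age_years < 18:
            return "<18"
        if age_years < 65:
            return "18-65"
        return ">=65"
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-45"
    if age_years < 65:
        return "45-65"
    if age_years < 75:
        return "65-75"
    return ">=75"


def weight_bin(weight_kg: Optional[float]) -> str:
    if weight_kg is None:
        return "unknown"
    if weight_kg < 40:
        return "<40"
    if weight_kg < 60:
        return "40-60"
    if weight_kg < 80:
        return "60-80"
    if weight_kg < 100:
        return "80-100"
    return ">=100"


def onset_bin(days: Optional[int]) -> str:
    if days is None:
        return "unknown"
    if days < 7:
        return "<7"
    if days < 28:
        return "7-28"
    if days < 60:
        return "28-60"
    return ">=60"


def onset_days(report: CaseReport, drug: str) -> Optional[int]:
    """Days from the earliest day-precise therapy start of the drug's PS
    rows to the event date; None when either side is absent, coarser
    than day precision, or the difference is negative."""
    event_dt = report.demo.event_dt
    if event_dt is None or event_dt.precision != "day":
        return None
    starts = [report.therapy_starts[d.drug_seq]
              for d in report.drugs
              if d.role == "PS" and d.name == drug
              and d.drug_seq in report.therapy_starts
              and report.therapy_starts[d.drug_seq].precision == "day"]
    if not starts:
        return None
    earliest = min(starts, key=lambda s: s.sort_key())
    days = earliest.days_until(event_dt)
    if days is None or days < 0:
        return None
    return days


def _target_cases(reports: Iterable[CaseReport], drug: str) -> list[CaseReport]:
    return [r for r in reports if r.is_primary_suspect(drug)]


def summarize(reports: Iterable[CaseReport], drug: str) -> pd.DataFrame:
    """Demographic / outcome / onset summary of the drug's PS cases.

    Returns a tidy frame (section, category, count, pct).  Outcome
    counts are per (case, outcome) pair; every other section counts
    each case once.  Percentages are taken against the full PS case
    total, unknowns included, so the outcome section may sum past 100.
    """
    cases = _target_cases(reports, drug)
    total = len(cases)
    sections: list[tuple[str, str, int]] = []

    def tally(section: str, values: Iterable[str],
              order: Optional[tuple[str, ...]] = None) -> None:
        counts = Counter(values)
        if order is None:
            keys = sorted(counts, key=lambda k: (-counts[k], k))
        else:
            keys = [k for k in order if k in counts]
            keys += sorted(set(counts) - set(order))
        for key in keys:
            sections.append((section, key, counts[key]))

    tally("year", (str(c.demo.fda_dt.year) for c in cases))
    tally("sex", (c.demo.sex for c in cases), ("female", "male", "unknown"))
    tally("age", (age_bin(c.age_years) for c in cases), AGE_BINS_FINE)
    tally("weight", (weight_bin(c.weight_kg) for c in cases), WEIGHT_BINS)
    tally("reporter", (c.demo.reporter for c in cases))
    tally("country", (c.demo.country for c in cases))
    tally("outcome",
          (o for c in cases for o in sorted(c.outcomes)), OUTCOME_ORDER)
    tally("onset", (onset_bin(onset_days(c, drug)) for c in cases), ONSET_BINS)

    df = pd.DataFrame(sections, columns=["section", "category", "count"])
    df["pct"] = (100.0 * df["count"] / total).round(2) if total else 0.0
    return df


def top_events_by_outcome(reports: Iterable[CaseReport], drug: str,
                          outcome: str, k: int = 10) -> list[tuple[str, int]]:
    """Top-k preferred terms among the drug's PS cases with the outcome.

    Counts are cases (a PT repeated within a case counts once);
    descending, ties broken by PT name.
    """
    if outcome not in OUTCOME_NAMES:
        raise ValueError(f"unknown outcome {outcome!r}; "
                         f"expected one of {sorted(OUTCOME_NAMES)}")
    counts: Counter[str] = Counter()
    for case in _target_cases(reports, drug):
        if outcome in case.outcomes:
            counts.update(set(case.pt_names()))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def concomitant_frequency(reports: Iterable[CaseReport], drug: str,
                          k: Optional[int] = None) -> list[tuple[str, int]]:
    """Distinct-case counts of every other drug co-reported (any role:
    SS, C, I — or even PS of a second suspect) in the drug's PS cases."""
    counts: Counter[str] = Counter()
    for case in _target_cases(reports, drug):
        others = {d.name for d in case.drugs if d.name != drug}
        counts.update(others)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k] if k is not None else ranked


Stratifier = Literal["age_coarse", "sex", "weight"]


def _stratum_of(report: CaseReport, stratifier: Stratifier) -> str:
    if stratifier == "age_coarse":
        return age_bin(report.age_years, coarse=True)
    if stratifier == "sex":
        return report.demo.sex
    if stratifier == "weight":
        return weight_bin(report.weight_kg)
    raise ValueError(f"unknown stratifier {stratifier!r}; "
                     "expected age_coarse, sex or weight")


def subgroup_signals(reports: Iterable[CaseReport], drug: str,
                     stratifier: Stratifier, level: Level,
                     thresholds: Thresholds | None = None,
                     priors: BcpnnPriors | None = None,
                     rank_by: str = "n",
                     ) -> dict[str, list[SignalStats]]:
    """Per-stratum disproportionality: both arms of every contingency
    table are restricted to the stratum's cases.  Strata with zero
    drug-PS cases are omitted."""
    from .signals import rank_signals

    strata: dict[str, list[CaseReport]] = {}
    for report in reports:
        strata.setdefault(_stratum_of(report, stratifier), []).append(report)

    out: dict[str, list[SignalStats]] = {}
    for stratum in sorted(strata):
        members = strata[stratum]
        if not any(r.is_primary_suspect(drug) for r in members):
            continue
        tables = build_all_tables(members, drug, level)
        soc_of = {}
        if level == "PT":
            for r in members:
                for pt, soc in r.pts:
                    soc_of.setdefault(pt, soc)
        rows = compute_all_signals(tables, level, soc_of=soc_of,
                                   priors=priors, thresholds=thresholds)
        out[stratum] = rank_signals(rows, by=rank_by)  # type: ignore[arg-type]
    return out
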