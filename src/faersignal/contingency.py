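"""Fourfold (2x2) contingency tables for drug-event pairs.

Every disproportionality statistic rests on the same table::

                      target event    other events    total
    target drug            a               b          a + b
    other drugs            c               d          c + d

The counting unit is the distinct (case, event) pair: a case with three
distinct preferred terms contributes three pairs, but a term reported
twice inside one case contributes once.  "Target drug" membership means
the drug appears with role PS (primary suspect) in the case; at SOC
level a case counts once per organ class however many of its terms
share it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .cleaning import CaseReport

Level = Literal["PT", "SOC"]


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """a/b/c/d cells; cells are ordinarily integer case counts but may
    be real-valued when a table is reconstructed from published summary
    statistics."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"negative cell {name}={getattr(self, name)}")

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    def with_correction(self, k: float = 0.5) -> "ContingencyTable":
        """Haldane-style continuity correction (adds k to every cell)."""
        return ContingencyTable(self.a + k, self.b + k, self.c + k, self.d + k)


def _case_events(report: CaseReport, level: Level) -> set[str]:
    if level == "PT":
        return set(report.pt_names())
    if level == "SOC":
        return report.socs()
    raise ValueError(f"unknown level {level!r}; expected 'PT' or 'SOC'")


def _is_target(report: CaseReport, drug: str) -> bool:
    return report.is_primary_suspect(drug)


def build_all_tables(reports: Iterable[CaseReport], drug: str, level: Level,
                     comparator: str = "non_ps",
                     ) -> dict[str, ContingencyTable]:
    """One fourfold table per event observed anywhere in the corpus.

    All tables share the same total N (the corpus-wide count of
    distinct (case, event) pairs), and for a fixed drug a+b is constant
    across events.

    ``comparator`` controls the "other drugs" arm: ``"non_ps"`` (the
    default) counts every case without a PS record of the target drug;
    ``"no_mention"`` additionally drops cases where the target drug
    appears in any role, removing them from the corpus entirely.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"unknown level {level!r}; expected 'PT' or 'SOC'")
    if comparator not in ("non_ps", "no_mention"):
        raise ValueError(f"unknown comparator {comparator!r}")

    a: dict[str, int] = {}
    c: dict[str, int] = {}
    pairs_target = 0
    pairs_other = 0
    for report in reports:
        target = _is_target(report, drug)
        if not target and comparator == "no_mention" and report.has_drug(drug):
            continue
        events = _case_events(report, level)
        if target:
            pairs_target += len(events)
            for e in events:
                a[e] = a.get(e, 0) + 1
        else:
            pairs_other += len(events)
            for e in events:
                c[e] = c.get(e, 0) + 1

    tables: dict[str, ContingencyTable] = {}
    for event in sorted(set(a) | set(c)):
        ae = a.get(event, 0)
        ce = c.get(event, 0)
        tables[event] = ContingencyTable(a=ae, b=pairs_target - ae,
                                         c=ce, d=pairs_other - ce)
    return tables


def build_table(reports: Iterable[CaseReport], drug: str, event: str,
                level: Level, comparator: str = "non_ps") -> ContingencyTable:
    """Fourfold table for a single (drug, event) pair.

    A drug absent from every report yields a table with a = b = 0.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"unknown level {level!r}; expected 'PT' or 'SOC'")
    if comparator not in ("non_ps", "no_mention"):
        raise ValueError(f"unknown comparator {comparator!r}")
    a = b = c = d = 0
    for report in reports:
        target = _is_target(report, drug)
        if not target and comparator == "no_mention" and report.has_drug(drug):
            continue
        events = _case_events(report, level)
        hit = event in events
        others = len(events) - int(hit)
        if target:
            a += int(hit)
            b += others
        else:
            c += int(hit)
            d += others
    return ContingencyTable(a=a, b=b, c=c, d=d)
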