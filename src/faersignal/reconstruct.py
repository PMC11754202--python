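"""Reconstruct a fourfold table from published summary statistics.

Published signal tables print, per drug-event row, the case count n,
the ROR point estimate with its 95% CI, and the PRR — but not the
underlying b, c, d cells.  Those three cells are nevertheless
identified by the printed numbers:

* SE(lnROR) is recovered from the CI as ln(high/low) / (2 * 1.96);
* ROR = ad/(bc) and PRR = (a/(a+b)) / (c/(c+d)) share b, c, d with
  SE(lnROR)^2 = 1/a + 1/b + 1/c + 1/d.

Eliminating d between the ROR and PRR equations gives a closed form:

    b = a (PRR - 1) / (ROR - PRR)
    1/c + 1/d = SE^2 - 1/a - 1/b   with  d = ROR * b * c / a
    c = (1 + a/(ROR*b)) / (SE^2 - 1/a - 1/b),   d = ROR*b*c/a

Re-evaluating the IC and EBGM formulas on the reconstructed table must
then reproduce the row's printed IC and EBGM — an internal-consistency
check of a published analysis that needs no access to the source
database.  The recovered cells are real-valued: printed rounding means
they are close to, but not exactly, the original integer counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .contingency import ContingencyTable
from .signals import SignalStats, Z95, compute_signal


def se_from_ci(ci_low: float, ci_high: float, z: float = Z95) -> float:
    """Standard error of a log-scale estimate from its log-symmetric CI."""
    if not (0 < ci_low < ci_high):
        raise ValueError(f"need 0 < low < high, got ({ci_low}, {ci_high})")
    return math.log(ci_high / ci_low) / (2.0 * z)


def reconstruct_table(a: float, ror: float, ror_ci_low: float,
                      ror_ci_high: float, prr: float) -> ContingencyTable:
    """Solve for b, c, d given a row's printed a=n, ROR, ROR CI and PRR.

    Requires ROR > PRR > 1 (which holds for any elevated signal in a
    large database, since ROR/PRR = (1 + a/b)/(1 + c/d) > 1 there).
    Raises ValueError when the printed numbers are mutually
    inconsistent (no positive solution).
    """
    if a <= 0:
        raise ValueError("a must be positive")
    if not (ror > prr > 1):
        raise ValueError(
            f"reconstruction needs ROR > PRR > 1, got ROR={ror}, PRR={prr}")
    se2 = se_from_ci(ror_ci_low, ror_ci_high) ** 2
    b = a * (prr - 1.0) / (ror - prr)
    rest = se2 - 1.0 / a - 1.0 / b
    if rest <= 0:
        raise ValueError(
            "printed CI is too narrow for the printed n/ROR/PRR "
            f"(SE^2 - 1/a - 1/b = {rest:g} <= 0)")
    c = (1.0 + a / (ror * b)) / rest
    d = ror * b * c / a
    return ContingencyTable(a=float(a), b=b, c=c, d=d)


@dataclass(frozen=True)
class PublishedRow:
    """A row of a published signal table, as printed."""

    event: str
    level: str                 # "PT" or "SOC"
    n: int
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    ic: float | None = None    # printed IC, for comparison
    ebgm: float | None = None  # printed EBGM, for comparison


def reevaluate_row(row: PublishedRow) -> SignalStats:
    """Reconstruct the row's table and re-run all four algorithms on it."""
    t = reconstruct_table(row.n, row.ror, row.ror_ci_low,
                          row.ror_ci_high, row.prr)
    return compute_signal(row.event, row.level, t)  # type: ignore[arg-type]
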