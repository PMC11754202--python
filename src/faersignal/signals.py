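"""Disproportionality statistics: ROR, PRR, BCPNN information component,
and the observed/expected EBGM, with their interval bounds and
screening thresholds.

All four statistics compare the observed count ``a`` of a drug-event
pair with what independence of drug and event would predict from the
margins of the fourfold table:

* ROR  = (a/c) / (b/d), the reporting odds ratio, with a log-normal
  95% CI from SE(lnROR) = sqrt(1/a + 1/b + 1/c + 1/d);
* PRR  = (a/(a+b)) / (c/(c+d)), the proportional reporting ratio, with
  SE(lnPRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d));
* IC   = log2( a*N / ((a+b)(a+c)) ), the BCPNN information component,
  with posterior moments E(IC), V(IC) from the Bate et al. Dirichlet
  priors and the two-sided bound IC025 = E(IC) - 2*sqrt(V(IC));
* EBGM = a*N / ((a+b)(a+c)), here the raw observed-to-expected ratio
  with a log-normal interval (no gamma-Poisson shrinkage; see
  ``ebgm_stats`` for the rationale), so that IC == log2(EBGM)
  identically.

A pair is screened in ("flagged") when it passes an algorithm's
threshold; the conjunction of all four (`flag_all4`) is the strictest
screen.  Default thresholds: ROR >= 3 with n >= 3 and CI lower bound
> 1; PRR >= 2 with n >= 3 and CI lower bound > 1; IC025 > 0;
EBGM05 > 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional

from .contingency import ContingencyTable

LN2 = math.log(2.0)
Z95 = 1.96          # as printed in the method tables of this literature
Z05 = 1.645         # one-sided 5th percentile, used for EBGM05/EBGM95

NAN = float("nan")


@dataclass(frozen=True, slots=True)
class BcpnnPriors:
    """Prior constants of the BCPNN posterior moments.

    The classic single-drug/single-event choice: Dirichlet hyperpriors
    alpha1 = beta1 = 1 on the margins, alpha = beta = 2 on the totals,
    gamma11 = 1 on the joint cell, with gamma tied to the margins so
    that E(IC) = 0 under exact independence.
    """

    alpha: float = 2.0
    alpha1: float = 1.0
    beta: float = 2.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def gamma(self, t: ContingencyTable) -> float:
        n = t.n_total
        return (self.gamma11 * (n + self.alpha) * (n + self.beta)
                / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1)))


@dataclass
class Thresholds:
    """Screening thresholds; defaults follow common pharmacovigilance
    practice (EMA-style PRR criterion, stricter ROR criterion)."""

    ror_min: float = 3.0
    ror_n_min: int = 3
    ror_ci_low_gt: float = 1.0
    prr_min: float = 2.0
    prr_n_min: int = 3
    prr_ci_low_gt: float = 1.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0
    #: require the PRR CI lower-bound condition in addition to PRR >= 2
    #: and n >= 3 (the text-only criterion omits it; both are defensible)
    require_prr_ci: bool = True


@dataclass
class SignalStats:
    """All four statistics for one drug-event pair at one level."""

    event: str
    level: Literal["PT", "SOC"]
    n: int
    soc: str = ""
    table: Optional[ContingencyTable] = None
    ror: float = NAN
    ror_ci_low: float = NAN
    ror_ci_high: float = NAN
    prr: float = NAN
    prr_ci_low: float = NAN
    prr_ci_high: float = NAN
    ic: float = NAN
    ic_expect: float = NAN
    ic_var: float = NAN
    ic025: float = NAN          # E(IC) - 2*sqrt(V(IC))
    ic025_crude: float = NAN    # IC - 2*sqrt(V(IC)), the published style
    ebgm: float = NAN
    ebgm05: float = NAN
    ebgm95: float = NAN
    flag_ror: bool = False
    flag_prr: bool = False
    flag_bcpnn: bool = False
    flag_ebgm: bool = False
    flag_all4: bool = False


def _finite(*xs: float) -> bool:
    return all(math.isfinite(x) for x in xs)


# ---------------------------------------------------------------------------
# Point estimates and intervals
# ---------------------------------------------------------------------------

def ror_stats(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with log-symmetric 95% CI.

    Any zero cell makes the statistic non-computable (returned as NaN);
    no continuity correction is applied by default — use
    ``t.with_correction()`` for a Haldane +0.5 table.
    """
    if min(t.a, t.b, t.c, t.d) <= 0:
        return NAN, NAN, NAN
    ror = (t.a / t.c) / (t.b / t.d)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


def prr_stats(t: ContingencyTable) -> tuple[float, float, float]:
    """Proportional reporting ratio with log-symmetric 95% CI."""
    if t.a <= 0 or t.c <= 0 or (t.a + t.b) <= 0 or (t.c + t.d) <= 0:
        return NAN, NAN, NAN
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se2 = 1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d)
    se = math.sqrt(max(se2, 0.0))
    return (prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se))


def bcpnn_stats(t: ContingencyTable, priors: BcpnnPriors | None = None,
                ) -> tuple[float, float, float, float]:
    """BCPNN information component and posterior moments.

    Returns ``(ic, e_ic, v_ic, ic025)`` where ``ic`` is the crude
    log2 observed/expected ratio (NaN when a = 0), and ``e_ic``,
    ``v_ic`` are the Bate et al. posterior mean and variance, which the
    priors keep finite even at a = 0.  ``ic025 = e_ic - 2*sqrt(v_ic)``.
    """
    if priors is None:
        priors = BcpnnPriors()
    n = t.n_total
    if n <= 0:
        raise ValueError("empty table: N must be positive")
    a, ab, ac = t.a, t.a + t.b, t.a + t.c
    if a > 0 and ab > 0 and ac > 0:
        ic = math.log2(a * n / (ab * ac))
    else:
        ic = NAN
    g11, al, al1, be, be1 = (priors.gamma11, priors.alpha, priors.alpha1,
                             priors.beta, priors.beta1)
    gamma = priors.gamma(t)
    e_ic = math.log2((a + g11) * (n + al) * (n + be)
                     / ((n + gamma) * (ab + al1) * (ac + be1)))
    v_ic = ((n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
            + (n - ab + al - al1) / ((ab + al1) * (1 + n + al))
            + (n - ac + be - be1) / ((ac + be1) * (1 + n + be))) / (LN2 ** 2)
    ic025 = e_ic - 2.0 * math.sqrt(v_ic)
    return ic, e_ic, v_ic, ic025


def ebgm_stats(t: ContingencyTable, z05: float = Z05,
               ) -> tuple[float, float, float]:
    """Observed/expected ratio a*N/((a+b)(a+c)) with log-normal bounds.

    This is the ratio form printed in this literature's method tables —
    the crude relative reporting rate, *not* the shrunk gamma-Poisson
    mixture estimate of full MGPS.  Consequently log2(EBGM) equals the
    BCPNN IC identically.  EBGM05/EBGM95 are the 5th/95th
    percentile-style bounds exp(lnEBGM -/+ z05*SE) with
    SE = sqrt(1/a + 1/b + 1/c + 1/d).
    """
    if t.a <= 0 or (t.a + t.b) <= 0 or (t.a + t.c) <= 0:
        return NAN, NAN, NAN
    ebgm = t.a * t.n_total / ((t.a + t.b) * (t.a + t.c))
    if min(t.b, t.c, t.d) <= 0:
        return ebgm, NAN, NAN
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return (ebgm, ebgm * math.exp(-z05 * se), ebgm * math.exp(z05 * se))


# ---------------------------------------------------------------------------
# Assembly, flags, ranking
# ---------------------------------------------------------------------------

def compute_signal(event: str, level: Literal["PT", "SOC"],
                   t: ContingencyTable, soc: str = "",
                   priors: BcpnnPriors | None = None,
                   thresholds: Thresholds | None = None) -> SignalStats:
    """Evaluate all four algorithms on one table and apply thresholds."""
    ror, ror_lo, ror_hi = ror_stats(t)
    prr, prr_lo, prr_hi = prr_stats(t)
    ic, e_ic, v_ic, ic025 = bcpnn_stats(t, priors)
    ebgm, ebgm05, ebgm95 = ebgm_stats(t)
    ic025_crude = ic - 2.0 * math.sqrt(v_ic) if _finite(ic, v_ic) else NAN
    stats = SignalStats(
        event=event, level=level, n=int(t.a) if float(t.a).is_integer() else t.a,
        soc=soc or (event if level == "SOC" else ""), table=t,
        ror=ror, ror_ci_low=ror_lo, ror_ci_high=ror_hi,
        prr=prr, prr_ci_low=prr_lo, prr_ci_high=prr_hi,
        ic=ic, ic_expect=e_ic, ic_var=v_ic, ic025=ic025,
        ic025_crude=ic025_crude,
        ebgm=ebgm, ebgm05=ebgm05, ebgm95=ebgm95,
    )
    return evaluate_flags(stats, thresholds or Thresholds())


def evaluate_flags(stats: SignalStats, th: Thresholds) -> SignalStats:
    """Apply the per-algorithm thresholds; NaN statistics never flag."""
    n = stats.n
    flag_ror = (_finite(stats.ror, stats.ror_ci_low)
                and n >= th.ror_n_min
                and stats.ror >= th.ror_min
                and stats.ror_ci_low > th.ror_ci_low_gt)
    flag_prr = (_finite(stats.prr)
                and n >= th.prr_n_min
                and stats.prr >= th.prr_min
                and (not th.require_prr_ci
                     or (_finite(stats.prr_ci_low)
                         and stats.prr_ci_low > th.prr_ci_low_gt)))
    flag_bcpnn = _finite(stats.ic025) and stats.ic025 > th.ic025_gt
    flag_ebgm = _finite(stats.ebgm05) and stats.ebgm05 > th.ebgm05_gt
    return replace(stats, flag_ror=flag_ror, flag_prr=flag_prr,
                   flag_bcpnn=flag_bcpnn, flag_ebgm=flag_ebgm,
                   flag_all4=flag_ror and flag_prr and flag_bcpnn and flag_ebgm)


def rank_signals(rows: Iterable[SignalStats],
                 by: Literal["n", "ror", "ebgm"] = "n") -> list[SignalStats]:
    """Stable descending sort; ties broken by n descending, then event
    name ascending.  NaN sorts last."""
    if by not in ("n", "ror", "ebgm"):
        raise ValueError(f"unknown ranking key {by!r}")

    def key(row: SignalStats):
        value = getattr(row, by)
        if isinstance(value, float) and math.isnan(value):
            value = -math.inf
        return (-value, -row.n, row.event)

    return sorted(rows, key=key)


def compute_all_signals(tables: dict[str, ContingencyTable],
                        level: Literal["PT", "SOC"],
                        soc_of: Optional[dict[str, str]] = None,
                        priors: BcpnnPriors | None = None,
                        thresholds: Thresholds | None = None,
                        ) -> list[SignalStats]:
    """Convenience: compute_signal over an event -> table mapping."""
    soc_of = soc_of or {}
    return [compute_signal(event, level, t, soc=soc_of.get(event, ""),
                           priors=priors, thresholds=thresholds)
            for event, t in tables.items()]
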