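# Methods

This note records the models implemented, the numerical and design
choices made where the design was genuinely open, and what the tests
do and do not establish.

## Counting model

The unit of analysis is the **unique case**, not the report: FAERS
distributes every revision of a case as a separate report version, so
all counting is preceded by deduplication — per CASEID keep the
version with the latest FDA receipt date, ties broken by the highest
numeric PRIMARYID.  Deduplication is idempotent and order-independent,
and a tie between non-numeric primaryids is a hard error because the
rule cannot be applied.

Contingency tables count **distinct (case, event) pairs**.  A case
with three distinct preferred terms contributes three pairs; a term
repeated within one case contributes once; at SOC level a case
contributes once per organ class regardless of how many of its terms
share it.  Consequences used as invariants: every table for a fixed
drug shares N (total pairs in the corpus) and a+b (pairs in the drug
arm); a+c equals the corpus-wide case count of the event.

"Target drug" membership means a primary-suspect (PS) role.  The
comparator arm (`c`, `d`) counts cases with *no PS record* of the
target drug; cases where it appears with non-PS roles remain in the
comparator by default, and `comparator="no_mention"` removes them
entirely — the choice matters only when secondary/concomitant mentions
are common.

## Disproportionality statistics

ROR and PRR are implemented exactly as their standard formulas with
log-symmetric 95% intervals (z = 1.96).  Any zero cell makes ROR
non-computable; no continuity correction is applied by default (a
Haldane +0.5 via `ContingencyTable.with_correction()` exists but is
off, because screening thresholds already require n ≥ 3).

**BCPNN.**  The information component is the crude
IC = log₂[aN/((a+b)(a+c))].  Posterior moments use the classic
single-drug/single-event Bate et al. priors γ₁₁ = 1, α = β = 2,
α₁ = β₁ = 1, with γ tied to the margins,

    γ = γ₁₁ (N+α)(N+β) / ((a+b+α₁)(a+c+β₁)),

which makes E(IC) = 0 under exact independence (verified symbolically
in the tests).  IC025 = E(IC) − 2√V(IC) is a moment-based
approximation, not an exact posterior quantile.  Published tables in
this literature often print the *crude* bound IC − 2√V(IC) instead;
both are carried in `SignalStats` (`ic025`, `ic025_crude`), and
flagging uses the E(IC)-based bound, which is the more conservative of
the two for sparse cells.

**EBGM.**  Implemented as the raw observed/expected ratio
aN/((a+b)(a+c)) with a log-normal interval — *not* the gamma-Poisson
shrinkage estimate of full MGPS.  This is deliberate: it reproduces
the ratio form printed in the method tables this package mirrors, and
it yields the exact identity IC ≡ log₂(EBGM), which the tests exploit.
The cost is that EBGM here is unshrunk and will overstate sparse-cell
signals relative to true MGPS; the screening threshold EBGM05 > 2
absorbs some of that.  EBGM05/EBGM95 use z = 1.645 (5th/95th
percentile-style bounds): published EBGM05 values in this literature
match 1.645 rather than the 1.96 their method tables nominally state,
and the percentile convention is the field's. The z is configurable.

**Thresholds** default to: ROR ≥ 3 ∧ n ≥ 3 ∧ CI low > 1; PRR ≥ 2 ∧
n ≥ 3 ∧ CI low > 1; IC025 > 0; EBGM05 > 2.  The PRR CI condition can
be switched off (`require_prr_ci=False`) to match the text-only EMA
form of the criterion.  Comparisons are strict or inclusive exactly as
written; non-computable statistics never flag.  No multiple-testing
adjustment is applied — the screen is a threshold rule, not a test.

A corrected monotonicity property replaces the naive one: ROR and PRR
strictly increase in a with b, c, d fixed, but IC and EBGM do not
(N grows with a, driving the observed/expected ratio back toward 1);
all four strictly increase under the margin-preserving move
(a+1, b−1, c−1, d+1), which is the meaningful "more observed at the
same expected" statement.

## Reconstruction of published rows

Given a printed row (n, ROR with 95% CI, PRR), the unprinted cells
are identified: SE(lnROR) = ln(high/low)/(2·1.96), and eliminating d
between the ROR and PRR equations gives the closed form

    b = n(PRR−1)/(ROR−PRR),
    c = (1 + n/(ROR·b)) / (SE² − 1/n − 1/b),    d = ROR·b·c/n.

It requires ROR > PRR > 1 (true for any elevated pair in a large
database) and fails loudly when the printed numbers are mutually
inconsistent.  Recovered cells are real-valued; because the printed
inputs are rounded, the re-derived IC/EBGM carry that input rounding —
the acceptance test propagates each input's half-ulp box and checks
the printed output lies in its image.

## Dates, units, bins

Dates keep an explicit day/month/year precision tag; ordering for
deduplication pads missing components with 01, but onset-time
arithmetic refuses anything below day precision.  Time to onset is
event date minus the earliest day-precise therapy start among the
drug's PS rows; negative differences are unknown.  Bins: <7, 7–28,
28–60, ≥60 days, half-open at the left edge of each upper bin.

Ages convert to years (decade×10, month÷12, week÷52.18, day÷365.25),
weights to kg (lbs×0.45359237).  Age bins are half-open [low, high):
18 → 18–45, 45 → 45–65, 65 → 65–75, 75 → ≥75; the coarse subgroup set
is <18 / 18–65 / ≥65.  Percentages in the demographic summary are
taken against the full PS-case total including unknowns, and outcome
counts are per (case, outcome) pair, so the outcome section may exceed
100%.

Drug-name normalization is dictionary lookup after lowercasing,
punctuation stripping and removal of dose/form tokens — a testable
stand-in for NLP-based standardizers.  Unmapped names are flagged
`unmapped:<name>` and tallied, never silently retained; unmapped
preferred terms get organ class "unmapped".

## Synthetic-data generator

The generator emulates the *structure* of quarterly report data at
desk scale: per-case PS drug, preferred terms sampled without
replacement with probability ∝ baseline(pt) × RR(drug, pt) (Gumbel
top-k), demographics/outcomes/dates with configurable missingness, raw
drug-name spelling variants, and duplicate report versions the
cleaning stage must collapse.  Ground truth (planted RRs, case
identity, surviving version) is exported with every corpus.

Default marginals are those of a tolvaptan-like reporting world:
sex ≈ 43/44/13% F/M/unknown, 34% missing age, 78% missing weight,
reporter mix led by physicians, US/Japan-dominated countries, outcome
mix led by "other serious", and an onset model with 56% unknown mass
implemented through missing or month-precision dates.  The target
drug's share of cases is 0.15 — vastly larger than any drug's share of
the real database — so that a 200-case fixture contains enough exposed
cases to exercise every stage; this is a deliberate desk-scale
compression, and absolute counts are therefore not comparable to real
screens.  `tolvaptan_study_config()` plants elevated RRs (5–80) for
the drug's characteristic events; a frozen 200-case corpus (seed 42)
generated from it ships in `tests/data/fixture` and is byte-compared
against regeneration to catch generator drift.

Because PT probabilities renormalize after applying RR, the planted RR
multiplies the per-draw reporting probability with a small attenuation
(measured ≈ 1.5% at RR = 8 for a rare term); recovery tolerances
account for it.  What passing recovery tests show: the pipeline
recovers a planted log-RR without material bias and flags it reliably
at E[a] ≈ 50, while an all-null corpus yields no four-way flags.  What
they do not show: robustness to real-data pathologies the generator
omits — free-text drug noise beyond the variant list, reporting-trend
dynamics, correlated events within cases, stratum-confounded risks.

## Problem sizes

Validation runs use 50,000-case corpora with 20 replicates for
parameter recovery (one pair at RR = 8, baseline calibrated to
E[a] ≈ 50) and a single 50,000-case corpus for null calibration; the
brute-force oracles run on ≤ 20-case corpora and all 6⁴ tables with
cells 1..6.  These sizes were chosen so the complete suite exercises
every claim in a few minutes on one CPU.

## Known limitations

- EBGM is unshrunk (see above); rankings by EBGM on sparse cells are
  more volatile than true MGPS.
- IC025 is a moment approximation, not a posterior quantile.
- The comparator is crude: no stratum-matched expected counts, so
  subgroup tables are the only confounding control offered.
- Record linkage is by CASEID only; probabilistic duplicate detection
  across case ids is out of scope.
- The generator's duplicates are content-identical versions; real
  revisions also amend fields, which the dedup rule handles but the
  tests do not exercise.
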