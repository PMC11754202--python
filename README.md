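# faersignal

Disproportionality signal detection for FAERS-style spontaneous
adverse-event report data.

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect millions of suspected adverse drug event
reports.  Because there is no denominator of exposed patients,
pharmacovigilance screens for *disproportionality*: drug–event pairs
reported more often than independence of drug and event would predict.
`faersignal` implements that workflow end to end for anyone who needs
to screen a drug's safety profile from quarterly ASCII report tables —
or to audit someone else's published screen:

- **Ingestion** of `$`-delimited DEMO/DRUG/REAC/OUTC/THER tables with
  era-tolerant column matching, partial-date precision tags, and
  counted (never silent) row rejection.
- **Cleaning**: FDA-rule deduplication (per case id, keep the latest
  FDA receipt date, ties to the highest primaryid), dictionary-based
  drug-name normalization, preferred-term → system-organ-class coding.
- **Contingency tables** per drug–event pair at PT or SOC level,
  counting distinct (case, event) pairs, with primary-suspect (PS)
  drug membership defining the exposed arm.
- **Four algorithms** with interval bounds and screening thresholds.
- **Descriptives**: demographics, outcome frequencies, time to onset,
  concomitant medication, and demographically stratified signals.
- **Synthetic data** generation with known ground-truth relative risks,
  so every stage is testable without the multi-gigabyte download.
- **Published-row reconstruction**: recover the unprinted fourfold
  cells of a published signal table from its printed n/ROR/CI/PRR and
  re-derive its IC and EBGM — an internal-consistency audit.

## The statistics

All four algorithms screen the fourfold table for a (drug, event) pair

|              | target event | other events |
|--------------|--------------|--------------|
| target drug  | a            | b            |
| other drugs  | c            | d            |

with N = a+b+c+d and the counting unit being the distinct
(case, event) pair:

- **ROR** = (a/c)/(b/d), SE(lnROR) = √(1/a+1/b+1/c+1/d), 95% CI
  log-symmetric.  Signal: n ≥ 3, ROR ≥ 3, CI lower bound > 1.
- **PRR** = [a/(a+b)]/[c/(c+d)], SE(lnPRR) = √(1/a−1/(a+b)+1/c−1/(c+d)).
  Signal: n ≥ 3, PRR ≥ 2, CI lower bound > 1.
- **BCPNN IC** = log₂[aN/((a+b)(a+c))], with posterior moments E(IC),
  V(IC) from the Bate et al. Dirichlet priors and
  IC025 = E(IC) − 2√V(IC).  Signal: IC025 > 0.
- **EBGM** = aN/((a+b)(a+c)) — the observed/expected reporting ratio
  with a log-normal interval, so IC ≡ log₂(EBGM); EBGM05 is the
  5th-percentile-style bound.  Signal: EBGM05 > 2.

A pair that passes all four criteria simultaneously (`flag_all4`) is
reported as a signal.

## Worked example

```python
from faersignal import ContingencyTable, compute_signal

table = ContingencyTable(a=50, b=6200, c=120, d=115_000)
stats = compute_signal("hypernatraemia", "PT", table)
```

prints, via `examples/01_disproportionality_statistics.py`:

```
table: a=50 b=6200 c=120 d=115000 N=121370
ROR     7.73  (95% CI 5.55, 10.76)
PRR     7.67  (95% CI 5.52, 10.66)
IC      2.51  (IC025 1.92)
EBGM    5.71  (EBGM05 4.33)
flags: ROR=True PRR=True BCPNN=True EBGM=True all4=True
```

The event is reported ~7.7× more often with the drug than its
background odds (ROR/PRR), is 5.7× over-expected (EBGM, = 2^IC), and
every lower uncertainty bound clears its threshold — a four-way
signal.  The other `examples/` scripts cover the synthetic end-to-end
pipeline, published-row reconstruction, and descriptive/subgroup
analyses; each prints what the numbers mean.  The same pipeline is
scriptable from the shell:

```bash
faersignal synth --out corpus --n-cases 5000 --seed 1
faersignal all --demo corpus/demo.txt --drug-file corpus/drug.txt \
    --reac corpus/reac.txt --outc corpus/outc.txt --ther corpus/ther.txt \
    --drug tolvaptan --map corpus/pt_soc_map.csv \
    --dictionary src/faersignal/data/tolvaptan_synonyms.csv --out results/
```

## Layout

```
src/faersignal/     library (io, cleaning, contingency, signals,
                    reconstruct, descriptives, synthetic, pipeline, cli)
examples/           narrative scripts, one per capability
tests/              pytest suite incl. end-to-end acceptance checks
docs/methods.md     models, assumptions, parameter choices, limitations
```
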