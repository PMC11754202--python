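"""Descriptive surfaces: demographics, onset time, concomitant drugs,
and age-stratified signals on a synthetic corpus."""

from faersignal import (assemble_reports, concomitant_frequency, deduplicate,
                        subgroup_signals, summarize, tolvaptan_study_config,
                        top_events_by_outcome)
from faersignal.synthetic import default_drug_dictionary, generate

cfg = tolvaptan_study_config(n_cases=3000, seed=2)
corpus = generate(cfg)
reports, _ = assemble_reports(corpus.data, cfg.pt_soc_map(),
                              default_drug_dictionary(),
                              demos=deduplicate(corpus.data.demo))

summary = summarize(reports, "tolvaptan")
print("onset-time bins (days from therapy start to event):")
print(summary[summary.section == "onset"].to_string(index=False))

print("\ntop events among death cases:")
for pt, count in top_events_by_outcome(reports, "tolvaptan", "death", k=5):
    print(f"  {pt:40s} {count}")

print("\nmost frequent concomitant drugs:")
for drug, count in concomitant_frequency(reports, "tolvaptan", k=5):
    print(f"  {drug:40s} {count}")

print("\nper-age-stratum top signal (all arms restricted to the stratum):")
for stratum, rows in subgroup_signals(reports, "tolvaptan",
                                      "age_coarse", "PT").items():
    top = rows[0]
    print(f"  {stratum:8s} {top.event:32s} n={top.n:3d} "
          f"ror={top.ror:7.2f} all4={top.flag_all4}")

# Onset bins and the unknown mass mirror the structure of real
# spontaneous-report data, where over half the reports lack a usable
# therapy-start or event date.
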