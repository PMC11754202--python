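"""Compute all four disproportionality statistics for one fourfold table.

A fourfold table counts distinct (case, event) pairs: a = cases with
the target drug and target event, b = other events among target-drug
cases, c/d = the same split among all other cases.
"""

from faersignal import ContingencyTable, compute_signal

# A strongly elevated pair: 50 target-event cases among ~6,000 pairs in
# the drug arm, against a background rate about 8x lower.
table = ContingencyTable(a=50, b=6200, c=120, d=115_000)
stats = compute_signal("hypernatraemia", "PT", table)

print(f"table: a={table.a} b={table.b} c={table.c} d={table.d} N={table.n_total}")
print(f"ROR  {stats.ror:7.2f}  (95% CI {stats.ror_ci_low:.2f}, {stats.ror_ci_high:.2f})")
print(f"PRR  {stats.prr:7.2f}  (95% CI {stats.prr_ci_low:.2f}, {stats.prr_ci_high:.2f})")
print(f"IC   {stats.ic:7.2f}  (IC025 {stats.ic025:.2f})")
print(f"EBGM {stats.ebgm:7.2f}  (EBGM05 {stats.ebgm05:.2f})")
print(f"flags: ROR={stats.flag_ror} PRR={stats.flag_prr} "
      f"BCPNN={stats.flag_bcpnn} EBGM={stats.flag_ebgm} all4={stats.flag_all4}")

# ROR/PRR measure how over-reported the pair is relative to the rest of
# the database; IC and EBGM express the same observed/expected ratio on
# log2 and natural scales (IC == log2(EBGM)).  flag_all4 means the pair
# passes every screening threshold simultaneously - a "signal".
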