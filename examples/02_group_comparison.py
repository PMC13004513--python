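"""Compare survival between cohorts with the log-rank test.

A single continuous marker ("marker") with a strong effect (beta = 0.9) is
median-split into low/high groups; we then ask whether the two Kaplan-Meier
curves differ more than chance would allow. The same workflow is available
as a one-call pipeline (see pipeline_km_compare), but here each stage is run
by hand so the intermediate objects are visible.
"""

import survflow as sf
from survflow.simulate import SimulationConfig, simulate_ph_dataset

ds, _ = simulate_ph_dataset(
    SimulationConfig(
        n=240,
        beta=(0.9,),
        feature_names=("marker",),
        target_censoring_fraction=0.25,
        seed=20240902,
    )
)

# Median split: subjects strictly below the sample median are "low",
# at-or-above are "high".
rule = sf.StratificationRule("marker", mode="median")
strat = sf.stratify(ds, rule)

curves = sf.km_by_group(strat)
for label, c in curves.items():
    med = "not reached" if c.median_survival is None else f"{c.median_survival:.2f}"
    print(f"group {label!r}: n={c.n_total}, events={c.n_events_total}, "
          f"median survival = {med}")

res = sf.logrank_test(strat)
print(f"\nlog-rank: chi2={res.chi_square:.2f} on {res.degrees_of_freedom} df, "
      f"p={res.p_value:.2e}")
if res.p_value < 0.05:
    print("the two groups' survival experiences differ at the 5% level, "
          "as expected for a marker with a true log hazard ratio of 0.9")

# With three or more groups, pairwise_logrank gives every pairwise test with
# Bonferroni-adjusted p-values:
rule3 = sf.StratificationRule("marker", mode="quantile", quantile_count=3)
strat3 = sf.stratify(ds, rule3)
pw = sf.pairwise_logrank(strat3)
print("\ntertile pairwise comparisons (Bonferroni-adjusted):")
for (a, b), p_adj in zip(pw.pairs, pw.p_adjusted):
    print(f"  {a} vs {b}: adjusted p = {p_adj:.3g}")
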