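"""Class-wise and per-position comparison of cfDNA-like vs gDNA-like samples.

Runs the full comparison stack on a simulated 10 kb panel: Welch t-tests per
substitution class (Bonferroni-corrected), per-position tests with a hit
list, and re-profiling after excluding the hit positions.
"""

from bgerr.synthetic import cfdna_counts_preset, gdna_counts_preset, simulate_counts
from bgerr.workflow import RunManifest, run_compare, run_profile

cf = cfdna_counts_preset(panel_bp=10_000, n_samples=5)
g = gdna_counts_preset(panel_bp=10_000, n_samples=5)
dataset = simulate_counts(cf, g, seed=17)

run = run_profile(RunManifest.from_simulated(dataset))
result = run_compare(run)

print("class-wise comparison (adjusted p < 0.01 flags):")
cols = ["class", "mean_cfDNA", "mean_gDNA", "t", "p_adj", "significant"]
print(result.class_comparison[cols].to_string(index=False,
                                              float_format="{:.3g}".format))

hits = result.position_hits
print(f"\nper-position tests: {hits.n_hits} significant positions out of "
      f"{sum(hits.n_tested.values())} tested "
      f"({100 * hits.fraction:.2f}%), by reference base: {hits.n_tested}")

total_delta = result.reprofile_deltas.query("`class` == 'total'")
print("\ntotal-rate change after excluding hit positions (per sample):")
print(total_delta[["sample_id", "rate_before", "rate_after", "rel_change"]]
      .to_string(index=False, float_format="{:.3g}".format))

print("\nOnly C>T and G>A (collapsed: C:G>T:A) separate the groups — the "
      "planted deamination excess is position-independent, so excluding the "
      "handful of position-level hits barely moves the totals.")
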