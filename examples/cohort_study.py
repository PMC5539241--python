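"""Simulate the six-group graded-atherosclerosis cohort and analyse it.

Groups 0-5 carry increasing latent vasa-vasorum density (control, 4/8/12
weeks of high-fat diet, small plaque, near-occlusive plaque).  Each animal
gets a cine loop driven by that density plus two-observer CD31/VEGF
microvessel counts from a Poisson link to the same density.  The pipeline
quantifies normalized MVE per animal (the occlusive group has no usable
luminal reference and is histology-only) and the report runs one-way ANOVA,
Dunnett-T3 pairwise contrasts against the control, and Pearson correlations
of normalized MVE against each marker count.
"""

from ceusvv import default_cohort_config, group_comparison_report, simulate_cohort

config = default_cohort_config(n_per_group=10, seed=7)
sim = simulate_cohort(config, render="frames")
print(f"simulated {len(sim.cohort)} animals; "
      f"{sim.cohort['nmve'].isna().sum()} histology-only (occlusive plaque)")

report = group_comparison_report(sim.cohort, control_group=0)
print("\nnormalized MVE by group (mean +/- SD):")
for _, row in report.summaries.query("variable == 'nmve'").iterrows():
    print(f"  group {int(row.group_id)}:  {row['mean']:.3f} +/- {row['sd']:.3f}  (n={int(row.n)})")

omni = report.omnibus["nmve"]
print(f"\none-way ANOVA across groups: F = {omni.statistic:.2f}, "
      f"p = {omni.p_value:.2e}")

print("\nDunnett T3 vs control (normalized MVE):")
vs_ctrl = report.pairwise.query("variable == 'nmve' and vs_control")
for _, row in vs_ctrl.iterrows():
    print(f"  group {row.group_a} vs {row.group_b}:  "
          f"T3 = {row.statistic:6.3f}, adjusted p = {row.p_adjusted:.4g}")

print("\ncorrelation of normalized MVE with histology counts:")
for _, row in report.correlations.iterrows():
    print(f"  {row.marker:10s} r = {row.r:.3f}  (n={int(row.n)}, p = {row.p_value:.2e})")
print("\nEnhancement rises with disease stage and tracks microvessel counts,")
print("the pattern the imaging statistic is designed to capture.")
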