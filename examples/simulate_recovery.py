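"""Synthetic-cohort round trip: generate, run the pipeline, recover truth.

Simulates 500 variants with known classes, evidence sets consistent with
those classes, paired SGE categories with 20% forced discordance, and
lognormal LR components, then checks what the pipeline recovers.
"""

from sgecurate import CohortConfig, recovery_report, run_pipeline, simulate_cohort

config = CohortConfig(n_variants=500, sge_discordance_rate=0.2, sge_error_rate=0.0, seed=1)
records, truth = simulate_cohort(config)
result = run_pipeline(records)
report = recovery_report(records, truth, result)

print(f"observed discordant fraction: {report['discordant_fraction']:.3f} (injected 0.2)")
print(f"truth-pathogenic variants with combined LR > 1: {report['lr_separation']['pathogenic_gt1']:.1%}")
print(f"truth-benign variants with combined LR < 1:     {report['lr_separation']['benign_lt1']:.1%}")
print("\nconfusion matrix (rows: true class, columns: post-integration class):")
print(report["confusion"])
# With no per-dataset corruption the discordant fraction tracks the
# injected rate, the LR groups separate almost perfectly, and definitive
# classes are never pushed to the opposite side of the scale.
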