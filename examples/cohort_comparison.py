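"""Compare single- vs multi-frequency alarm counts on a simulated cohort.

Simulates 20 trauma-free insertions (tonotopic passages plus hair-cell-patch
transits only), scores each with both monitoring schemes, and prints the
per-subject comparison table — the same arithmetic the published 10-subject
reference table reports (means 2.8 vs 0.5 alarms per subject).
"""

import ecochg_monitor as em

config = em.RunConfig()
template = em.InsertionScenario(noise_sigma=0.02)
cohort = em.generate_cohort(20, trauma_rate=0.0, patch_rate=1.0, seed=5,
                            template=template)

single, multi = {}, {}
for i, (bundle, _) in enumerate(cohort):
    name = f"S{i + 1}"
    single[name] = em.single_freq_baseline(bundle, config, subject=name)
    multi[name] = em.run_monitor(bundle, config, subject=name)

summary = em.compare_alarms(single, multi)
print(summary)
print("\nNo trauma was injected: every multi-frequency alarm would be a false")
print("positive. The single-frequency column counts amplitude-only drop")
print("alarms (passages and patches included).")

print("\npublished 10-subject reference counts:")
print(em.summary_from_counts(em.REFERENCE_COHORT_COUNTS))
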