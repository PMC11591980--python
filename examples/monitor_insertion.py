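"""Simulate one electrode insertion with a trauma event and monitor it.

Builds a synthetic insertion in which the electrode advances past all four
characteristic places and suffers one traumatic event at t = 30 s, then runs
both the multi-frequency monitor and the conventional single-frequency
(≈500 Hz) amplitude-only baseline over the same tracings.
"""

import ecochg_monitor as em

scenario = em.InsertionScenario(
    noise_sigma=0.02,
    seed=11,
    events=(em.TraumaEvent(t=30.0, drop_db=10.0, phase_jump_rad=3.5),),
)
bundle, truth = em.simulate_insertion(scenario)
config = em.RunConfig()

log = em.run_monitor(bundle, config)
print("multi-frequency monitor:")
for c in log.classifications:
    freqs = ",".join(f"{f:.0f}" for f in c.group.frequencies)
    print(f"  t={c.t:5.1f}s  {c.label.value:18s} frequencies={freqs} Hz")
print(f"  trauma alarms: {log.n_alarms}")

baseline = em.single_freq_baseline(bundle, config)  # uses the 507 Hz tracing
print(f"single-frequency baseline alarms: {len(baseline.classifications)}")

print("\nground truth: trauma at t=30.0 s; place crossings at "
      + ", ".join(f"{f:.0f} Hz @ {t:.1f}s" for f, t in truth.crossings))
print("Each tonotopic passage (drop + ~180° phase reversal on one frequency)")
print("alarms the baseline but is recognized as non-traumatic by the")
print("multi-frequency rules; only the correlated drop with a large phase")
print("shift on >2 frequencies raises the trauma alarm.")
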