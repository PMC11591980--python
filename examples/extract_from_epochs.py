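"""Extract CM amplitude and phase from raw multi-tone epochs.

Renders raw waveform epochs for a short noiseless insertion, extracts one
amplitude/phase frame per epoch per stimulus tone by FFT at the exact tone
bins, and verifies the extraction against the simulator's ground-truth
tracings and the independent quadrature-demodulation cross-check.
"""

import numpy as np

import ecochg_monitor as em

scenario = em.InsertionScenario(duration=20.0)
truth_bundle, _ = em.simulate_insertion(scenario)
epochs = em.render_epochs(scenario)
bundle = em.build_bundle(epochs, scenario.stimulus, noise_floor_uv=0.05)

print(f"{len(epochs)} epochs of {scenario.stimulus.epoch_duration} s at "
      f"{scenario.stimulus.sample_rate:.0f} Hz")
print("frame 10 extraction (amplitude µV / phase rad):")
for tone in scenario.stimulus.tones:
    tr = bundle.tracing(tone.frequency)
    a_q, p_q = em.quadrature_demodulate(epochs[10], tone.frequency)
    print(f"  {tone.frequency:6.0f} Hz: FFT {tr.amplitude[10]:7.4f} / "
          f"{tr.phase[10]:+7.4f}   quadrature {a_q:7.4f} / {p_q:+7.4f}")

err = max(
    float(np.max(np.abs(bundle.tracing(f).amplitude
                        - truth_bundle.tracing(f).amplitude)))
    for f in scenario.stimulus.frequencies
)
print(f"max |extracted - simulated| amplitude: {err:.2e} µV")
print("FFT at bin-aligned tones recovers the generating amplitudes exactly;")
print("the quadrature path is an independent check of the same measurement.")
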