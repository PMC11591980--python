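# Methods

## Signal model and extraction

Each recording epoch (default 1.0 s at 22050 Hz) contains all stimulus tones
simultaneously. Tone frequencies must be integer cycles per epoch
(bin-aligned), so the rectangular-window DFT evaluated at a tone's exact bin
k = f·T recovers its amplitude and phase without leakage:
amplitude = 2|X_k|/N (µV), phase = arg(X_k) (rad, wrapped to (−π, π]).
The default tones 2011/1015/507/253 Hz are integer bins at 1 s epochs, are
pairwise non-harmonic (so distortion products of one tone cannot land on
another's bin), and no window function is applied — with bin-aligned tones a
rectangular window is exact, which is the point. The phase convention means a
pure sine A·sin(2πft) reports −π/2; only phase *differences* enter any
decision, so the convention is free once synthesis and analysis share it.

A quadrature-demodulation path (explicit cosine/sine dot products per tone)
implements the same measurement independently and is used purely as a
cross-check; tests require agreement with the FFT path to 1e-9 relative.

Amplitudes below `noise_floor_uv` (default 0.05 µV) are flagged: phase is
meaningless at the noise floor, so flagged frames neither trigger detection
nor contribute to phase statistics. This is also why the method degrades for
ears with little residual hearing — with no measurable CM nothing can be
monitored.

## Detection

Tracings are smoothed with a centered moving average (`smoothing_frames`,
default 3, odd; shrunken windows at the edges) before detection. A drop event
on one frequency fires when amplitude in dB (20·log10(a/1 µV)) falls at least
`drop_threshold_db` (default 6) below the running maximum since the last
emitted event on that frequency. The reference is the best-yet response
because CM rises toward each characteristic place; it resets after each
emission so a recovered signal can alarm again, and a per-frequency
refractory period (default 2 s) keeps one continuous decline from spawning an
event per frame. Lowering the threshold never removes an event, and dB ratios
make detection invariant to amplitude rescaling.

The phase shift attached to an event is the difference of window means of
*raw* (unsmoothed) unwrapped phase — the windows provide the averaging. The
post-drop window starts one smoothing window after the detection frame:
detection lags the raw amplitude fall by up to a smoothing window while the
phase change is still developing, so sampling immediately at detection would
read a half-completed transition (e.g. ~3.1 rad of a 3.5 rad trauma jump).
The pre-peak baseline ends a guard of one smoothing window before the peak
frame, keeping it clear of the reversal that straddles the peak itself and of
peak-time jitter under noise; when the running maximum sits at the very start
of the record (a flat tracing has no meaningful peak) the baseline anchors
before the drop instead. Unwrapping is computed over the non-flagged frames
only; if either window contains no valid frame the shift is indeterminate and
the event is low-confidence.

Coincident drops are grouped greedily in time order: each ungrouped drop
anchors a group absorbing later drops (one per frequency, earliest first)
within `coincidence_window_s` (default 2 s — a few epochs; the source rules
require drops to be "correlated" across frequencies without quantifying a
window). The grouping is a partition and is deterministic under ties.

## Decision rules

Evaluated in order on each group (n_large = member events whose shift passes
the large-shift test, n_small = determinate shifts that fail it):

1. |group| ≥ `min_freqs_for_trauma` (default 3, "more than two" of four) and
   n_large ≥ that count → **TRAUMA_ALARM**;
2. |group| ≥ that count and all member shifts determinate-and-small →
   **HAIR_CELL_PATCH** (no alarm);
3. singleton with a large shift → **TONOTOPIC_PASSAGE** (no alarm);
4. everything else → **AMBIGUOUS** (no alarm, logged). This includes
   two-frequency groups — the source rules address "more than 2" and "fewer
   than two" frequencies but not exactly two — and groups dominated by
   indeterminate phase. Alarming here would defeat the false-positive goal;
   discarding silently would hide information.

The large-shift test is inclusive (shift ≥ π counts) and allows a margin
`phase_tolerance_rad` (default 0.15 rad ≈ 8.6°) below the 180° threshold.
The margin exists because the canonical tonotopic reversal is *exactly* π,
i.e. exactly on the threshold: any unbiased measurement of it under noise
falls below π about half the time, so a hard inequality would misclassify
half of all clean passages. 0.15 rad is large against the phase-noise scale
of a healthy CM (floor/amplitude ≈ 0.004–0.04 rad per frame) and small
against the patch-vs-reversal contrast (≤0.3 rad vs π).

`koka_mode` restores the older single-frequency convention (drop without
phase change is itself traumatic) for comparison studies; it is off by
default.

Classification is a pure function of group and configuration. The online
monitor buffers frames and emits each classification once its coincidence
window has closed, its members' smoothed values are final (the centered
smoother needs half a window of lookahead) and their post-drop phase windows
are complete — a worst-case latency of the coincidence window plus about two
smoothing windows after the triggering frame. Online and batch processing
are bitwise identical on labels and times (tested property).

The single-frequency baseline applies the same drop detector to the tracing
nearest 500 Hz (507 Hz with the default stimulus) and alarms on every event,
phase ignored — the comparison condition the multi-frequency rules are
evaluated against.

## Simulator

The simulator is pattern-level, not biophysical. The frequency→place map is
the Greenwood function F(x) = A(10^{a·x} − k), A = 165.4 Hz, a = 2.1 per
normalized length, k = 0.88 (standard human constants; any monotone map would
do for the classifier). Places are expressed as insertion depth from the
base (depth = 1 − place-from-apex), so a monotone advance crosses high
frequencies first, matching real tracings. Per frequency the noise-free
amplitude is peak_amp · max(basal_tail, exp(−(d(t) − d_f)²/2σ²)) with
σ = `peak_width` = 0.08 and `basal_tail` = 0.15 — the simplest shape giving
both the rise-peak-fall of a passage and a non-zero floor on which patch
transits are visible. The phase reverses by exactly π across each crossing.

Injected events: trauma multiplies all subsequent amplitudes by
10^(−drop_db/20) (default 10 dB) and adds a persistent phase jump (default
3.5 rad); a patch applies the same attenuation over a finite span (defaults
8 dB, 6 s) with a small phase wobble (0.3 rad) that reverts. Event phase
transitions ramp linearly over `transition_frames` (default 3) frames:
unwrapping can only track inter-frame steps below π, so an instantaneous
3.5 rad jump would alias to 2π − 3.5 ≈ 2.78 rad for *any* analysis method;
physically the ramp models a change developing over a couple of seconds.

Noise: multiplicative log-normal amplitude noise with σ = `noise_sigma`
(fraction of signal; 0 disables all noise) plus an additive half-normal floor
(`floor_noise_uv` = 0.02 µV). Phase noise has standard deviation
floor/amplitude — an additive disturbance of std u on a tone of amplitude A
perturbs its extracted phase by ~u/A rad, whereas multiplicative gain noise
leaves phase untouched — so phase is clean on strong responses and unreliable
near the floor, which exercises the below-floor handling.

`render_epochs` synthesizes the raw waveforms (cosine convention, plus white
noise at σ > 0); extract∘render reproduces the simulated tracings to ~1e-12
at zero noise. `generate_cohort` draws per-subject Poisson event counts with
times uniform over the central 10–85% of the insertion (so detection and
phase windows fit inside the recording) and derives per-subject seeds from
one master seed.

What the simulator does **not** capture: real CM tracings show multiple local
maxima and richer structure than the single-peak tuning model; electrode
geometry, scala position and contact impedance are absent; epoch averaging
counts and vendor-specific acquisition details are unknown and not modeled.
Passing tests on synthetic data therefore demonstrates that the decision
logic is correct for the canonical patterns and robust to the modeled noise —
not clinical validity, which requires CT-correlated outcome data.

## Problem sizes and notable behaviors

Validation scenarios use 80-frame (80 s) insertions, 20 seeds per noise level
{0, 2%, 5%} for the canonical patterns, a 50-subject trauma-free cohort for
the alarm-reduction comparison, and 200 seeded runs for trauma sensitivity.
Sensitivity lands at 97–99%, not 100%: the misses occur when the trauma
coincides with a place crossing, where the concurrent steep tonotopic rise
partially masks the amplitude step on the rising frequency and splits the
coincidence group — a genuine physical confound, not a detector artifact.
The post-passage decline re-triggers the drop detector once per passage
(~10 dB of decline remains below the reset reference before the basal-tail
floor); those singleton small-shift events are logged AMBIGUOUS and never
alarm.

## File formats

Tracings interchange as CSV (`t_s,freq_hz,amplitude_uv,phase_rad`, one row
per frame × frequency, phases wrapped to (−π, π], values at 9 significant
digits so write→read→write is byte-identical); configuration as flat JSON
with `RunConfig` field names (unknown keys warn, invalid values error); raw
epochs as float32 WAV with a JSON sidecar giving the µV full scale; alarm
logs as JSON lines. Amplitude units are µV throughout — the conventional
ECochG scale; conversion from vendor units is the caller's job.
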