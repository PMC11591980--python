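"""Multi-tone stimulus composition and CM amplitude/phase extraction.

Each recording epoch is a fixed-duration waveform acquired from the apical
electrode while all stimulus tones play simultaneously.  Because every tone
frequency is an integer number of cycles per epoch (bin-aligned), a
rectangular-window DFT evaluated at the tone's exact bin recovers the tone
amplitude and phase with no spectral leakage:

    amplitude = 2 |X_k| / N,    phase = arg(X_k),

where ``X_k`` is the DFT coefficient at bin ``k = f · epoch_duration``.  Under
this convention a pure sine ``A·sin(2πft)`` reports phase ``-π/2`` and a pure
cosine ``A·cos(2πft + φ)`` reports ``φ``; the classifier only ever uses phase
*changes*, so any fixed convention works as long as synthesis and analysis
agree.

:func:`quadrature_demodulate` implements the same measurement as explicit
dot products with cosine/sine references.  It is retained as an independent
cross-check of the FFT path (the two must agree to ~1e-9 relative on
noiseless input) and is never used by the pipeline itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.io import wavfile

from .tracing_io import (
    CMTracing,
    StimulusSet,
    TracingBundle,
    wrap_phase,
)

__all__ = [
    "EpochRecord",
    "CMEstimate",
    "compose_stimulus",
    "extract_cm",
    "quadrature_demodulate",
    "build_bundle",
    "unwrap_phase",
    "smooth_tracing",
    "smooth_bundle",
    "write_epochs_wav",
    "read_epochs_wav",
]


@dataclass
class EpochRecord:
    """One recorded epoch: waveform in µV, its sample rate, and start time."""

    samples: np.ndarray
    sample_rate: float
    t_start: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("epoch waveform must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def matches(self, stimulus: StimulusSet) -> bool:
        """Epoch length equals the stimulus epoch duration within one sample."""
        return abs(len(self.samples) - stimulus.n_epoch_samples) <= 1


class CMEstimate(NamedTuple):
    """Extraction result for one tone of one epoch."""

    frequency: float
    amplitude: float  # µV
    phase: float      # rad, wrapped to (-π, π]
    below_floor: bool


def _tone_bin(frequency: float, n: int, sample_rate: float) -> int:
    k = frequency * n / sample_rate
    if abs(k - round(k)) > 1e-6:
        raise ValueError(
            f"{frequency} Hz is not representable at length {n} / rate {sample_rate}"
        )
    k = int(round(k))
    if not 0 < k < n / 2:
        raise ValueError(f"{frequency} Hz out of analyzable range for n={n}")
    return k


def compose_stimulus(
    stimulus: StimulusSet,
    amplitudes: Sequence[float] | None = None,
) -> np.ndarray:
    """Render one epoch of the multi-tone stimulus.

    The waveform is the sample-wise sum of ``a_i · sin(2π f_i t + φ_i)`` over
    the stimulus tones; ``amplitudes`` defaults to 1.0 per tone (tone level is
    nominal metadata and is not applied numerically).  An empty tone list
    yields silence.
    """
    n = stimulus.n_epoch_samples
    t = np.arange(n) / stimulus.sample_rate
    if amplitudes is None:
        amplitudes = [1.0] * len(stimulus.tones)
    if len(amplitudes) != len(stimulus.tones):
        raise ValueError("one amplitude per tone required")
    wave = np.zeros(n)
    for tone, a in zip(stimulus.tones, amplitudes):
        _tone_bin(tone.frequency, n, stimulus.sample_rate)  # bin-alignment check
        wave += a * np.sin(2 * np.pi * tone.frequency * t + tone.phase_offset)
    return wave


def extract_cm(
    epoch: EpochRecord,
    stimulus: StimulusSet,
    noise_floor_uv: float = 0.0,
) -> list[CMEstimate]:
    """Extract CM amplitude (µV) and phase (rad) at each stimulus tone by FFT.

    Amplitudes below ``noise_floor_uv`` are flagged and their phase is
    reported as 0 (phase is meaningless at the noise floor).
    """
    if not epoch.matches(stimulus):
        raise ValueError(
            f"epoch length {len(epoch.samples)} does not match stimulus "
            f"epoch of {stimulus.n_epoch_samples} samples"
        )
    n = len(epoch.samples)
    spectrum = np.fft.rfft(epoch.samples)
    out = []
    for tone in stimulus.tones:
        k = _tone_bin(tone.frequency, n, epoch.sample_rate)
        coeff = spectrum[k]
        amplitude = 2.0 * abs(coeff) / n
        if amplitude < noise_floor_uv or amplitude == 0.0:
            out.append(CMEstimate(tone.frequency, amplitude, 0.0, True))
        else:
            out.append(
                CMEstimate(tone.frequency, amplitude,
                           float(wrap_phase(np.angle(coeff))), False)
            )
    return out


def quadrature_demodulate(
    epoch: EpochRecord, frequency: float
) -> tuple[float, float]:
    """Amplitude and phase at one frequency via explicit quadrature dot products.

    Independent of the FFT path: projects the waveform onto cosine and sine
    references at the target frequency.  Returns ``(amplitude_uv, phase_rad)``
    with the same phase convention as :func:`extract_cm`.
    """
    x = epoch.samples
    n = len(x)
    _tone_bin(frequency, n, epoch.sample_rate)
    t = np.arange(n) / epoch.sample_rate
    c = 2.0 / n * float(np.dot(x, np.cos(2 * np.pi * frequency * t)))
    s = 2.0 / n * float(np.dot(x, np.sin(2 * np.pi * frequency * t)))
    # x = A·cos(2πft+φ) gives c = A·cosφ, s = -A·sinφ.
    return float(np.hypot(c, s)), float(wrap_phase(np.arctan2(-s, c)))


def build_bundle(
    epochs: Sequence[EpochRecord],
    stimulus: StimulusSet,
    noise_floor_uv: float = 0.0,
    meta: dict | None = None,
) -> TracingBundle | None:
    """Extract every epoch and assemble the per-frequency tracings.

    One frame per epoch; the frame time is the epoch midpoint.  Epochs must be
    time-ordered, non-overlapping, and share one sample rate.  Returns ``None``
    for an empty epoch list (there is nothing to trace).
    """
    if not epochs:
        return None
    rate = epochs[0].sample_rate
    prev_end = -np.inf
    frames = []
    times = []
    for ep in epochs:
        if ep.sample_rate != rate:
            raise ValueError("all epochs must share one sample rate")
        if ep.t_start < prev_end - 1e-9:
            raise ValueError("epochs must be time-ordered and non-overlapping")
        prev_end = ep.t_start + ep.duration
        frames.append(extract_cm(ep, stimulus, noise_floor_uv))
        times.append(ep.t_start + ep.duration / 2.0)
    t = np.asarray(times)
    tracings = []
    for j, tone in enumerate(stimulus.tones):
        tracings.append(
            CMTracing(
                tone.frequency,
                t,
                np.array([fr[j].amplitude for fr in frames]),
                np.array([fr[j].phase for fr in frames]),
                np.array([fr[j].below_floor for fr in frames]),
            )
        )
    return TracingBundle(tuple(tracings), meta=dict(meta or {}), stimulus=stimulus)


def unwrap_phase(phases) -> np.ndarray:
    """Unwrap a time-ordered phase sequence.

    Successive differences of the output lie in ``(-π, π]`` and the output is
    congruent to the input modulo 2π.  Correct whenever the true inter-frame
    phase step is below π in magnitude; larger true steps alias (fundamental
    limit of any unwrapping).
    """
    return np.unwrap(np.asarray(phases, dtype=float))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrunken windows at the edges."""
    n = len(x)
    if n == 0:
        return x.copy()
    h = window // 2
    cs = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def smooth_tracing(tracing: CMTracing, window: int) -> CMTracing:
    """Centered moving average over amplitude and unwrapped phase.

    ``window`` must be odd and >= 1; edges use shrunken windows so the time
    grid is unchanged.  The smoothed phase is stored re-wrapped; below-floor
    flags pass through untouched.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    if window == 1 or len(tracing) == 0:
        return CMTracing(tracing.frequency, tracing.t.copy(),
                         tracing.amplitude.copy(), tracing.phase.copy(),
                         None if tracing.below_floor is None
                         else tracing.below_floor.copy())
    amp = _moving_average(tracing.amplitude, window)
    ph = wrap_phase(_moving_average(unwrap_phase(tracing.phase), window))
    return CMTracing(tracing.frequency, tracing.t.copy(), amp, ph,
                     None if tracing.below_floor is None
                     else tracing.below_floor.copy())


def smooth_bundle(bundle: TracingBundle, window: int) -> TracingBundle:
    return TracingBundle(
        tuple(smooth_tracing(tr, window) for tr in bundle.tracings),
        dict(bundle.meta),
        bundle.stimulus,
    )


# --------------------------------------------------------------------------
# raw-epoch WAV I/O
#
# One float32 WAV per insertion, epochs back to back; a JSON sidecar
# ``<name>.json`` records {"fullscale_uv": ...} so sample values map to µV.


def write_epochs_wav(epochs: Sequence[EpochRecord], path, fullscale_uv: float | None = None) -> None:
    """Concatenate epochs into a float32 WAV plus a µV-fullscale sidecar JSON."""
    path = Path(path)
    if not epochs:
        raise ValueError("no epochs to write")
    rate = epochs[0].sample_rate
    data = np.concatenate([ep.samples for ep in epochs])
    if fullscale_uv is None:
        peak = float(np.max(np.abs(data)))
        fullscale_uv = peak if peak > 0 else 1.0
    wavfile.write(path, int(round(rate)), (data / fullscale_uv).astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"fullscale_uv": fullscale_uv,
                    "epoch_duration_s": epochs[0].duration,
                    "t_start_s": epochs[0].t_start}),
        encoding="utf-8",
    )


def read_epochs_wav(path, epoch_duration: float | None = None) -> list[EpochRecord]:
    """Split an insertion WAV back into µV epochs using its sidecar JSON."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    if epoch_duration is None:
        epoch_duration = float(meta["epoch_duration_s"])
    rate, data = wavfile.read(path)
    if data.dtype.kind == "i":  # PCM int -> full-scale normalized
        data = data.astype(float) / np.iinfo(data.dtype).max
    data = np.asarray(data, dtype=float) * float(meta["fullscale_uv"])
    n_epoch = int(round(epoch_duration * rate))
    t0 = float(meta.get("t_start_s", 0.0))
    epochs = []
    for i in range(len(data) // n_epoch):
        epochs.append(
            EpochRecord(data[i * n_epoch:(i + 1) * n_epoch], float(rate),
                        t0 + i * epoch_duration)
        )
    return epochs
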