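"""Domain types and on-disk formats for cochlear-microphonic (CM) tracings.

During cochlear implant electrode insertion, the most apical electrode is used
as an intracochlear electrocochleography sensor while a multi-tone acoustic
stimulus (up to four pure tones) is presented.  Each recording epoch yields one
CM amplitude (µV) and phase (rad) estimate per stimulus frequency; the
time-ordered sequence of those estimates is a *tracing*, and the time-aligned
set of tracings across all stimulus frequencies is a :class:`TracingBundle` —
the unit the monitoring pipeline consumes.

On-disk interchange formats (all plain text):

* tracing CSV — header ``t_s,freq_hz,amplitude_uv,phase_rad``, one row per
  (frame, frequency), ``.`` decimal separator, LF line endings;
* run configuration — a flat JSON object with :class:`RunConfig` field names.

Phases are stored wrapped to ``(-π, π]``; unwrapping is always recomputed in
memory (see :func:`ecochg_monitor.cm_extraction.unwrap_phase`).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TWO_PI",
    "wrap_phase",
    "ToneSpec",
    "StimulusSet",
    "CMSample",
    "CMTracing",
    "TracingBundle",
    "RunConfig",
    "TracingFormatError",
    "read_tracing_csv",
    "write_tracing_csv",
    "load_config",
]

TWO_PI = 2.0 * math.pi

#: Relative tolerance used when checking that a tone frequency sits exactly on
#: a DFT bin (frequency × epoch_duration must be an integer).
_BIN_RTOL = 1e-9


def wrap_phase(phase):
    """Wrap angles to the storage convention ``(-π, π]``.

    Accepts scalars or arrays; ``-π`` maps to ``+π`` so the interval is
    half-open on the left, matching how phases are serialized.
    """
    return math.pi - np.mod(math.pi - np.asarray(phase, dtype=float), TWO_PI)


class TracingFormatError(ValueError):
    """A tracing file violates the CSV dialect or a bundle invariant."""


@dataclass(frozen=True)
class ToneSpec:
    """One pure tone of the multi-tone stimulus.

    ``level_db`` is the nominal presentation level and is informational only;
    waveform amplitudes are specified explicitly where stimuli are composed.
    """

    frequency: float
    level_db: float = 70.0
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"tone frequency must be positive, got {self.frequency}")
        if not (0.0 <= self.phase_offset < TWO_PI):
            raise ValueError(
                f"phase_offset must lie in [0, 2π), got {self.phase_offset}"
            )


@dataclass(frozen=True)
class StimulusSet:
    """A simultaneous multi-tone stimulus and its acquisition parameters.

    All tone frequencies must be integer multiples of ``1/epoch_duration``
    (bin-aligned, so rectangular-window FFT extraction recovers amplitudes
    exactly) and no tone may be an integer multiple of another (keeps harmonic
    distortion products out of the analysis bins).  Tone order is preserved as
    given.  An empty tone list is permitted and composes silence, but a
    :class:`TracingBundle` always carries at least one tracing.
    """

    tones: tuple[ToneSpec, ...]
    epoch_duration: float = 1.0
    sample_rate: float = 22050.0
    max_tones: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "tones", tuple(self.tones))
        if len(self.tones) > self.max_tones:
            raise ValueError(
                f"at most {self.max_tones} simultaneous tones, got {len(self.tones)}"
            )
        if self.epoch_duration <= 0 or self.sample_rate <= 0:
            raise ValueError("epoch_duration and sample_rate must be positive")
        freqs = [t.frequency for t in self.tones]
        if len(set(freqs)) != len(freqs):
            raise ValueError(f"stimulus frequencies must be distinct: {freqs}")
        for f in freqs:
            cycles = f * self.epoch_duration
            if abs(cycles - round(cycles)) > _BIN_RTOL * max(1.0, cycles):
                raise ValueError(
                    f"tone {f} Hz is not bin-aligned for epoch_duration "
                    f"{self.epoch_duration} s ({cycles} cycles/epoch)"
                )
            if f >= self.sample_rate / 2:
                raise ValueError(f"tone {f} Hz exceeds Nyquist for {self.sample_rate} Hz")
        for fi in freqs:
            for fj in freqs:
                if fi > fj:
                    ratio = fi / fj
                    if abs(ratio - round(ratio)) < 1e-9:
                        raise ValueError(
                            f"{fi} Hz is a harmonic of {fj} Hz; tones must be "
                            "harmonically separated"
                        )

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(t.frequency for t in self.tones)

    @property
    def n_epoch_samples(self) -> int:
        return int(round(self.epoch_duration * self.sample_rate))


class CMSample(NamedTuple):
    """One CM estimate: time since insertion start, amplitude (µV), phase (rad)."""

    t: float
    amplitude: float
    phase: float


@dataclass
class CMTracing:
    """Time series of CM amplitude and phase at one stimulus frequency.

    ``below_floor`` marks frames whose amplitude fell under the configured
    noise floor at extraction time; phase is meaningless on those frames and
    downstream statistics exclude them.  ``None`` means "not yet assessed".
    """

    frequency: float
    t: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    below_floor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.below_floor is not None:
            self.below_floor = np.asarray(self.below_floor, dtype=bool)
        n = len(self.t)
        if len(self.amplitude) != n or len(self.phase) != n:
            raise ValueError("t, amplitude and phase must have equal length")
        if self.below_floor is not None and len(self.below_floor) != n:
            raise ValueError("below_floor length mismatch")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError(f"sample times must be strictly increasing ({self.frequency} Hz)")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")
        if not self.frequency > 0:
            raise ValueError("tracing frequency must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def samples(self) -> Iterator[CMSample]:
        for row in zip(self.t, self.amplitude, self.phase):
            yield CMSample(*row)

    def flags(self) -> np.ndarray:
        """Below-floor flags, defaulting to all-clear when unassessed."""
        if self.below_floor is None:
            return np.zeros(len(self.t), dtype=bool)
        return self.below_floor


@dataclass
class TracingBundle:
    """Time-aligned CM tracings across all stimulus frequencies of one insertion."""

    tracings: tuple[CMTracing, ...]
    meta: dict = field(default_factory=dict)
    stimulus: StimulusSet | None = None

    def __post_init__(self) -> None:
        self.tracings = tuple(self.tracings)
        if not self.tracings:
            raise ValueError("a bundle needs at least one tracing")
        freqs = [tr.frequency for tr in self.tracings]
        if len(set(freqs)) != len(freqs):
            raise ValueError(f"bundle frequencies must be unique: {freqs}")
        grid = self.tracings[0].t
        for tr in self.tracings[1:]:
            if len(tr.t) != len(grid) or not np.array_equal(tr.t, grid):
                raise ValueError(
                    f"tracing at {tr.frequency} Hz is not on the shared time grid"
                )

    @property
    def frame_times(self) -> np.ndarray:
        return self.tracings[0].t

    @property
    def n_frames(self) -> int:
        return len(self.tracings[0])

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(tr.frequency for tr in self.tracings)

    def tracing(self, frequency: float) -> CMTracing:
        for tr in self.tracings:
            if tr.frequency == frequency:
                return tr
        raise KeyError(f"no tracing at {frequency} Hz (have {self.frequencies})")

    def nearest_tracing(self, frequency: float) -> CMTracing:
        return min(self.tracings, key=lambda tr: abs(tr.frequency - frequency))

    def head(self, n_frames: int) -> "TracingBundle":
        """The bundle restricted to its first ``n_frames`` frames."""
        cut = []
        for tr in self.tracings:
            bf = None if tr.below_floor is None else tr.below_floor[:n_frames]
            cut.append(
                CMTracing(tr.frequency, tr.t[:n_frames], tr.amplitude[:n_frames],
                          tr.phase[:n_frames], bf)
            )
        return TracingBundle(tuple(cut), dict(self.meta), self.stimulus)


# --------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the monitoring algorithm.

    Defaults follow the deployed algorithm: a drop alarm candidate requires an
    amplitude decline of at least 6 dB, a "large" phase shift is one of at
    least 180° (π rad, inclusive), and a trauma alarm needs the drop + large
    shift on more than two frequencies.

    ``phase_tolerance_rad`` is a measurement-noise allowance on the large-shift
    comparison: a tonotopic place crossing reverses phase by exactly π, i.e.
    exactly on the threshold, so the comparison accepts shifts within this
    margin below ``phase_threshold_rad``.

    ``koka_mode`` restores the older single-frequency rule in which an
    amplitude drop *without* an accompanying phase change is itself treated as
    traumatic; it exists for comparison studies only.
    """

    drop_threshold_db: float = 6.0
    phase_threshold_rad: float = math.pi
    min_freqs_for_trauma: int = 3
    coincidence_window_s: float = 2.0
    smoothing_frames: int = 3
    noise_floor_uv: float = 0.05
    refractory_s: float = 2.0
    seed: int = 0
    phase_tolerance_rad: float = 0.15
    koka_mode: bool = False

    def __post_init__(self) -> None:
        if not self.drop_threshold_db > 0:
            raise ValueError("drop_threshold_db must be > 0")
        if not (0 < self.phase_threshold_rad <= TWO_PI):
            raise ValueError("phase_threshold_rad must lie in (0, 2π]")
        if self.min_freqs_for_trauma < 2:
            raise ValueError("min_freqs_for_trauma must be >= 2")
        if self.smoothing_frames < 1 or self.smoothing_frames % 2 == 0:
            raise ValueError("smoothing_frames must be odd and >= 1")
        if self.coincidence_window_s < 0 or self.refractory_s < 0:
            raise ValueError("windows must be non-negative")
        if self.noise_floor_uv < 0:
            raise ValueError("noise_floor_uv must be >= 0")
        if self.phase_tolerance_rad < 0:
            raise ValueError("phase_tolerance_rad must be >= 0")

    def large_shift(self, shift: float | None) -> bool:
        """Whether a measured |Δphase| counts as a large (≥ threshold) shift."""
        if shift is None:
            return False
        return shift >= self.phase_threshold_rad - self.phase_tolerance_rad

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            warnings.warn(
                f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2
            )
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a JSON file; missing fields take defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise TracingFormatError(f"{path}: config must be a JSON object")
    return RunConfig.from_dict(data)


# --------------------------------------------------------------------------
# tracing CSV dialect

_CSV_COLUMNS = ["t_s", "freq_hz", "amplitude_uv", "phase_rad"]
#: Values are serialized with 9 significant digits — enough that
#: write -> read -> write is byte-identical and values survive to >= 6 digits.
_CSV_FLOAT_FORMAT = "%.9g"


def read_tracing_csv(path) -> TracingBundle:
    """Read a tracing CSV file into a validated :class:`TracingBundle`.

    Raises :class:`TracingFormatError` (naming the offending data row) on
    missing columns, duplicate (t, frequency) rows, non-monotone time within a
    frequency, or tracings that do not share one time grid.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TracingFormatError(f"{path}: empty file") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TracingFormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise TracingFormatError(f"{path}: no data rows")

    dup = df.duplicated(subset=["t_s", "freq_hz"])
    if dup.any():
        row = int(df.index[dup][0]) + 2  # header is line 1
        raise TracingFormatError(f"{path}: duplicate (t, frequency) at row {row}")

    tracings = []
    for freq in df["freq_hz"].drop_duplicates():
        sub = df[df["freq_hz"] == freq]
        t = sub["t_s"].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(sub.index[np.argmin(np.diff(t) > 0) + 1]) + 2
            raise TracingFormatError(
                f"{path}: non-monotone time for {freq} Hz at row {bad}"
            )
        phase = sub["phase_rad"].to_numpy(float)
        if np.any((phase <= -math.pi - 1e-9) | (phase > math.pi + 1e-9)):
            bad = int(sub.index[np.argmax(
                (phase <= -math.pi - 1e-9) | (phase > math.pi + 1e-9))]) + 2
            raise TracingFormatError(
                f"{path}: phase outside (-π, π] for {freq} Hz at row {bad}"
            )
        try:
            tracings.append(
                CMTracing(float(freq), t, sub["amplitude_uv"].to_numpy(float),
                          wrap_phase(phase))
            )
        except ValueError as exc:
            raise TracingFormatError(f"{path}: {exc}") from exc
    try:
        return TracingBundle(tuple(tracings), meta={"source": str(path)})
    except ValueError as exc:
        raise TracingFormatError(f"{path}: {exc}") from exc


def write_tracing_csv(bundle: TracingBundle | None, path) -> None:
    """Write a bundle in the tracing CSV dialect (frame-major row order).

    ``None`` or an explicitly empty bundle argument writes a header-only file.
    """
    path = Path(path)
    if bundle is None or bundle.n_frames == 0:
        path.write_text(",".join(_CSV_COLUMNS) + "\n", encoding="utf-8")
        return
    rows = {c: [] for c in _CSV_COLUMNS}
    for i in range(bundle.n_frames):
        for tr in bundle.tracings:
            rows["t_s"].append(tr.t[i])
            rows["freq_hz"].append(tr.frequency)
            rows["amplitude_uv"].append(tr.amplitude[i])
            rows["phase_rad"].append(wrap_phase(tr.phase[i]))
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT,
              lineterminator="\n", encoding="utf-8")
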