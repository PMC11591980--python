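"""Ground-truthed synthetic cochlear implant insertions.

No public intraoperative multi-frequency ECochG recordings exist, so the
package carries a phenomenological simulator that reproduces the statistical
structure the monitor is built to recognize:

* per-frequency CM amplitude rising to a peak as the recording electrode
  approaches that frequency's characteristic place, then declining toward a
  basal-tail floor, with a 180° phase reversal across the peak;
* correlated multi-frequency amplitude drops with large phase jumps
  (**trauma**) or with only minor phase wobble (**hair-cell patch**, which
  recovers after a span);
* amplitude- and phase-measurement noise.

The frequency→place map is the Greenwood function
``F(x) = A·(10^{a·x} − k)`` with standard human constants (A = 165.4 Hz,
a = 2.1 per normalized length, k = 0.88), ``x`` measured apex→base in [0, 1].
The electrode coordinate is insertion *depth from the base*, so high
frequencies are crossed first (the tonotopic order seen in real tracings);
depth and Greenwood place are related by ``depth = 1 − place``.

Injected phase transitions (the π reversal at a place crossing, a trauma
phase jump, patch wobble) are ramped over a few frames rather than applied
between two samples: unwrapping can only track inter-frame steps below π, so
an abrupt 3.5 rad jump would alias to 2π − 3.5.  Physically the ramp models a
change developing over a couple of seconds of electrode movement.

This is pattern-level realism only: no cochlear mechanics, no electrode
geometry, and real tracings show richer structure (multiple local maxima)
than the single-peak tuning model used here.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cm_extraction import EpochRecord, build_bundle
from .tracing_io import (
    CMTracing,
    StimulusSet,
    ToneSpec,
    TracingBundle,
    wrap_phase,
)

__all__ = [
    "CochleaModel",
    "TraumaEvent",
    "PatchEvent",
    "InsertionScenario",
    "GroundTruth",
    "default_stimulus",
    "greenwood_frequency",
    "greenwood_place",
    "simulate_insertion",
    "render_epochs",
    "generate_cohort",
    "panel_a_scenario",
    "panel_b_scenario",
    "panel_c_scenario",
]

#: The deployed four-tone stimulus, high to low (1 Hz bins at 1 s epochs).
DEFAULT_FREQUENCIES = (2011.0, 1015.0, 507.0, 253.0)


def default_stimulus(n_tones: int = 4) -> StimulusSet:
    """The standard multi-tone stimulus (2011/1015/507/253 Hz, 1 s epochs)."""
    if not 1 <= n_tones <= 4:
        raise ValueError("n_tones must be in 1..4")
    return StimulusSet(tuple(ToneSpec(f) for f in DEFAULT_FREQUENCIES[:n_tones]))


@dataclass(frozen=True)
class CochleaModel:
    """Greenwood map constants and the phenomenological CM place tuning.

    ``peak_width`` is the standard deviation (normalized length) of the
    Gaussian place tuning; ``basal_tail`` is the floor fraction of the peak
    amplitude contributed by the basal tails of the tuning curve.
    """

    greenwood_A: float = 165.4
    greenwood_a: float = 2.1
    greenwood_k: float = 0.88
    length_norm: float = 1.0
    peak_width: float = 0.08
    basal_tail: float = 0.15

    def __post_init__(self) -> None:
        if self.greenwood_A <= 0 or not (0 < self.greenwood_k < 1):
            raise ValueError("require A > 0 and 0 < k < 1")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if not (0 <= self.basal_tail < 1):
            raise ValueError("basal_tail must lie in [0, 1)")

    @property
    def apex_frequency(self) -> float:
        return self.greenwood_A * (1.0 - self.greenwood_k)


def greenwood_frequency(place: float, model: CochleaModel = CochleaModel()) -> float:
    """Greenwood map: characteristic frequency at normalized place (apex→base)."""
    return model.greenwood_A * (10.0 ** (model.greenwood_a * place) - model.greenwood_k)


def greenwood_place(frequency: float, model: CochleaModel = CochleaModel()) -> float:
    """Inverse Greenwood map: normalized place in [0, 1] from the apex.

    Monotone increasing in frequency; errors below the apex frequency
    ``A·(1 − k)``.
    """
    if frequency < model.apex_frequency - 1e-9:
        raise ValueError(
            f"{frequency} Hz is below the apex frequency "
            f"{model.apex_frequency:.3f} Hz"
        )
    return math.log10(frequency / model.greenwood_A + model.greenwood_k) / model.greenwood_a


@dataclass(frozen=True)
class TraumaEvent:
    """All-frequency amplitude drop with a large persistent phase jump."""

    t: float
    drop_db: float = 10.0
    phase_jump_rad: float = 3.5


@dataclass(frozen=True)
class PatchEvent:
    """All-frequency amplitude dip over ``span_s`` with only minor phase wobble."""

    t: float
    drop_db: float = 8.0
    span_s: float = 6.0
    phase_wobble_rad: float = 0.3  # must stay well below π


@dataclass(frozen=True)
class InsertionScenario:
    """Everything that defines one simulated insertion.

    ``advance_times``/``advance_depths`` are knots of a piecewise-linear,
    non-decreasing map from time (s) to normalized insertion depth from the
    base in [0, 1]; the default advances linearly from 0 to 0.95 over the
    recording, deep enough to cross all four default characteristic places.
    ``noise_sigma`` is the multiplicative log-normal amplitude noise (as a
    fraction; 0 disables all noise), ``floor_noise_uv`` the additive noise
    floor, and phase noise scales as ``floor/amplitude`` so phase degrades
    near the floor while staying clean on strong responses.  Injected phase transitions ramp over
    ``transition_frames`` frames.
    """

    duration: float = 80.0
    stimulus: StimulusSet = field(default_factory=default_stimulus)
    advance_times: tuple[float, ...] = ()
    advance_depths: tuple[float, ...] = ()
    peak_amp_uv: float = 10.0
    noise_sigma: float = 0.0
    floor_noise_uv: float = 0.02
    transition_frames: int = 3
    events: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.advance_times:
            object.__setattr__(self, "advance_times", (0.0, self.duration))
            object.__setattr__(self, "advance_depths", (0.0, 0.95))
        if len(self.advance_times) != len(self.advance_depths):
            raise ValueError("advance knots must pair times with depths")
        d = np.asarray(self.advance_depths, float)
        if np.any(np.diff(d) < 0):
            raise ValueError("advance profile must be non-decreasing")
        if np.any((d < 0) | (d > 1)):
            raise ValueError("advance depths must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for ev in self.events:
            if not (0 <= ev.t <= self.duration):
                raise ValueError(f"event at t={ev.t} outside [0, {self.duration}]")

    def depth(self, t) -> np.ndarray:
        """Electrode insertion depth (fraction, from base) at time(s) ``t``."""
        return np.interp(t, self.advance_times, self.advance_depths)

    @property
    def frame_times(self) -> np.ndarray:
        dt = self.stimulus.epoch_duration
        n = int(self.duration / dt + 1e-9)
        return (np.arange(n) + 0.5) * dt


@dataclass
class GroundTruth:
    """What the simulator actually injected, frame-accurate."""

    crossings: list  # (frequency_hz, t_s) for each place crossing
    events: list     # injected TraumaEvent / PatchEvent instances

    def to_json(self) -> str:
        return json.dumps(
            {
                "crossings": [
                    {"frequency_hz": f, "t_s": t} for f, t in self.crossings
                ],
                "events": [
                    dict(type=type(ev).__name__, **dataclasses.asdict(ev))
                    for ev in self.events
                ],
            },
            indent=2,
        )


def _ramp(n_frames: int, start: int, width: int) -> np.ndarray:
    """0→1 ramp beginning at frame ``start``, completing over ``width`` frames."""
    out = np.zeros(n_frames)
    if start >= n_frames:
        return out
    steps = np.arange(1, width + 1) / width
    hi = min(n_frames, start + width)
    out[start:hi] = steps[: hi - start]
    out[hi:] = 1.0
    return out


def _clean_tracings(
    scenario: InsertionScenario, model: CochleaModel
) -> tuple[np.ndarray, dict[float, np.ndarray], dict[float, np.ndarray], GroundTruth]:
    """Noise-free amplitude (µV) and unwrapped phase (rad) per frequency."""
    t = scenario.frame_times
    n = len(t)
    depth = scenario.depth(t)
    k = scenario.transition_frames
    amps: dict[float, np.ndarray] = {}
    phases: dict[float, np.ndarray] = {}
    crossings = []
    for tone in scenario.stimulus.tones:
        f = tone.frequency
        place_depth = 1.0 - greenwood_place(f, model)
        tuning = np.exp(-((depth - place_depth) ** 2) / (2.0 * model.peak_width**2))
        amp = scenario.peak_amp_uv * np.maximum(model.basal_tail, tuning)
        phase = np.full(n, tone.phase_offset, dtype=float)
        crossed = np.nonzero(depth >= place_depth)[0]
        if len(crossed):
            c = int(crossed[0])
            phase = phase + math.pi * _ramp(n, c, k)
            crossings.append((f, float(t[c])))
        amps[f] = amp
        phases[f] = phase

    for ev in scenario.events:
        i0 = int(np.searchsorted(t, ev.t))
        if isinstance(ev, TraumaEvent):
            gain = 10.0 ** (-ev.drop_db / 20.0)
            for f in amps:
                amps[f][i0:] *= gain
                phases[f] = phases[f] + ev.phase_jump_rad * _ramp(n, i0, k)
        elif isinstance(ev, PatchEvent):
            gain = 10.0 ** (-ev.drop_db / 20.0)
            i1 = int(np.searchsorted(t, ev.t + ev.span_s))
            up = _ramp(n, i0, k)
            down = _ramp(n, i1, k)
            for f in amps:
                amps[f][i0:i1] *= gain
                phases[f] = phases[f] + ev.phase_wobble_rad * (up - down)
        else:
            raise TypeError(f"unknown event type: {ev!r}")
    return t, amps, phases, GroundTruth(crossings, list(scenario.events))


def _noisy_tracings(scenario, amps, phases):
    """Apply the measurement-noise model (no-op at noise_sigma = 0)."""
    if scenario.noise_sigma == 0:
        return amps, phases
    rng = np.random.default_rng(scenario.seed)
    out_a, out_p = {}, {}
    for f in amps:
        a = amps[f]
        n = len(a)
        noisy = a * np.exp(scenario.noise_sigma * rng.standard_normal(n))
        noisy = noisy + np.abs(scenario.floor_noise_uv * rng.standard_normal(n))
        # Phase noise tracks additive floor vs. signal: an additive noise of
        # std u on a tone of amplitude A perturbs its extracted phase by
        # ~u/A rad.  Multiplicative gain noise leaves phase untouched.
        phase_sigma = np.minimum(
            scenario.floor_noise_uv / np.maximum(a, 1e-12), 1.0
        )
        out_a[f] = noisy
        out_p[f] = phases[f] + phase_sigma * rng.standard_normal(n)
    return out_a, out_p


def simulate_insertion(
    scenario: InsertionScenario, model: CochleaModel = CochleaModel()
) -> tuple[TracingBundle, GroundTruth]:
    """Simulate one insertion; returns the tracing bundle and its ground truth.

    Phases are stored wrapped to ``(-π, π]``; at ``noise_sigma = 0`` the
    unwrapped phase change across each place crossing is exactly π and a
    trauma event multiplies every frequency's subsequent amplitude by exactly
    ``10^(−drop_db/20)``.
    """
    t, amps, phases, truth = _clean_tracings(scenario, model)
    amps, phases = _noisy_tracings(scenario, amps, phases)
    tracings = tuple(
        CMTracing(f, t, amps[f], wrap_phase(phases[f]))
        for f in (tone.frequency for tone in scenario.stimulus.tones)
    )
    bundle = TracingBundle(
        tracings,
        meta={"seed": scenario.seed, "noise_sigma": scenario.noise_sigma},
        stimulus=scenario.stimulus,
    )
    return bundle, truth


def render_epochs(
    scenario: InsertionScenario, model: CochleaModel = CochleaModel()
) -> list[EpochRecord]:
    """Synthesize raw waveform epochs realizing the scenario's tracings.

    Each epoch is ``Σ_f A_f(t)·cos(2πfτ + φ_f(t))`` (cosine so the stored
    phase equals the DFT-coefficient phase the extractor reports) plus white
    noise when ``noise_sigma > 0``; ``build_bundle`` of the result reproduces
    :func:`simulate_insertion`'s tracings (exactly at zero noise).
    """
    t, amps, phases, _ = _clean_tracings(scenario, model)
    amps, phases = _noisy_tracings(scenario, amps, phases)
    stim = scenario.stimulus
    n_samp = stim.n_epoch_samples
    tau = np.arange(n_samp) / stim.sample_rate
    rng = np.random.default_rng(scenario.seed + 1)
    epochs = []
    for i, tc in enumerate(t):
        wave = np.zeros(n_samp)
        for tone in stim.tones:
            f = tone.frequency
            wave += amps[f][i] * np.cos(2 * np.pi * f * tau + phases[f][i])
        if scenario.noise_sigma > 0:
            wave += (
                scenario.noise_sigma * scenario.peak_amp_uv
                * rng.standard_normal(n_samp)
            )
        epochs.append(
            EpochRecord(wave, stim.sample_rate, tc - stim.epoch_duration / 2.0)
        )
    return epochs


def generate_cohort(
    n_subjects: int,
    trauma_rate: float,
    patch_rate: float,
    seed: int,
    model: CochleaModel = CochleaModel(),
    template: InsertionScenario | None = None,
) -> list[tuple[TracingBundle, GroundTruth]]:
    """Simulate a cohort of insertions with Poisson-distributed event counts.

    Event times are drawn uniformly over the central part of the insertion
    (10%–85% of the duration, so detection and phase windows fit inside the
    recording).  Per-subject seeds derive deterministically from ``seed``:
    the same master seed reproduces the cohort bitwise.
    """
    if trauma_rate < 0 or patch_rate < 0:
        raise ValueError("event rates must be >= 0")
    template = template or InsertionScenario()
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        events = []
        lo, hi = 0.10 * template.duration, 0.85 * template.duration
        for _ in range(sub_rng.poisson(trauma_rate)):
            events.append(TraumaEvent(t=float(sub_rng.uniform(lo, hi))))
        for _ in range(sub_rng.poisson(patch_rate)):
            events.append(PatchEvent(t=float(sub_rng.uniform(lo, hi))))
        scenario = dataclasses.replace(
            template, events=tuple(events), seed=sub_seed
        )
        cohort.append(simulate_insertion(scenario, model))
    return cohort


# --------------------------------------------------------------------------
# canonical pattern archetypes
#
# Panel A: sequential tonotopic passages (full advance, no injected events).
# Panel B: a hair-cell-patch transit with the electrode short of every
#          characteristic place (correlated dip, minor phase wobble).
# Panel C: an insertion trauma (correlated drop + large phase jump).

_SHALLOW_ADVANCE = dict(advance_times=(0.0, 80.0), advance_depths=(0.0, 0.35))


def panel_a_scenario(seed: int = 0, noise_sigma: float = 0.0) -> InsertionScenario:
    """Full advance past all characteristic places; no injected events."""
    return InsertionScenario(seed=seed, noise_sigma=noise_sigma)


def panel_b_scenario(seed: int = 0, noise_sigma: float = 0.0) -> InsertionScenario:
    """Shallow advance with one hair-cell-patch transit at mid-insertion."""
    return InsertionScenario(
        seed=seed, noise_sigma=noise_sigma,
        events=(PatchEvent(t=40.0),), **_SHALLOW_ADVANCE,
    )


def panel_c_scenario(seed: int = 0, noise_sigma: float = 0.0) -> InsertionScenario:
    """Shallow advance with one trauma event at mid-insertion."""
    return InsertionScenario(
        seed=seed, noise_sigma=noise_sigma,
        events=(TraumaEvent(t=40.0),), **_SHALLOW_ADVANCE,
    )
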