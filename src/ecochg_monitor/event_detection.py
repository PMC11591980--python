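"""Per-frequency amplitude-drop detection and cross-frequency event grouping.

A *drop event* on one frequency is a decline of at least ``drop_threshold_db``
(in dB re 1 µV, i.e. ``20·log10(amplitude)``) below the running maximum seen
since the last emitted event on that frequency.  The running-max reference is
the clinically salient "best response so far": CM amplitude rises as the
recording electrode approaches a frequency's characteristic place, so declines
are judged against the best-yet response, and the reference resets after each
emission so a recovered-then-re-dropped signal can fire again.

Coincident drops across frequencies are grouped greedily left to right: each
not-yet-grouped drop anchors a group that absorbs all later drops (at most one
per frequency, earliest first) whose onset lies within ``coincidence_window_s``
of the anchor.  The resulting groups partition the drop set and are the unit
the decision engine classifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cm_extraction import unwrap_phase
from .tracing_io import CMTracing, RunConfig

__all__ = ["DropEvent", "EventGroup", "detect_drops", "measure_phase_shift",
           "group_events"]


@dataclass(frozen=True)
class DropEvent:
    """A ≥threshold amplitude decline on one frequency.

    ``phase_shift`` is |Δ unwrapped phase| between the pre-peak baseline and
    the post-drop window (``None`` until measured, or indeterminate when both
    windows hold only below-floor frames, in which case ``low_confidence`` is
    set).
    """

    frequency: float
    t_peak: float
    t_drop: float
    peak_index: int
    drop_index: int
    magnitude_db: float
    phase_shift: float | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.t_drop <= self.t_peak:
            raise ValueError("t_drop must follow t_peak")
        if self.magnitude_db <= 0:
            raise ValueError("drop magnitude must be positive (a decline)")
        if self.phase_shift is not None and self.phase_shift < 0:
            raise ValueError("phase_shift is a magnitude, must be >= 0")


@dataclass(frozen=True)
class EventGroup:
    """Temporally coincident drop events, at most one per frequency."""

    events: tuple[DropEvent, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("an event group cannot be empty")
        freqs = [e.frequency for e in self.events]
        if len(set(freqs)) != len(freqs):
            raise ValueError("at most one event per frequency in a group")

    @property
    def t_anchor(self) -> float:
        return min(e.t_drop for e in self.events)

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(e.frequency for e in self.events)

    def __len__(self) -> int:
        return len(self.events)


def _amplitude_db(amplitude: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(amplitude)


def detect_drops(tracing: CMTracing, config: RunConfig) -> list[DropEvent]:
    """Scan one (already smoothed) tracing for threshold amplitude drops.

    Emits an event at the first frame where the amplitude in dB falls at least
    ``drop_threshold_db`` below the running maximum since the last emission,
    provided the previous emission on this frequency is at least
    ``refractory_s`` old.  Below-floor frames neither trigger nor move the
    reference.  Tracings shorter than two frames yield no events.
    """
    n = len(tracing)
    if n < 2:
        return []
    flags = tracing.flags() | (tracing.amplitude < config.noise_floor_uv)
    db = _amplitude_db(tracing.amplitude)
    events: list[DropEvent] = []
    ref_db = -np.inf
    ref_idx = -1
    last_drop_t = -np.inf
    for i in range(n):
        if flags[i]:
            continue
        if db[i] > ref_db:
            ref_db = db[i]
            ref_idx = i
        elif (
            ref_db - db[i] >= config.drop_threshold_db
            and tracing.t[i] - last_drop_t >= config.refractory_s
        ):
            events.append(
                DropEvent(
                    frequency=tracing.frequency,
                    t_peak=float(tracing.t[ref_idx]),
                    t_drop=float(tracing.t[i]),
                    peak_index=ref_idx,
                    drop_index=i,
                    magnitude_db=float(ref_db - db[i]),
                )
            )
            last_drop_t = tracing.t[i]
            ref_db = db[i]  # reference resets after each emission
            ref_idx = i
    return events


def measure_phase_shift(
    tracing: CMTracing, event: DropEvent, config: RunConfig
) -> DropEvent:
    """Attach the measured |Δphase| (rad) across the drop to the event.

    The shift is the absolute difference between mean unwrapped phase over a
    *post-drop* window and a *pre-peak baseline* window, each
    ``smoothing_frames`` frames long.  The baseline ends a guard of
    ``smoothing_frames`` frames before the peak frame, keeping it clear of the
    phase transition that straddles the amplitude peak; when the peak sits too
    early for that (e.g. a flat tracing, whose running maximum is its first
    frame), the baseline anchors to the drop instead, ending one smoothing
    window plus the guard before the detection frame.  The post-drop window
    starts one smoothing window after the detection frame — detection lags the
    raw amplitude fall by up to a smoothing window while the phase change is
    still developing, so this measures the settled post-event phase — clamped
    to the end of the recording so at least one frame is always read.

    Phases are taken from the raw tracing (the window means provide the
    averaging) after unwrapping over the frames not flagged below the noise
    floor.  If either window holds no valid frame the shift is indeterminate
    (``None``) and the event is flagged low-confidence.
    """
    n = len(tracing)
    w = config.smoothing_frames
    guard = config.smoothing_frames
    flags = tracing.flags() | (tracing.amplitude < config.noise_floor_uv)
    valid = ~flags
    phase = np.full(n, np.nan)
    if valid.any():
        phase[valid] = unwrap_phase(tracing.phase[valid])

    pre_hi = event.peak_index - guard            # exclusive
    if pre_hi <= 0:
        fallback = event.drop_index - (w - 1) - guard
        pre_hi = fallback if event.peak_index == 0 else min(event.peak_index, fallback)
    pre_lo = max(0, pre_hi - w)
    post_lo = min(event.drop_index + w - 1, n - 1)
    post_hi = min(n, post_lo + w)

    def window_mean(lo: int, hi: int) -> float | None:
        if hi <= lo:
            return None
        seg = phase[lo:hi]
        seg = seg[~np.isnan(seg)]
        return float(np.mean(seg)) if len(seg) else None

    pre = window_mean(pre_lo, pre_hi)
    post = window_mean(post_lo, post_hi)
    if pre is None or post is None:
        return replace(event, phase_shift=None, low_confidence=True)
    return replace(event, phase_shift=abs(post - pre), low_confidence=False)


def group_events(
    drops: Sequence[DropEvent], config: RunConfig
) -> list[EventGroup]:
    """Partition time-sorted drops into coincidence groups (greedy, earliest-anchor).

    Each ungrouped drop anchors a group absorbing every later ungrouped drop
    whose onset is within ``coincidence_window_s`` of the anchor, keeping at
    most one drop per frequency (the earliest wins).  Deterministic: ties are
    broken by (t_drop, frequency) order.
    """
    ordered = sorted(drops, key=lambda e: (e.t_drop, e.frequency))
    groups: list[EventGroup] = []
    used = [False] * len(ordered)
    for i, anchor in enumerate(ordered):
        if used[i]:
            continue
        members = [anchor]
        used[i] = True
        seen = {anchor.frequency}
        for j in range(i + 1, len(ordered)):
            cand = ordered[j]
            if used[j] or cand.frequency in seen:
                continue
            if cand.t_drop - anchor.t_drop <= config.coincidence_window_s:
                members.append(cand)
                used[j] = True
                seen.add(cand.frequency)
        groups.append(EventGroup(tuple(members)))
    return groups
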