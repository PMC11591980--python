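"""Classification of drop-event groups and online monitoring.

The decision table distinguishes three canonical patterns seen during
electrode insertion:

* **trauma alarm** — a correlated amplitude drop on at least
  ``min_freqs_for_trauma`` frequencies ("more than two" with the default
  four-tone stimulus) in which at least that many member events also carry a
  large (≥180°) phase shift: the signature of an insult to the basilar
  membrane, the only pattern that raises an alarm;
* **hair-cell patch** — the same correlated multi-frequency drop but with all
  phase shifts small (<180°): the electrode passing a patch of hair cells or
  the basal tails of tuning curves; non-traumatic;
* **tonotopic passage** — a drop on a single frequency accompanied by a
  ≥180° phase reversal: the electrode advancing past that frequency's
  characteristic place; non-traumatic.

Everything else — two-frequency groups (for which the source rules are
silent), indeterminate phase evidence, mixed patterns below the trauma count —
is AMBIGUOUS: no alarm, logged for review.

Classification is a pure function of the group and the configuration, so the
whole monitor is deterministic; :class:`OnlineMonitor` streams frames and
emits each classification as soon as it can no longer change (bounded
latency), bitwise identical to the batch pipeline on the same data.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cm_extraction import smooth_tracing
from .event_detection import (
    DropEvent,
    EventGroup,
    detect_drops,
    group_events,
    measure_phase_shift,
)
from .tracing_io import CMTracing, RunConfig, TracingBundle

__all__ = [
    "Label",
    "Classification",
    "AlarmLog",
    "classify_group",
    "run_monitor",
    "OnlineMonitor",
    "single_freq_baseline",
]


class Label(str, enum.Enum):
    TRAUMA_ALARM = "TRAUMA_ALARM"
    TONOTOPIC_PASSAGE = "TONOTOPIC_PASSAGE"
    HAIR_CELL_PATCH = "HAIR_CELL_PATCH"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class Classification:
    """One classified event group with its structured evidence."""

    label: Label
    t: float
    group: EventGroup
    rationale: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "label": self.label.value,
            "t_s": self.t,
            "frequencies_hz": list(self.group.frequencies),
            "magnitudes_db": [e.magnitude_db for e in self.group.events],
            "phase_shifts_rad": [e.phase_shift for e in self.group.events],
            "rationale": self.rationale,
        }
        return json.dumps(payload)


@dataclass
class AlarmLog:
    """Time-ordered classifications produced during one insertion."""

    classifications: list[Classification]
    config: RunConfig
    subject: str = ""

    def __post_init__(self) -> None:
        times = [c.t for c in self.classifications]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("classification times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.classifications)

    def counts(self) -> dict[str, int]:
        out = {label.value: 0 for label in Label}
        for c in self.classifications:
            out[c.label.value] += 1
        return out

    @property
    def n_alarms(self) -> int:
        """Number of trauma alarms (the only label that alerts the surgeon)."""
        return sum(c.label is Label.TRAUMA_ALARM for c in self.classifications)

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for c in self.classifications:
                fh.write(c.to_json() + "\n")


def classify_group(
    group: EventGroup, n_freqs_total: int, config: RunConfig
) -> Classification:
    """Apply the decision table to one coincidence group (pure function).

    Rules, in order: (1) drop + large shift on ≥ ``min_freqs_for_trauma``
    frequencies → TRAUMA_ALARM; (2) drop on ≥ that many frequencies, all
    shifts small → HAIR_CELL_PATCH; (3) singleton drop with large shift →
    TONOTOPIC_PASSAGE; (4) otherwise AMBIGUOUS.  Events with indeterminate
    phase count toward neither the large- nor the small-shift tally.

    With ``config.koka_mode`` the older single-frequency convention is
    restored for comparison studies: any drop lacking a large phase shift is
    itself treated as traumatic.
    """
    if len(group) == 0:
        raise ValueError("cannot classify an empty group")
    shifts = [e.phase_shift for e in group.events]
    n_large = sum(config.large_shift(s) for s in shifts)
    n_small = sum(
        s is not None and not config.large_shift(s) for s in shifts
    )
    rationale = {
        "n_freqs_total": n_freqs_total,
        "n_freqs_dropped": len(group),
        "n_freqs_large_phase": n_large,
        "n_freqs_small_phase": n_small,
        "magnitudes_db": {e.frequency: e.magnitude_db for e in group.events},
        "phase_shifts_rad": {e.frequency: e.phase_shift for e in group.events},
    }

    if config.koka_mode:
        label = (
            Label.TONOTOPIC_PASSAGE
            if n_large == len(group)
            else Label.TRAUMA_ALARM
        )
        rationale["mode"] = "koka_single_frequency_convention"
        return Classification(label, group.t_anchor, group, rationale)

    if len(group) >= config.min_freqs_for_trauma and n_large >= config.min_freqs_for_trauma:
        label = Label.TRAUMA_ALARM
    elif len(group) >= config.min_freqs_for_trauma and n_small == len(group):
        label = Label.HAIR_CELL_PATCH
    elif len(group) == 1 and n_large == 1:
        label = Label.TONOTOPIC_PASSAGE
    else:
        label = Label.AMBIGUOUS
    return Classification(label, group.t_anchor, group, rationale)


def _analyze(bundle: TracingBundle, config: RunConfig) -> list[Classification]:
    """Batch pipeline: smooth → detect → measure phase → group → classify."""
    drops: list[DropEvent] = []
    for tr in bundle.tracings:
        smoothed = smooth_tracing(tr, config.smoothing_frames)
        for ev in detect_drops(smoothed, config):
            # phase windows read the raw (unsmoothed) tracing
            drops.append(measure_phase_shift(tr, ev, config))
    groups = group_events(drops, config)
    out = [classify_group(g, len(bundle.tracings), config) for g in groups]
    out.sort(key=lambda c: (c.t, c.group.frequencies))
    return out


def run_monitor(
    bundle: TracingBundle, config: RunConfig, subject: str = ""
) -> AlarmLog:
    """Run the full multi-frequency monitor over one insertion.

    Equivalent to streaming the frames through :class:`OnlineMonitor`
    (online/offline equivalence is a tested property).  Bundles with fewer
    than two frames yield an empty log.
    """
    if bundle.n_frames < 2:
        return AlarmLog([], config, subject)
    return AlarmLog(_analyze(bundle, config), config, subject)


class OnlineMonitor:
    """Frame-by-frame monitoring with bounded decision latency.

    Frames are pushed in time order; a classification is emitted as soon as
    (a) every frame inside its coincidence window has a final smoothed value
    (the centered smoother needs ``smoothing_frames // 2`` frames of
    lookahead) and (b) the post-drop phase window of every member event is
    complete — i.e. no later than roughly the coincidence window plus one
    smoothing window after the triggering frame.  :meth:`finalize` flushes
    decisions still pending at the end of the recording.  The emitted stream
    is identical to :func:`run_monitor` on the same data.
    """

    def __init__(self, bundle_template: TracingBundle, config: RunConfig,
                 subject: str = ""):
        self._frequencies = bundle_template.frequencies
        self._stimulus = bundle_template.stimulus
        self._config = config
        self._subject = subject
        self._t: list[float] = []
        self._amp: dict[float, list[float]] = {f: [] for f in self._frequencies}
        self._phase: dict[float, list[float]] = {f: [] for f in self._frequencies}
        self._flag: dict[float, list[bool]] = {f: [] for f in self._frequencies}
        self._emitted: set = set()
        self._log: list[Classification] = []

    @staticmethod
    def _key(c: Classification) -> tuple:
        return tuple((e.frequency, e.drop_index) for e in c.group.events)

    def _bundle(self) -> TracingBundle:
        tracings = tuple(
            CMTracing(f, np.asarray(self._t), np.asarray(self._amp[f]),
                      np.asarray(self._phase[f]),
                      np.asarray(self._flag[f], dtype=bool))
            for f in self._frequencies
        )
        return TracingBundle(tracings, stimulus=self._stimulus)

    def push(
        self,
        t: float,
        frame: Mapping[float, tuple[float, float]],
        flags: Mapping[float, bool] | None = None,
    ) -> list[Classification]:
        """Add one frame ``{frequency: (amplitude_uv, phase_rad)}``; return
        any classifications that became final."""
        if self._t and t <= self._t[-1]:
            raise ValueError("frames must be pushed in strictly increasing time")
        self._t.append(t)
        for f in self._frequencies:
            amp, phase = frame[f]
            self._amp[f].append(amp)
            self._phase[f].append(phase)
            self._flag[f].append(bool(flags[f]) if flags else False)
        n = len(self._t)
        if n < 2:
            return []
        cfg = self._config
        stable_idx = n - 1 - cfg.smoothing_frames // 2
        if stable_idx < 0:
            return []
        stable_t = self._t[stable_idx]
        fresh = []
        for c in _analyze(self._bundle(), cfg):
            key = self._key(c)
            if key in self._emitted:
                continue
            window_closed = stable_t >= c.group.t_anchor + cfg.coincidence_window_s
            members_stable = all(e.drop_index <= stable_idx for e in c.group.events)
            phase_complete = all(
                e.drop_index + 2 * cfg.smoothing_frames - 1 <= n
                for e in c.group.events
            )
            if window_closed and members_stable and phase_complete:
                self._emitted.add(key)
                fresh.append(c)
        self._log.extend(fresh)
        return fresh

    def finalize(self) -> AlarmLog:
        """Flush pending decisions and return the complete log."""
        if len(self._t) >= 2:
            for c in _analyze(self._bundle(), self._config):
                if self._key(c) not in self._emitted:
                    self._emitted.add(self._key(c))
                    self._log.append(c)
        self._log.sort(key=lambda c: (c.t, c.group.frequencies))
        return AlarmLog(self._log, self._config, self._subject)


def single_freq_baseline(
    bundle: TracingBundle,
    config: RunConfig,
    frequency: float = 500.0,
    subject: str = "",
) -> AlarmLog:
    """Amplitude-only alarms from the single tracing nearest ``frequency``.

    This is the conventional monitoring scheme (500 Hz by default): every
    threshold amplitude drop on that one tracing raises an alarm, phase
    ignored.  Errors if no tracing lies within 20% of the requested frequency.
    """
    tr = bundle.nearest_tracing(frequency)
    if abs(tr.frequency - frequency) > 0.2 * frequency:
        raise ValueError(
            f"no tracing within 20% of {frequency} Hz (nearest: {tr.frequency} Hz)"
        )
    smoothed = smooth_tracing(tr, config.smoothing_frames)
    out = []
    for ev in detect_drops(smoothed, config):
        group = EventGroup((ev,))
        out.append(
            Classification(
                Label.TRAUMA_ALARM,
                ev.t_drop,
                group,
                {
                    "mode": "single_frequency_amplitude_only",
                    "frequency_hz": tr.frequency,
                    "magnitude_db": ev.magnitude_db,
                },
            )
        )
    return AlarmLog(out, config, subject)
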