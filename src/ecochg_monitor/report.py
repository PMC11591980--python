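"""Cohort-level comparison of single- versus multi-frequency alarm counts."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .decision_engine import AlarmLog

__all__ = ["CohortSummary", "compare_alarms", "summary_from_counts"]


@dataclass
class CohortSummary:
    """Per-subject alarm counts under both monitoring schemes, plus means.

    ``mean_single`` / ``mean_multi`` are the arithmetic means of the two count
    columns (alarms per subject).
    """

    rows: pd.DataFrame  # columns: subject, single_freq_alarms, multi_freq_alarms

    def __post_init__(self) -> None:
        required = ["subject", "single_freq_alarms", "multi_freq_alarms"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise ValueError(f"summary missing columns {missing}")
        for col in required[1:]:
            vals = self.rows[col]
            if (vals < 0).any() or not (vals == vals.astype(int)).all():
                raise ValueError(f"{col} must hold non-negative integer counts")

    @property
    def mean_single(self) -> float:
        return float(self.rows["single_freq_alarms"].mean())

    @property
    def mean_multi(self) -> float:
        return float(self.rows["multi_freq_alarms"].mean())

    def to_frame(self) -> pd.DataFrame:
        """The per-subject table with a terminal MEAN row."""
        mean_row = pd.DataFrame(
            [{
                "subject": "MEAN",
                "single_freq_alarms": self.mean_single,
                "multi_freq_alarms": self.mean_multi,
            }]
        )
        return pd.concat([self.rows, mean_row], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False)


def summary_from_counts(
    counts: Mapping[str, tuple[int, int]] | pd.DataFrame,
) -> CohortSummary:
    """Build a summary from pre-tabulated per-subject (single, multi) counts."""
    if isinstance(counts, pd.DataFrame):
        df = counts[["subject", "single_freq_alarms", "multi_freq_alarms"]].copy()
    else:
        df = pd.DataFrame(
            [
                {"subject": s, "single_freq_alarms": a, "multi_freq_alarms": m}
                for s, (a, m) in counts.items()
            ]
        )
    return CohortSummary(df)


def compare_alarms(
    single: Mapping[str, AlarmLog], multi: Mapping[str, AlarmLog]
) -> CohortSummary:
    """Per-subject alarm counts and their means for the two monitoring schemes.

    ``single`` logs count every entry (amplitude-only drop alarms); ``multi``
    logs count only trauma alarms (the sole alerting label).  Both mappings
    must cover the same subjects.
    """
    if set(single) != set(multi):
        raise ValueError(
            f"subject mismatch: {sorted(set(single) ^ set(multi))}"
        )
    rows = [
        {
            "subject": s,
            "single_freq_alarms": len(single[s].classifications),
            "multi_freq_alarms": multi[s].n_alarms,
        }
        for s in single
    ]
    return CohortSummary(pd.DataFrame(rows))
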