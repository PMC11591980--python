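"""Reference data shipped with the package.

``REFERENCE_COHORT_COUNTS`` holds the published per-subject intraoperative
alarm counts for a 10-patient cochlear implant cohort in which the same
insertions were scored both ways: conventional single-frequency (500 Hz)
amplitude-only drop alarms versus the multi-frequency amplitude+phase
algorithm implemented here.  The column means (2.8 vs 0.5 alarms per subject)
are the headline clinical contrast the multi-frequency rules were designed to
achieve; the underlying raw recordings are not public, so these counts are the
reference against which the reporting arithmetic is validated.
"""

from __future__ import annotations

#: subject -> (single-frequency 500 Hz alarms, multi-frequency trauma alarms)
REFERENCE_COHORT_COUNTS: dict[str, tuple[int, int]] = {
    "CI1": (4, 0),
    "CI2": (7, 0),
    "CI3": (0, 0),
    "CI4": (2, 0),
    "CI5": (5, 1),
    "CI6": (0, 0),
    "CI7": (2, 2),
    "CI8": (2, 2),
    "CI9": (3, 0),
    "CI10": (3, 0),
}
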