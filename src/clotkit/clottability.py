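"""Fibrinogen clottability time courses under proteolytic digestion.

Fibrinogen incubated with a fibrinolytic protease progressively loses the
ability to clot on thrombin addition.  Samples withdrawn at increasing
digestion times are clotted in a coagulometer; a clotting time longer than
120 s means the residual fibrinogen is non-clottable, and such readings are
censored: stored as censored and displayed as 121 s for plotting.  The
course is summarized by the earliest digestion time at which a censored
reading occurs (time to non-clottability) — no interpolation between the
discrete withdrawal times is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClottabilityCourse",
    "censor_course",
    "time_to_nonclottability",
    "CENSOR_THRESHOLD_S",
    "CENSOR_DISPLAY_S",
]

CENSOR_THRESHOLD_S = 120.0
CENSOR_DISPLAY_S = 121.0


@dataclass(frozen=True)
class ClottabilityCourse:
    """A censored clotting-time course over digestion time.

    `clotting_times_s` holds the raw readings (NaN where the instrument
    reported no clot); `censored` marks readings beyond the threshold or
    instrument no-clot flags; `display_values_s` replaces censored readings
    with the display sentinel (121 s) for plotting.
    """

    digestion_times_min: np.ndarray
    clotting_times_s: np.ndarray
    censored: np.ndarray
    display_values_s: np.ndarray
    threshold_s: float = CENSOR_THRESHOLD_S

    def __post_init__(self) -> None:
        d = np.asarray(self.digestion_times_min, dtype=float)
        if not np.all(np.diff(d) > 0):
            raise ValueError("digestion times must be strictly increasing")
        n = d.size
        for name in ("clotting_times_s", "censored", "display_values_s"):
            v = np.asarray(getattr(self, name))
            if v.shape != (n,):
                raise ValueError("all course arrays must have equal length")
        object.__setattr__(self, "digestion_times_min", d)
        object.__setattr__(self, "clotting_times_s", np.asarray(self.clotting_times_s, dtype=float))
        object.__setattr__(self, "censored", np.asarray(self.censored, dtype=bool))
        object.__setattr__(self, "display_values_s", np.asarray(self.display_values_s, dtype=float))


def censor_course(
    digestion_times_min,
    clotting_times_s,
    no_clot_flags=None,
    threshold_s: float = CENSOR_THRESHOLD_S,
    display_s: float = CENSOR_DISPLAY_S,
) -> ClottabilityCourse:
    """Apply the censoring rule to raw clotting-time readings.

    Readings strictly longer than `threshold_s` (120 s), instrument no-clot
    flags, and NaN readings are censored and displayed as `display_s`
    (121 s); a reading of exactly 120 s is *not* censored.  Negative
    clotting times are rejected.  The operation is idempotent: display
    values of an already-censored course pass through unchanged.
    """
    d = np.asarray(digestion_times_min, dtype=float)
    ct = np.asarray(clotting_times_s, dtype=float)
    if np.any(ct[~np.isnan(ct)] < 0):
        raise ValueError("negative clotting time")
    no_clot = (
        np.zeros(ct.shape, dtype=bool)
        if no_clot_flags is None
        else np.asarray(no_clot_flags, dtype=bool)
    )
    censored = np.isnan(ct) | no_clot | (ct > threshold_s)
    display = np.where(censored, display_s, ct)
    return ClottabilityCourse(
        digestion_times_min=d,
        clotting_times_s=ct,
        censored=censored,
        display_values_s=display,
        threshold_s=threshold_s,
    )


def time_to_nonclottability(course: ClottabilityCourse) -> tuple[float | None, str]:
    """Earliest digestion time (min) with a censored reading.

    Returns ``(time, status)``; time is None with status
    ``"clottable throughout"`` when no reading is censored.
    """
    if course.digestion_times_min.size < 2:
        raise ValueError("course needs at least 2 points")
    idx = np.nonzero(course.censored)[0]
    if idx.size == 0:
        return None, "clottable throughout"
    return float(course.digestion_times_min[idx[0]]), "non-clottable"
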