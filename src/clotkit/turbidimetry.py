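"""Clot-formation and lysis metrics from turbidity traces.

A clotting assay records light absorbance at 340 nm (A340), which rises as
fibrin fibers assemble and falls again when a fibrinolytic enzyme dissolves
the network.  The quantities extracted here are the ones conventionally read
off such curves:

* ``A_max`` — maximal turbidity above baseline, a proxy for fiber
  mass/length ratio;
* ``CT90`` / ``CT50`` — clotting time, the time to reach 90% or 50% of
  ``A_max`` on the ascending branch;
* ``LT50`` — lysis time, the time (from an assay-dependent origin) until
  turbidity falls back to half-maximum on the descending branch.

Intrinsic assays (lytic enzyme present from time zero) measure lysis time
from time zero; extrinsic assays (enzyme layered on a pre-formed clot)
measure it from the addition time.  Threshold crossings are located by
linear interpolation between samples, so metrics resolve below the sampling
interval and are invariant under affine transforms of the absorbance axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticTrace",
    "ClotLysisMetrics",
    "NoClottingError",
    "normalize_trace",
    "max_turbidity",
    "clotting_time",
    "lysis_time",
    "relative_units",
    "analyze_trace",
    "amax_qc",
    "smooth_trace",
]

#: Minimum clot amplitude (AU above baseline) to call a clot at all.
MIN_CLOT_AMPLITUDE = 0.05


class NoClottingError(ValueError):
    """Raised when a trace never develops measurable turbidity."""


@dataclass(frozen=True)
class KineticTrace:
    """A single well's turbidity time course.

    Parameters
    ----------
    times : array-like of float
        Sample times in seconds, strictly increasing, >= 3 points.
    absorbance : array-like of float
        A340 readings (AU), same length as `times`.
    assay_mode : {"intrinsic", "extrinsic"}
        Lysis-time origin convention.  Extrinsic mode requires `t_addition`.
    t_addition : float, optional
        Time (s) at which the lytic agent was applied (extrinsic assays).
    baseline : float, optional
        Pre-clot absorbance; defaults to the first reading.
    """

    times: np.ndarray
    absorbance: np.ndarray
    assay_mode: str = "intrinsic"
    t_addition: float | None = None
    baseline: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times and absorbance must be 1-D and equal length")
        if t.size < 3:
            raise ValueError("a kinetic trace needs at least 3 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.assay_mode not in ("intrinsic", "extrinsic"):
            raise ValueError(f"unknown assay_mode {self.assay_mode!r}")
        if self.assay_mode == "extrinsic":
            if self.t_addition is None:
                raise ValueError("extrinsic mode requires t_addition")
            if not (t[0] <= self.t_addition <= t[-1]):
                raise ValueError("t_addition outside the recorded time range")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)

    @property
    def baseline_value(self) -> float:
        return float(self.absorbance[0]) if self.baseline is None else float(self.baseline)

    def replace(self, **kw) -> "KineticTrace":
        return dataclasses.replace(self, **kw)


@dataclass
class ClotLysisMetrics:
    """Scalar summary of one clotting/lysis curve.

    ``lt50`` is None when the curve never descends to half-maximum; the
    ``flags`` set then records why (``no_lysis`` or ``incomplete_lysis``).
    """

    a_max: float
    t_amax: float
    ct90: float | None = None
    ct50: float | None = None
    lt50: float | None = None
    flags: set[str] = field(default_factory=set)


def smooth_trace(trace: KineticTrace, window: int = 5) -> KineticTrace:
    """Centered moving average with an odd window; endpoints use a
    shrunken symmetric window so the trace length is preserved."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    a = trace.absorbance
    half = window // 2
    out = np.empty_like(a)
    for i in range(a.size):
        k = min(half, i, a.size - 1 - i)
        out[i] = a[i - k : i + k + 1].mean()
    return trace.replace(absorbance=out)


def normalize_trace(trace: KineticTrace) -> KineticTrace:
    """Affinely map absorbance so baseline -> 0 and the maximum -> 1.

    Metric times computed on the normalized trace equal those on the raw
    trace because every threshold here is defined as a fraction of the
    baseline-to-maximum amplitude.
    """
    b = trace.baseline_value
    amp = float(trace.absorbance.max()) - b
    if amp <= 0:
        raise NoClottingError("flat trace: maximum does not exceed baseline")
    return trace.replace(absorbance=(trace.absorbance - b) / amp, baseline=0.0)


def max_turbidity(trace: KineticTrace) -> tuple[float, float]:
    """Return (a_max, t_amax): the global absorbance maximum above baseline
    and its time.  Ties are broken by the earliest time."""
    a = trace.absorbance
    i = int(np.argmax(a))  # argmax returns the first occurrence
    return float(a[i]), float(trace.times[i])


def _first_crossing_up(t: np.ndarray, a: np.ndarray, level: float) -> float:
    """First time the linearly interpolated signal reaches `level` from below."""
    above = a >= level
    if not above.any():
        raise ValueError("signal never reaches the level")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1, a0, a1 = t[i - 1], t[i], a[i - 1], a[i]
    if a1 == a0:
        return float(t1)
    return float(t0 + (level - a0) * (t1 - t0) / (a1 - a0))


def _first_crossing_down(t: np.ndarray, a: np.ndarray, level: float) -> float | None:
    """First time the interpolated signal falls to `level` from above, or None."""
    below = a <= level
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(t[0])
    t0, t1, a0, a1 = t[i - 1], t[i], a[i - 1], a[i]
    if a1 == a0:
        return float(t1)
    return float(t0 + (level - a0) * (t1 - t0) / (a1 - a0))


def clotting_time(
    trace: KineticTrace,
    fraction: float = 0.9,
    min_amplitude: float = MIN_CLOT_AMPLITUDE,
) -> float:
    """Time (from time zero) to reach `fraction` of A_max on the ascending branch.

    `fraction` = 0.9 gives CT90, 0.5 gives CT50.  The crossing is located by
    linear interpolation on the sub-trace up to t_amax.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    b = trace.baseline_value
    a_max, t_amax = max_turbidity(trace)
    if a_max - b < min_amplitude:
        raise NoClottingError(
            f"amplitude {a_max - b:.4f} AU below the clotting threshold {min_amplitude} AU"
        )
    asc = trace.times <= t_amax
    level = b + fraction * (a_max - b)
    return _first_crossing_up(trace.times[asc], trace.absorbance[asc], level)


def lysis_time(
    trace: KineticTrace,
    min_amplitude: float = MIN_CLOT_AMPLITUDE,
) -> tuple[float | None, set[str]]:
    """LT50: time until turbidity halves on the descending branch, measured
    from time zero (intrinsic) or from `t_addition` (extrinsic).

    Returns ``(lt50, flags)``; lt50 is None with an explanatory flag when
    the curve never descends to half-maximum (the first post-peak crossing
    wins when noise produces several).
    """
    b = trace.baseline_value
    a_max, t_amax = max_turbidity(trace)
    if a_max - b < min_amplitude:
        raise NoClottingError("no clot formed; lysis time undefined")
    desc = trace.times >= t_amax
    level = b + 0.5 * (a_max - b)
    t_cross = _first_crossing_down(trace.times[desc], trace.absorbance[desc], level)
    if t_cross is None:
        flags = {"incomplete_lysis"}
        if float(trace.absorbance[-1]) >= b + 0.95 * (a_max - b):
            flags.add("no_lysis")  # turbidity never meaningfully descended
        return None, flags
    origin = trace.t_addition if trace.assay_mode == "extrinsic" else 0.0
    return float(t_cross - origin), set()


def relative_units(value: float, reference: float) -> float:
    """Express `value` as a dimensionless multiple of `reference` (RU).

    A reference against itself is exactly 1.00; RU = 2.00 corresponds to a
    100% prolongation.
    """
    if reference <= 0:
        raise ValueError("reference must be strictly positive")
    return float(value) / float(reference)


def amax_qc(a_max_lytic: float, a_max_reference: float, tol: float = 0.10) -> bool:
    """Assay-validity check: maximal turbidity of a lytic well must fall
    within ±`tol` (default 10%) of the non-lytic reference well's A_max."""
    if a_max_reference <= 0:
        raise ValueError("reference A_max must be positive")
    return abs(a_max_lytic - a_max_reference) <= tol * a_max_reference


def analyze_trace(
    trace: KineticTrace,
    min_amplitude: float = MIN_CLOT_AMPLITUDE,
    smooth_window: int | None = None,
) -> ClotLysisMetrics:
    """Compute the full metric set (A_max, CT90, CT50, LT50) for one trace.

    Optional centered moving-average smoothing (odd `smooth_window`) tames
    noisy descending branches; by default no smoothing is applied.
    """
    if smooth_window is not None:
        trace = smooth_trace(trace, smooth_window)
    b = trace.baseline_value
    a_max, t_amax = max_turbidity(trace)
    if a_max - b < min_amplitude:
        return ClotLysisMetrics(a_max=a_max, t_amax=t_amax, flags={"no_clotting"})
    m = ClotLysisMetrics(a_max=a_max, t_amax=t_amax)
    m.ct90 = clotting_time(trace, 0.9, min_amplitude)
    m.ct50 = clotting_time(trace, 0.5, min_amplitude)
    m.lt50, lysis_flags = lysis_time(trace, min_amplitude)
    m.flags |= lysis_flags
    return m
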