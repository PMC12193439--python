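"""Darcy permeability of fibrin gels from throughput-length readings.

A clot formed in a pipette tip is perfused under a constant hydrostatic
pressure head; the advance of buffer along an attached tube of known inner
diameter is read periodically.  The permeation coefficient (Darcy's
constant) is

    K_s = Q * n * L / (t * A * dP)        [cm^2]

with Q the permeated volume (cm^3), n the buffer viscosity (N.s/cm^2),
L the clot length (cm), t the elapsed time (s), A the clot cross-section
(cm^2) and dP the pressure drop (N/cm^2).  K_s is a standard proxy for
network pore size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PermeationGeometry",
    "PermeationExperiment",
    "FlowResult",
    "volumetric_flow",
    "darcy_constant",
    "analyze_permeation",
]


@dataclass(frozen=True, kw_only=True)
class PermeationGeometry:
    """Geometry and physical constants of a permeation setup.

    Defaults follow the conventional fibrin permeation configuration:
    HBS viscosity 1e-7 N.s/cm^2 (1e-2 poise), 1.5 cm clot, 0.09 cm^2
    cross-section, 0.170 N/cm^2 pressure drop.  The tubing inner diameter
    has no default: it is instrument-specific and must be supplied.
    """

    tubing_inner_diameter: float  # cm
    viscosity_n: float = 1e-7  # N.s/cm^2
    clot_length_L: float = 1.5  # cm
    clot_area_A: float = 0.09  # cm^2
    pressure_drop_dP: float = 0.170  # N/cm^2

    def __post_init__(self) -> None:
        for name in (
            "tubing_inner_diameter",
            "viscosity_n",
            "clot_length_L",
            "clot_area_A",
            "pressure_drop_dP",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def tube_cross_section(self) -> float:
        """Tube lumen area, pi*(d/2)^2, in cm^2."""
        return float(np.pi * (self.tubing_inner_diameter / 2.0) ** 2)


@dataclass(frozen=True)
class PermeationExperiment:
    """Cumulative throughput-length readings for one clot.

    `times_s` and `lengths_mm` are matched series; lengths are cumulative
    liquid advance along the tube (mm) and must be non-decreasing up to the
    reading precision (decreasing readings indicate a reading error and are
    rejected at analysis time).
    """

    geometry: PermeationGeometry
    times_s: np.ndarray
    lengths_mm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        x = np.asarray(self.lengths_mm, dtype=float)
        if t.shape != x.shape or t.ndim != 1:
            raise ValueError("times and lengths must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("need at least 2 readings")
        if not np.all(np.diff(t) > 0):
            raise ValueError("reading times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "lengths_mm", x)


@dataclass
class FlowResult:
    Q_cm3: float
    elapsed_s: float
    interval_rates: np.ndarray  # cm^3/s per reading interval
    rate_cv: float  # coefficient of variation of interval rates
    flags: set[str] = field(default_factory=set)


def volumetric_flow(
    experiment: PermeationExperiment,
    start_offset_s: float = 0.0,
    cv_limit: float = 0.20,
) -> FlowResult:
    """Convert throughput lengths to permeated volume Q over the analysis window.

    Q = pi*(d/2)^2 * advance, with advance the cumulative length gain (cm)
    between the first and last reading at or after `start_offset_s` (the
    offset excludes an initial wash period).  Per-interval volumetric rates
    are returned for a steadiness check: a coefficient of variation above
    `cv_limit` flags ``unsteady_flow`` (possible clot rupture or leak).
    """
    sel = experiment.times_s >= start_offset_s
    t = experiment.times_s[sel]
    x_cm = experiment.lengths_mm[sel] / 10.0
    if t.size < 2:
        raise ValueError("fewer than 2 readings in the analysis window")
    if np.any(np.diff(x_cm) < 0):
        raise ValueError("decreasing cumulative length: reading error")
    area = experiment.geometry.tube_cross_section
    q_total = area * float(x_cm[-1] - x_cm[0])
    elapsed = float(t[-1] - t[0])
    rates = area * np.diff(x_cm) / np.diff(t)
    mean_rate = rates.mean()
    cv = float(rates.std(ddof=0) / mean_rate) if mean_rate > 0 else np.inf
    flags = {"unsteady_flow"} if cv > cv_limit else set()
    return FlowResult(Q_cm3=q_total, elapsed_s=elapsed, interval_rates=rates, rate_cv=cv, flags=flags)


def darcy_constant(Q: float, t: float, geometry: PermeationGeometry) -> float:
    """K_s = Q*n*L / (t*A*dP) in cm^2."""
    if t <= 0:
        raise ValueError("elapsed time must be strictly positive")
    g = geometry
    return float(Q * g.viscosity_n * g.clot_length_L / (t * g.clot_area_A * g.pressure_drop_dP))


def analyze_permeation(
    experiment: PermeationExperiment,
    start_offset_s: float = 0.0,
    cv_limit: float = 0.20,
) -> dict:
    """Full pipeline: flow -> K_s, with QC flags.

    Returns a dict with ``Q_cm3``, ``elapsed_s``, ``mean_rate_cm3_s``,
    ``ks_cm2``, ``rate_cv`` and ``flags``.
    """
    flow = volumetric_flow(experiment, start_offset_s=start_offset_s, cv_limit=cv_limit)
    ks = darcy_constant(flow.Q_cm3, flow.elapsed_s, experiment.geometry)
    return {
        "Q_cm3": flow.Q_cm3,
        "elapsed_s": flow.elapsed_s,
        "mean_rate_cm3_s": float(flow.interval_rates.mean()),
        "ks_cm2": ks,
        "rate_cv": flow.rate_cv,
        "flags": flow.flags,
    }
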