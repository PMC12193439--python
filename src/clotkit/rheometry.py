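"""Oscillation-rheometry analysis of fibrin gels.

Two phases are analyzed.  During clotting, a small oscillatory strain
(0.015 at 1 Hz) probes the developing network and the storage (G') and
loss (G'') moduli plateau as clotting completes; the plateau values and
their ratio (loss tangent G''/G') characterize gel stiffness and
dissipation.  Afterwards a stress ramp (tau from 0.01 to 1000 Pa, stepwise
over 300 s) loads the gel to failure: the apparent dynamic viscosity
eta = tau / (dgamma/dt) grows or holds until the network yields, then falls
abruptly as the gel starts to flow.  The gel-fluid transition is summarized
by gamma_max, the maximal bearable strain before the viscosity fall, and
tau0, the critical shear stress at that strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RheoRecord",
    "FlowLimit",
    "NoGelError",
    "plateau_moduli",
    "apparent_viscosity",
    "flow_limit",
    "characterize_record",
]


class NoGelError(ValueError):
    """Raised when the clotting phase shows no positive storage modulus."""


@dataclass(frozen=True)
class RheoRecord:
    """Clotting-phase moduli and ramp-phase stress/strain for one sample.

    clotting phase: (time_s, gprime_Pa, gdoubleprime_Pa);
    ramp phase: (time_s, tau_Pa, gamma).  Ramp stress must be non-decreasing
    and the two phases must not overlap in time.
    """

    clot_time_s: np.ndarray
    gprime_Pa: np.ndarray
    gdoubleprime_Pa: np.ndarray
    ramp_time_s: np.ndarray
    tau_Pa: np.ndarray
    gamma: np.ndarray
    oscillation_strain: float = 0.015
    oscillation_hz: float = 1.0

    def __post_init__(self) -> None:
        for name in ("clot_time_s", "gprime_Pa", "gdoubleprime_Pa", "ramp_time_s", "tau_Pa", "gamma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.clot_time_s.shape == self.gprime_Pa.shape == self.gdoubleprime_Pa.shape):
            raise ValueError("clotting-phase series must have matching lengths")
        if not (self.ramp_time_s.shape == self.tau_Pa.shape == self.gamma.shape):
            raise ValueError("ramp-phase series must have matching lengths")
        if np.any(np.diff(self.tau_Pa) < 0):
            raise ValueError("ramp stress must be non-decreasing")
        if self.clot_time_s.size and self.ramp_time_s.size:
            if self.ramp_time_s[0] <= self.clot_time_s[-1]:
                raise ValueError("clotting and ramp phases overlap in time")


@dataclass
class FlowLimit:
    """Plateau moduli and gel-fluid transition parameters."""

    gprime_plateau: float
    gdoubleprime_plateau: float
    loss_tangent: float
    gamma_max: float | None = None
    tau0: float | None = None
    transition_found: bool = False


def plateau_moduli(
    time_s: np.ndarray,
    gprime: np.ndarray,
    gdoubleprime: np.ndarray,
    window_frac: float = 0.2,
) -> tuple[float, float, float]:
    """Plateau G', G'' and loss tangent from the clotting phase.

    The plateau is the mean over the final `window_frac` of the phase
    duration (default last 20%).  A non-positive plateau G' means no gel
    formed and raises :class:`NoGelError`.
    """
    time_s = np.asarray(time_s, dtype=float)
    if time_s.size < 2 or time_s[-1] - time_s[0] < 60.0:
        raise ValueError("need at least 1 min of clotting-phase data")
    if not 0.0 < window_frac <= 1.0:
        raise ValueError("window_frac must be in (0, 1]")
    t_start = time_s[-1] - window_frac * (time_s[-1] - time_s[0])
    sel = time_s >= t_start
    gp = float(np.mean(np.asarray(gprime, dtype=float)[sel]))
    gpp = float(np.mean(np.asarray(gdoubleprime, dtype=float)[sel]))
    if gp <= 0:
        raise NoGelError("plateau storage modulus is not positive: no gel")
    return gp, gpp, gpp / gp


def apparent_viscosity(
    time_s: np.ndarray, tau_Pa: np.ndarray, gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Apparent dynamic viscosity eta(t) = tau(t) / (dgamma/dt)(t).

    The strain rate uses centered finite differences (one-sided at the
    ends).  Where the strain rate is not positive (no creep) eta is
    reported as +inf and flagged; returns ``(eta, zero_rate_flags)``.
    """
    t = np.asarray(time_s, dtype=float)
    tau = np.asarray(tau_Pa, dtype=float)
    g = np.asarray(gamma, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 ramp points")
    gdot = np.gradient(g, t)
    # centered differences of a constant strain leave O(eps) residue
    tol = 1e-12 * max(1.0, float(np.max(np.abs(g)))) / float(np.min(np.diff(t)))
    flags = gdot <= tol
    eta = np.full_like(tau, np.inf)
    np.divide(tau, gdot, out=eta, where=~flags)
    return eta, flags


def flow_limit(
    time_s: np.ndarray,
    tau_Pa: np.ndarray,
    gamma: np.ndarray,
    fall_factor: float = 10.0,
    eta_Pa_s: np.ndarray | None = None,
) -> tuple[float | None, float | None, bool]:
    """Detect the gel-fluid transition on a stress ramp.

    Some instruments export the dynamic viscosity directly; pass it as
    `eta_Pa_s` (aligned with the ramp samples) to skip the strain-rate
    derivation.

    The transition index is the first ramp point at which eta drops below
    (running maximum of eta) / `fall_factor`; gamma_max and tau0 are the
    strain and stress at the last point before that index.  Returns
    ``(gamma_max, tau0, transition_found)``; ``(None, None, False)`` when
    no such drop exists.  On a sharp (orders-of-magnitude) yield the result
    is insensitive to the exact fall factor.

    Detection uses backward strain-rate differences so that the viscosity
    collapse registers at the first post-yield sample (a centered
    difference would flag the last pre-yield point, whose rate estimate
    already sees the strain jump, and bias the reported stress one ramp
    step low).
    """
    if fall_factor <= 1:
        raise ValueError("fall_factor must exceed 1")
    t = np.asarray(time_s, dtype=float)
    tau = np.asarray(tau_Pa, dtype=float)
    g = np.asarray(gamma, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 ramp points")
    if eta_Pa_s is not None:
        eta = np.asarray(eta_Pa_s, dtype=float)[1:]
    else:
        gdot = np.diff(g) / np.diff(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            eta = np.where(gdot > 0, tau[1:] / gdot, np.inf)  # eta[i] belongs to sample i+1
    finite = np.isfinite(eta)
    if finite.sum() < 3:
        raise ValueError("fewer than 3 finite viscosity values")
    run_max = -np.inf
    for j in range(eta.size):
        if not finite[j]:
            continue
        if run_max > 0 and eta[j] < run_max / fall_factor:
            return float(g[j]), float(tau[j]), True  # sample j = last point before j+1
        run_max = max(run_max, eta[j])
    return None, None, False


def characterize_record(
    record: RheoRecord,
    window_frac: float = 0.2,
    fall_factor: float = 10.0,
) -> FlowLimit:
    """Full characterization: plateau moduli plus gel-fluid transition."""
    gp, gpp, lt = plateau_moduli(
        record.clot_time_s, record.gprime_Pa, record.gdoubleprime_Pa, window_frac
    )
    gamma_max, tau0, found = flow_limit(
        record.ramp_time_s, record.tau_Pa, record.gamma, fall_factor
    )
    return FlowLimit(
        gprime_plateau=gp,
        gdoubleprime_plateau=gpp,
        loss_tangent=lt,
        gamma_max=gamma_max,
        tau0=tau0,
        transition_found=found,
    )
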