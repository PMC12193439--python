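"""Seeded synthetic-data generators for all five assay modalities.

Every analysis stage in the package has a generator here that produces data
with known ground truth, so parameter recovery can be tested without any
instrument export: sigmoidal turbidity curves with optional lysis decay,
linear cumulative permeation, plateauing rheometric moduli plus a stress
ramp with an abrupt viscosity fall, rendered fiber fields with a specified
diameter distribution, and clottability courses with progressive clotting
time prolongation and censoring.

Default parameter values are set to the scale of real fibrin experiments:
K_s around 0.29e-9 cm^2, plateau G' around 34.6 Pa with loss tangent near
0.08, yield at tau0 near 100 Pa and gamma_max near 1.9, fiber diameter
median near 95 nm, lysis times of tens of minutes, and a 10 s clotting time
for undigested fibrinogen.

All randomness flows from a single integer seed per call; no global state.
Noiseless generation followed by the matching analysis operation is an
exact round trip (to one sampling or ramp step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .clottability import CENSOR_THRESHOLD_S, ClottabilityCourse, censor_course
from .permeation import PermeationExperiment, PermeationGeometry
from .rheometry import RheoRecord
from .turbidimetry import KineticTrace

__all__ = [
    "TurbidityParams",
    "TurbidityTruth",
    "gen_turbidity_trace",
    "DEFAULT_TUBING_DIAMETER_CM",
    "default_permeation_geometry",
    "gen_permeation_readings",
    "gen_rheo_record",
    "FiberFieldParams",
    "FiberFieldTruth",
    "render_fibers",
    "gen_fiber_image",
    "gen_clottability_course",
]


# ---------------------------------------------------------------------------
# turbidity

def _smoothstep(u: np.ndarray) -> np.ndarray:
    """3u^2 - 2u^3 clamped to [0, 1]; reaches 0 and 1 exactly and passes
    through 1/2 at u = 1/2 with point symmetry about the center."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _smoothstep_inverse(level: float) -> float:
    """u in [0, 1] with smoothstep(u) = level."""
    return brentq(lambda u: u * u * (3.0 - 2.0 * u) - level, 0.0, 1.0, xtol=1e-12)


@dataclass(frozen=True, kw_only=True)
class TurbidityParams:
    """Ground-truth parameters of a synthetic turbidity curve.

    The curve rises from `baseline` to `a_max` through a finite-support
    sigmoidal branch crossing half-amplitude exactly at `ct50_true`, holds
    a plateau, and (when `lt50_true` is set) falls back through a second
    branch crossing half-amplitude exactly at `lt50_true`.  Steepness
    values are the maximal slope of the normalized branch (1/s).
    """

    baseline: float = 0.05  # AU
    a_max: float = 0.8  # AU
    ct50_true: float = 600.0  # s
    formation_steepness: float = 0.005  # 1/s
    lt50_true: float | None = 2400.0  # s; None = no lysis
    lysis_steepness: float = 0.002  # 1/s
    noise_sd: float = 0.0  # AU
    sample_interval: float = 10.0  # s
    duration: float = 3600.0  # s
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.a_max > self.baseline >= 0:
            raise ValueError("need a_max > baseline >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.formation_steepness <= 0 or self.lysis_steepness <= 0:
            raise ValueError("steepness values must be positive")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise ValueError("sample_interval and duration must be positive")
        if self.lt50_true is not None:
            if self.ct50_true >= self.lt50_true:
                raise ValueError("ct50_true must precede lt50_true")
            if self.duration < self.lt50_true:
                raise ValueError("duration shorter than lt50_true: lysis not observable")
            if self.ct50_true + self.rise_halfwidth >= self.lt50_true - self.fall_halfwidth:
                raise ValueError("formation and lysis branches overlap; steepen them or separate the midpoints")

    @property
    def rise_halfwidth(self) -> float:
        return 0.75 / self.formation_steepness

    @property
    def fall_halfwidth(self) -> float:
        return 0.75 / self.lysis_steepness


@dataclass(frozen=True)
class TurbidityTruth:
    """Noise-free metric values implied by :class:`TurbidityParams`."""

    a_max: float
    t_amax: float
    ct50: float
    ct90: float
    lt50: float | None


def gen_turbidity_trace(params: TurbidityParams) -> tuple[KineticTrace, TurbidityTruth]:
    """Generate a turbidity trace with known ground-truth metrics.

    At ``noise_sd = 0`` the curve crosses half-amplitude exactly at
    `ct50_true` on the ascending branch and exactly at `lt50_true` on the
    descending branch, and the plateau equals `a_max` exactly.
    """
    p = params
    t = np.arange(0.0, p.duration + 0.5 * p.sample_interval, p.sample_interval)
    amp = p.a_max - p.baseline
    w_r = p.rise_halfwidth
    rise = _smoothstep((t - (p.ct50_true - w_r)) / (2.0 * w_r))
    if p.lt50_true is not None:
        w_f = p.fall_halfwidth
        fall = 1.0 - _smoothstep((t - (p.lt50_true - w_f)) / (2.0 * w_f))
    else:
        fall = np.ones_like(t)
    a = p.baseline + amp * rise * fall
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        a = a + rng.normal(0.0, p.noise_sd, size=a.shape)
    u90 = _smoothstep_inverse(0.9)
    truth = TurbidityTruth(
        a_max=p.a_max,
        t_amax=p.ct50_true + w_r,
        ct50=p.ct50_true,
        ct90=p.ct50_true - w_r + 2.0 * w_r * u90,
        lt50=p.lt50_true,
    )
    return KineticTrace(times=t, absorbance=a, assay_mode="intrinsic"), truth


# ---------------------------------------------------------------------------
# permeation

#: The tubing inner diameter used by the synthetic generator (cm).  Real
#: setups must measure their own; 0.2 cm gives ~6 mm advance per 10 min at
#: K_s = 0.29e-9 cm^2 under the default geometry, a realistic reading pace.
DEFAULT_TUBING_DIAMETER_CM = 0.2


def default_permeation_geometry() -> PermeationGeometry:
    return PermeationGeometry(tubing_inner_diameter=DEFAULT_TUBING_DIAMETER_CM)


def gen_permeation_readings(
    ks_true: float = 0.29e-9,
    geometry: PermeationGeometry | None = None,
    read_interval_s: float = 600.0,
    n_reads: int = 13,
    noise_sd_mm: float = 0.0,
    seed: int | None = None,
) -> PermeationExperiment:
    """Cumulative throughput readings implied by a true Darcy constant.

    The constant-pressure flow rate follows Darcy's law,
    Q/t = K_s*A*dP/(n*L); the cumulative tube advance is that volume spread
    over the tube lumen, read every `read_interval_s` (default 10 min)
    starting at t = 0, with optional Gaussian reading noise in mm.  At zero
    noise the analysis round trip recovers `ks_true` exactly.
    """
    if ks_true <= 0:
        raise ValueError("ks_true must be positive")
    if read_interval_s <= 0:
        raise ValueError("read interval must be positive")
    if n_reads < 2:
        raise ValueError("need at least 2 readings")
    g = geometry or default_permeation_geometry()
    q_rate = ks_true * g.clot_area_A * g.pressure_drop_dP / (g.viscosity_n * g.clot_length_L)
    t = np.arange(n_reads) * read_interval_s
    lengths_mm = 10.0 * q_rate * t / g.tube_cross_section
    if noise_sd_mm > 0:
        rng = np.random.default_rng(seed)
        lengths_mm = lengths_mm + rng.normal(0.0, noise_sd_mm, size=lengths_mm.shape)
        lengths_mm = np.maximum.accumulate(lengths_mm)  # readings cannot run backwards
    return PermeationExperiment(geometry=g, times_s=t, lengths_mm=lengths_mm)


# ---------------------------------------------------------------------------
# rheometry

def gen_rheo_record(
    gprime_plateau: float = 34.6,
    gdoubleprime_plateau: float = 2.8,
    tau0_true: float | None = 100.4,
    gamma_max_true: float = 1.9,
    ramp_tau_min: float = 0.01,
    ramp_tau_max: float = 1000.0,
    ramp_duration_s: float = 300.0,
    n_ramp_steps: int = 151,
    clot_duration_s: float = 600.0,
    clot_dt_s: float = 1.0,
    moduli_rise_time_s: float = 300.0,
    noise_sd_pa: float = 0.0,
    seed: int | None = None,
) -> RheoRecord:
    """Synthetic rheometer record: clotting phase plus stress ramp.

    The clotting-phase moduli rise smoothly and sit exactly on their
    plateaus over the final phase.  The ramp applies logarithmically spaced
    stress steps from `ramp_tau_min` to `ramp_tau_max` over
    `ramp_duration_s`.  Pre-yield strain follows

        gamma(tau) = tau/G' + (gamma_max - tau0/G') * (tau/tau0)^2,

    i.e. Hookean compliance at small stress bending to hit `gamma_max_true`
    exactly at `tau0_true`; beyond tau0 the sample flows as a Newtonian
    fluid whose viscosity is 1000x below the pre-yield apparent viscosity,
    an abrupt gel-fluid transition.  With ``tau0_true=None`` the record is
    Hookean throughout (no transition).  Monotone pre-yield strain requires
    gamma_max > tau0/(2 G'); inconsistent combinations are rejected.
    """
    if gprime_plateau <= 0:
        raise ValueError("gprime_plateau must be positive")
    t_clot = np.arange(0.0, clot_duration_s + 0.5 * clot_dt_s, clot_dt_s)
    ramp_shape = _smoothstep(t_clot / moduli_rise_time_s)
    gp = gprime_plateau * ramp_shape
    gpp = gdoubleprime_plateau * ramp_shape
    rng = np.random.default_rng(seed)
    if noise_sd_pa > 0:
        gp = gp + rng.normal(0.0, noise_sd_pa, size=gp.shape)
        gpp = gpp + rng.normal(0.0, noise_sd_pa, size=gpp.shape)

    t_ramp = clot_duration_s + 10.0 + np.linspace(0.0, ramp_duration_s, n_ramp_steps)
    tau = np.geomspace(ramp_tau_min, ramp_tau_max, n_ramp_steps)
    log_rate = np.log(ramp_tau_max / ramp_tau_min) / ramp_duration_s  # d(ln tau)/dt

    if tau0_true is None:
        gamma = tau / gprime_plateau
        return RheoRecord(t_clot, gp, gpp, t_ramp, tau, gamma)

    if not ramp_tau_min < tau0_true < ramp_tau_max:
        raise ValueError("tau0_true must lie inside the ramp stress range")
    coeff = gamma_max_true - tau0_true / gprime_plateau
    if gamma_max_true <= tau0_true / (2.0 * gprime_plateau):
        raise ValueError(
            "gamma_max_true inconsistent with tau0_true/gprime relation: "
            f"need gamma_max > tau0/(2 G') = {tau0_true / (2 * gprime_plateau):.3g} "
            "for a monotone pre-yield strain"
        )

    gamma = np.empty_like(tau)
    pre = tau <= tau0_true
    gamma[pre] = tau[pre] / gprime_plateau + coeff * (tau[pre] / tau0_true) ** 2
    # apparent viscosity at the last pre-yield step, from the analytic strain rate
    tau_last = tau[pre][-1]
    dgamma_dtau = 1.0 / gprime_plateau + 2.0 * coeff * tau_last / tau0_true**2
    gdot_last = dgamma_dtau * tau_last * log_rate
    eta_post = (tau_last / gdot_last) / 1000.0
    idx_post = np.nonzero(~pre)[0]
    g_prev = gamma[pre][-1]
    t_prev = t_ramp[pre][-1]
    for i in idx_post:
        dt = t_ramp[i] - t_prev
        g_prev = g_prev + tau[i] / eta_post * dt
        t_prev = t_ramp[i]
        gamma[i] = g_prev
    return RheoRecord(t_clot, gp, gpp, t_ramp, tau, gamma)


# ---------------------------------------------------------------------------
# fiber fields

@dataclass(frozen=True, kw_only=True)
class FiberFieldParams:
    """Parameters of a rendered straight-fiber field.

    `diameter_law` names the width distribution:
    ``{"family": "lognormal", "median_nm": 95.0, "sigma": 0.35}`` or
    ``{"family": "constant", "value_nm": 96.0}``.  Fibers are straight
    full-length segments with uniformly random orientation; curvature and
    branching affect network topology but not diameter recovery, so the
    renderer omits them and the drawn widths remain exact ground truth.
    """

    image_size: tuple[int, int] = (512, 512)
    nm_per_pixel: float = 8.0
    n_fibers: int = 40
    diameter_law: dict = field(
        default_factory=lambda: {"family": "lognormal", "median_nm": 95.0, "sigma": 0.35}
    )
    blur_sigma: float = 1.0  # px
    noise_sd: float = 5.0  # gray levels
    fg_gray: float = 200.0
    bg_gray: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image must be at least 64x64")
        if self.nm_per_pixel <= 0:
            raise ValueError("nm_per_pixel must be positive")
        if self.n_fibers < 1:
            raise ValueError("need at least one fiber")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")
        fam = self.diameter_law.get("family")
        if fam not in ("lognormal", "constant"):
            raise ValueError("diameter_law family must be 'lognormal' or 'constant'")


@dataclass(frozen=True)
class FiberFieldTruth:
    """Ground truth attached to a rendered fiber field."""

    widths_nm: np.ndarray
    mask: np.ndarray  # analytic foreground (coverage >= 1/2)


def render_fibers(
    shape: tuple[int, int],
    centers: np.ndarray,
    angles: np.ndarray,
    widths_px: np.ndarray,
    fg_gray: float = 200.0,
    bg_gray: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render anti-aliased straight fibers; returns (image, true mask).

    Each fiber is an infinite straight band through `center` at `angle`
    with the given width; pixel coverage falls off linearly over one pixel
    at the band edge (anti-aliasing) and overlapping fibers compose by
    maximum coverage.  The truth mask marks pixels whose center lies within
    half a width of any fiber axis.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coverage = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for (cy, cx), ang, width in zip(centers, angles, widths_px):
        # perpendicular distance to the fiber axis
        d = np.abs(-np.sin(ang) * (xx - cx) + np.cos(ang) * (yy - cy))
        np.maximum(coverage, np.clip(width / 2.0 + 0.5 - d, 0.0, 1.0), out=coverage)
        mask |= d <= width / 2.0
    img = bg_gray + (fg_gray - bg_gray) * coverage
    return img, mask


def gen_fiber_image(params: FiberFieldParams):
    """Render a fiber field with known true widths.

    Returns ``(FiberImage, FiberFieldTruth)``.  Widths are drawn from the
    diameter law (nm, strictly positive), converted to pixels with the
    image scale; sub-resolution fibers (< 2 px wide) trigger a warning.
    Gaussian blur and additive Gaussian noise follow rendering.
    """
    from scipy.ndimage import gaussian_filter

    from .fiber_morphometry import FiberImage

    p = params
    rng = np.random.default_rng(p.seed)
    law = p.diameter_law
    if law["family"] == "constant":
        widths_nm = np.full(p.n_fibers, float(law["value_nm"]))
    else:
        widths_nm = np.exp(rng.normal(np.log(law["median_nm"]), law["sigma"], size=p.n_fibers))
    if np.any(widths_nm <= 0):
        raise ValueError("drawn diameters must be strictly positive")
    widths_px = widths_nm / p.nm_per_pixel
    if np.any(widths_px < 2):
        warnings.warn("sub-resolution fibers (< 2 px wide) in the rendered field", stacklevel=2)
    h, w = p.image_size
    centers = np.column_stack([rng.uniform(0, h, p.n_fibers), rng.uniform(0, w, p.n_fibers)])
    angles = rng.uniform(0.0, np.pi, p.n_fibers)
    img, mask = render_fibers((h, w), centers, angles, widths_px, p.fg_gray, p.bg_gray)
    if p.blur_sigma > 0:
        img = gaussian_filter(img, p.blur_sigma)
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    return FiberImage(pixels=img, nm_per_pixel=p.nm_per_pixel), FiberFieldTruth(
        widths_nm=widths_nm, mask=mask
    )


# ---------------------------------------------------------------------------
# clottability

def gen_clottability_course(
    initial_ct_s: float = 10.0,
    prolongation_rate_per_min: float = 0.12,
    censor_threshold_s: float = CENSOR_THRESHOLD_S,
    sampling_times_min=(0, 5, 10, 15, 20, 30, 45, 60),
    noise_sd_s: float = 0.0,
    seed: int | None = None,
) -> ClottabilityCourse:
    """Clotting-time course of fibrinogen under progressive digestion.

    The expected clotting time grows exponentially,
    ct(t) = initial_ct * exp(rate * t) — monotone non-decreasing for
    rate >= 0 — starting from the conventional 10 s with undigested
    fibrinogen.  Optional Gaussian noise perturbs each reading (floored at
    a tenth of the initial value).  Readings beyond the censoring threshold
    come back flagged censored with display value 121 s.
    """
    if initial_ct_s <= 0:
        raise ValueError("initial_ct_s must be positive")
    if prolongation_rate_per_min < 0:
        raise ValueError("prolongation rate must be >= 0")
    t = np.asarray(sampling_times_min, dtype=float)
    if t.size == 0:
        raise ValueError("sampling_times_min must be non-empty")
    ct = initial_ct_s * np.exp(prolongation_rate_per_min * t)
    if noise_sd_s > 0:
        rng = np.random.default_rng(seed)
        ct = np.maximum(ct + rng.normal(0.0, noise_sd_s, size=ct.shape), 0.1 * initial_ct_s)
    return censor_course(t, ct, threshold_s=censor_threshold_s)
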