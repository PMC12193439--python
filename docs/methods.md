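# Methods

This note records the models, numerical choices and defaults behind each
analysis stage, what the synthetic generators emulate, and the known
limitations. Nothing here reports an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Turbidimetric waveform metrics

A clotting well's A340 trace is modeled operationally, not mechanistically:
the metrics are defined directly on the recorded curve. A_max is the global
absorbance maximum above baseline (ties broken to the earliest time, so a
noiseless plateau reports its onset). CT90/CT50 are the first times on the
ascending branch (t ≤ t_Amax) at which the linearly interpolated signal
reaches 90%/50% of the baseline-to-maximum amplitude; LT50 is the first
post-peak time at which it falls back to 50%, minus the assay origin
(0 for intrinsic lysis, the lytic-agent addition time for extrinsic
lysis). Linear interpolation between samples resolves crossings below the
sampling interval and makes every metric exactly invariant under affine
transforms of the absorbance axis — normalizing a trace to [0, 1] changes
no metric time.

Choices where the assay convention is silent:

- **Baseline** defaults to the first reading, overridable per trace.
- **Minimum clot amplitude** 0.05 AU above baseline; below it a well is
  flagged `no_clotting` rather than yielding meaningless crossing times.
- **Smoothing**: none by default. A centered moving average (odd window)
  is available because noisy descending branches can cross half-maximum
  several times; with or without smoothing the *first* crossing wins, a
  deterministic tie-break.
- When the curve never descends to half-maximum the well is flagged
  `incomplete_lysis` (plus `no_lysis` when turbidity never meaningfully
  descended at all) and LT50 is undefined rather than extrapolated.
- A QC helper checks that a lytic well's A_max stays within ±10% of its
  non-lytic reference, the usual validity criterion for lysis assays.
- Whether a plasma-clot "clotting time" means CT90 or CT50 varies between
  laboratories; both are always computed and the report metric is a config
  option (`StudyConfig.metric`).

## Darcy permeability

K_s = Q·n·L/(t·A·ΔP) in cm², evaluated over the full analysis window:
Q = π(d/2)² × cumulative tube advance, t the elapsed time between the
first and last reading at or after a configurable start offset (default
0 s; set it to exclude an initial wash period). Constants default to the
conventional fibrin-permeation configuration — n = 1e-7 N·s/cm²,
L = 1.5 cm, A = 0.09 cm², ΔP = 0.170 N/cm² — and the tubing inner
diameter is deliberately mandatory: it is instrument-specific and K_s
scales with d². Per-interval volumetric rates are always returned, and a
coefficient of variation above 20% (configurable) flags `unsteady_flow`
(clot rupture or leak). Decreasing cumulative readings are rejected as
reading errors. Whether t should be the full window or per-interval is
ambiguous in common write-ups; the full window is used (it is the minimum-
variance choice for a constant rate) with the per-interval rates exposed
for inspection.

## Rheometry

Plateau G′ and G″ are means over the final 20% (configurable) of the
clotting phase; the loss tangent is their ratio. A non-positive plateau G′
raises a no-gel error.

On the stress ramp, the apparent viscosity is η = τ/γ̇ with γ̇ from
centered finite differences (one-sided at the ends); non-positive rates
are reported as +∞ with a flag. The gel–fluid transition is declared at
the first ramp point where η drops below (running max of η)/10. The fall
factor 10 quantifies "abrupt": a true gel→flow transition drops η by
orders of magnitude, so on sharp yields the detection is insensitive to
the exact factor (10 vs 100 give the same point), while mild noise cannot
trigger it. γ_max and τ0 are the strain and stress at the last point
before the transition. Inside the detector, strain rates use *backward*
differences: a centered difference at the last pre-yield sample already
sees the post-yield strain jump and would bias the reported stress one
ramp step low. Instruments that export η directly are accepted via the
`eta_Pa_s` argument.

## Fiber morphometry

Fibers are segmented with Otsu's global threshold after optional Gaussian
denoising (σ = 1 px default), with small objects removed and an
inverted-contrast flag for dark-fiber images. The mask is skeletonized and
the local diameter at a skeleton point is (2·EDT_w − 1) px × nm/px, where
EDT_w is the maximum of the Euclidean distance transform over valid
skeleton points in a 5×5 window. Two discretization effects motivate this:
the EDT measures to the nearest background pixel *center*, overshooting
the mask boundary by half a pixel per side (the −1 px), and the discrete
skeleton wobbles ±0.5 px around the true axis on oblique fibers, biasing
per-point EDT low (the windowed maximum). Together they hold the recovered
width within one pixel of truth for straight fibers of 4–30 px at any
orientation.

Skeleton points near junctions are excluded — fiber crossings are not
fibers — with the exclusion radius taken from the *branch point's* own
half-width, because spur points at crossings and clipped fiber ends carry
spuriously small distances of their own. Points whose EDT disk extends
beyond the image frame are likewise dropped. From the surviving points,
300 (configurable) are drawn uniformly without replacement under a seed;
a smaller pool returns everything with a `shortfall` flag.

Quantiles use the inverse-ECDF convention (`numpy` `inverted_cdf`), so the
quartiles of {90, 95, 100} are 90 and 100 (IQR 10), matching hand
computation on small samples; the method is a parameter. Because
"low-bottom quartile" is used ambiguously in the field, both Q1 and the
IQR are reported. The 2-D projection bias of SEM (apparent width of a
cylinder) is accepted as-is, matching laboratory practice.

## Distribution statistics

Diameter distributions are compared through a fitted theoretical family —
lognormal by default, the standard choice for fiber diameters, with gamma
and normal selectable; lognormal and normal use closed-form MLE, gamma
scipy's numerical MLE with location fixed at 0. Kuiper's V = D⁺ + D⁻ is
used as the distance: unlike KS it weights the tails evenly, which matters
for skewed diameter data. Because the reference distribution is *fitted*,
naive critical values are anti-conservative; the p-value therefore comes
from a parametric bootstrap: n_mc (default 10,000) synthetic sample pairs
of matching sizes are drawn from the pooled fit and the *identical*
fit-plus-statistic procedure is re-run on each. The add-one estimator
p = (1 + #{V_mc ≥ V_obs})/(n_mc + 1) avoids p = 0 and is deterministic
given the seed. Whether the reference is fitted to the second sample or to
the pool is a flag (`fit_to="other"`/`"pooled"`, default `"other"`);
comparing a sample against itself is biased toward large p (the reference
fit is maximally adapted) but not pinned at 1, since the null pairs are
independent.

The two-sample KS test computes D = sup|ECDF_a − ECDF_b| over all jump
points (tie-safe). The p-value is exact by full enumeration of pooled-rank
partitions when min(n_a, n_b) ≤ 10 and the pooled data are tie-free — all
C(n, n_a) assignments are equally likely under the null — and otherwise
uses the asymptotic Kolmogorov distribution with the standard small-sample
effective-n correction.

## Clottability

Raw clotting-time readings over digestion time are censored by the
standard rule: strictly greater than 120 s (or an instrument no-clot flag)
means non-clottable, displayed as 121 s for plotting; exactly 120 s is not
censored. Censoring is idempotent. The time to non-clottability is the
earliest digestion time with a censored reading, on the discrete
withdrawal grid — no interpolation, because samples are physically
withdrawn at those times and nothing is observed between them.

## Synthetic generators

All generators draw every random number from a single integer seed per
call (no global state) and are bit-reproducible.

- **Turbidity**: rise and fall are finite-support smoothstep branches
  (3u² − 2u³), scaled between baseline and A_max. Unlike logistic
  branches, smoothsteps reach their extremes exactly, so the noiseless
  curve attains A_max exactly and crosses half-amplitude exactly at the
  programmed CT50 and LT50 — the analysis round trip is exact up to
  interpolation on the sampling grid. Steepness parameters are the maximal
  slope of the normalized branch (half-width 0.75/k). Noise is additive
  i.i.d. Gaussian on absorbance, the simplest defensible plate-reader
  model. Defaults: baseline 0.05 AU, A_max 0.8 AU, CT50 600 s, LT50
  2400 s, 10 s sampling (a typical plate-reader cadence; the protocol
  convention does not fix one), 3600 s duration.
- **Permeation**: constant-rate cumulative advance implied by the
  programmed K_s (default 0.29e-9 cm², a typical pure-fibrin value)
  through the Darcy relation, read every 10 min for 2 h, with optional
  Gaussian reading noise in mm (monotonized, since a cumulative reading
  cannot run backwards). The generator's tubing inner diameter is 0.2 cm,
  which yields ~6 mm advance per 10 min — a realistic reading pace.
- **Rheometry**: moduli rise along a smoothstep to sit exactly on their
  plateaus (defaults G′ = 34.6 Pa, G″ = 2.8 Pa, typical of a pure fibrin
  gel). The ramp applies log-spaced stress steps 0.01→1000 Pa over 300 s.
  Pre-yield strain follows γ(τ) = τ/G′ + (γ_max − τ0/G′)(τ/τ0)²: Hookean
  compliance at small stress, bending to hit γ_max exactly at τ0 (defaults
  γ_max = 1.9, τ0 = 100.4 Pa). Monotone strain requires
  γ_max > τ0/(2G′); inconsistent triples are rejected. Beyond τ0 the
  sample flows as a Newtonian fluid 1000× less viscous than the last
  pre-yield apparent viscosity — an unambiguous, abrupt transition.
- **Fiber fields**: straight anti-aliased full-length fibers with uniform
  random orientation and centers, widths drawn from a lognormal (median
  95 nm, σ_log 0.35 by default, at 8 nm/px) or held constant, composed by
  maximum coverage, then Gaussian blur (σ 1 px) and additive noise (5 gray
  levels). Straight segments keep the drawn widths exact ground truth;
  curvature and branching alter network topology, not the diameter-
  recovery question. Sub-resolution widths (< 2 px) warn.
- **Clottability**: exponentially prolonging expected clotting time
  ct(t) = ct₀·exp(rate·t) from the conventional 10 s start, optional
  Gaussian reading noise, then the standard censoring rule.

What passing tests on these generators do **not** show: real turbidity
curves have asymmetric, multi-phase rises and drifting baselines; real
permeation series suffer clot compaction and rupture; real gels
strain-stiffen continuously rather than yielding at a single point; real
SEM fields contain curved, branching, three-dimensionally overlapping
fibers with texture noise; real digestion courses have heteroscedastic
coagulometer error. The generators validate the *measurement* chain under
controlled truth, not the biology.

## Problem sizes in the validation suite

The test suite and acceptance script use: 1,000 noisy traces for waveform
recovery; a 10×10 (τ0, γ_max) grid (stiffness tied to the yield point via
G′ = 2τ0/γ_max so every combination is generable); fiber widths 4–30 px
plus ten 512² lognormal fields; every tie-free KS rank partition at
n = 3–4 per group; 500 null and 200 shifted repetitions of the Kuiper
Monte-Carlo test at n = 300 per group with n_mc = 1,000 (the vectorized
closed-form-MLE null makes this cheap; production use defaults to
n_mc = 10,000); and an 8+8-well end-to-end plate.

## Known limitations

- The mixed-field pooled fiber median runs a few percent low against the
  drawn-width median: skeleton sampling weights fibers by visible length,
  junction exclusion removes crossing-rich (locally thicker) regions, and
  oblique quantization biases individual points slightly low. Recovery
  stays within 10% at the default field density.
- The exact KS enumeration is O(C(n_a+n_b, n_a)) and is capped at
  min(n) ≤ 10; ties always fall through to the asymptotic path.
- Kuiper MC replicates refit by closed form only for lognormal/normal;
  gamma nulls loop and are correspondingly slower.
- The flow-limit detector assumes a non-decreasing stress ramp; stress-
  controlled oscillatory sweeps or LAOS analysis are out of scope, as are
  curve deconvolution of turbidity into rate constants, capillary pore-
  radius models beyond K_s, and 3-D network reconstruction.
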