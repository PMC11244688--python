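# Methods

## Signal model

The detector signal model treats a single PBS spot as an isotropic 2D
Gaussian fluence of standard deviation σ (mm) at the detector plane and a
detector as a centred circular aperture of diameter d (mm). The
normalized signal S(r) is the aperture integral of the Gaussian displaced
radially by r, divided by its value at r = 0. Isotropy is justified for
this use because measured spot ellipticity is below 1.1 and σ is taken as
the mean of the two axes; the model therefore depends on |offset| only.

Defaults: σ = 4.8 mm with d = 13.8 mm for the central-axis chamber
(centering/isocenter-coincidence QA) and σ = 2.2 mm with d = 0.8 mm for
the four positioning diodes. The diode is modelled as a 0.8 mm disk even
though the physical element is a 0.8 × 0.8 mm square: at these σ/d ratios
the aperture shape contributes far less than the sigma uncertainty, and
the circular region keeps the model strictly axisymmetric. Both σ and d
are per-detector configurable (YAML geometry file).

Numerics: the disk integral uses a Gauss–Legendre product rule in polar
coordinates, 64 radial × 64 angular nodes. Against the closed-form disk
probability of a noncentral bivariate normal (expressible through the
noncentral χ² CDF with 2 degrees of freedom) the rule agrees to ~1e-14
over σ ∈ [1, 10] mm, d ∈ [0.8, 13.8] mm, r ∈ [0, 5] mm. The closed form
is deliberately kept out of the production path and used only as an
independent oracle in the tests: the quadrature generalizes unchanged to
non-circular apertures. S(0) is pinned to exactly 1 by normalization.
Nodes and the r = 0 normalization integral are cached per (σ, d).

All lengths are mm; S is a fraction in (0, 1]; percentages appear only at
reporting boundaries.

## Offset estimation

The five-position measurement (aligned plus ±δ couch shifts in each axis,
δ = 1.5 mm by default — of the order of the spot size, as it must be for
sensitivity) yields asymmetries Ax, Ay. The production inversion uses the
decoupled 1D model A(dx) = (S(dx+δ,0) − S(dx−δ,0))/S(dx,0), which is odd
and strictly monotone on [−3, 3] mm for both detector models; Brent root
finding on that bracket converges to 1e-4 mm. Asymmetries outside the
attainable range raise an error — a gross (> 3 mm) misalignment must be
investigated, not extrapolated.

The fully coupled 2D system is implemented as an alternating-1D
fixed-point solver and used as a test oracle: with a 3 mm transverse
offset the decoupled estimate differs from the coupled solution by less
than 0.05 mm for the chamber, which is why the decoupling is acceptable
below 3 mm.

Sign convention (the measurement itself does not fix one): offsets are
spot minus detector in the room frame, and a +δ couch shift samples
S(offset + δ), making A decreasing in the offset. Any self-consistent
convention gives identical magnitudes; the synthetic generator enforces
this one, and a per-room flip is a config concern outside the estimator.

Sensitivity: inverting one and the same measured asymmetry with the spot
sigma mis-assumed by ±10 % displaces a 1.5 mm diode estimate by up to
≈ 0.25 mm (≈ 0.22 mm for the −10 % case) and a chamber estimate by
≈ 0.10–0.14 mm; the induced relative error in S(1.5) is at most ≈ 5.2 %
for the diode. These are the numbers that bound the clinical impact of
the single-sigma simplification.

## Rice calibration and thresholds

Per-day offsets over an N-day campaign (default 20) are reduced to
ν = mean of the per-day radial distances and σxy = max of the per-axis
sample standard deviations (n−1). Two deliberate estimator choices:

* ν as the mean radial distance is a biased estimator of the Rice
  noncentrality (it converges to the Rice *mean*, not to the distance of
  the bivariate mean from the origin). It is kept exactly as defined
  because the downstream Δ̄ is computed from this same ν, so the bias is
  absorbed by construction; tests therefore compare the recovered ν to
  the generator's Rice mean, not to its μ-distance.
* taking the larger per-axis std is conservative: it inflates Δ̄ and
  hence the threshold band.

Δ̄ is the Rice mean σxy√(π/2)·L_{1/2}(−ν²/2σxy²), evaluated through
exponentially scaled Bessel functions (i0e, i1e) so it is stable for any
ν/σxy. The 1σ bounds are Δ̄ ∓ the Rice standard deviation
√(ν² + 2σxy² − Δ̄²), floored at 0. These bounds reproduce the published
calibration-table parentheses to ≈ 0.02 mm; quantile-based (16/84)
bounds were considered and rejected because the mean ± sd form matches
the published ranges more closely and is what the advisory band is
defined from. A campaign with zero spread raises a diagnostic (the Rice
model is undefined) instead of silently returning Δ̄ = ν.

Thresholds: th = D̄0 · S(tol)/S(Δ̄) per detector, with D̄0 compiled
separately per plan configuration (the central spot energies differ
between configurations, so the aligned-signal baselines do, while Δ̄ is
shared — setup errors do not depend on the delivered plan). The 1σ
threshold band uses S at the Δ̄ bounds. Default tolerance 1.5 mm for
both positioning and centering; configurable (e.g. 2.0/1.0 mm for
TG-224-style settings).

## Range and output QA

Range constancy is monitored by distal-edge/plateau chamber signal ratios
(TL/BL and BR/TR). Tolerances are purely empirical: the ratio measured
with 1 mm added plastic water is the reference and the ratios at 0 and
2 mm are the upper/lower bounds, realizing ±1 mm without any analytic
depth-dose model. Calibration curves are monotone piecewise-linearly
interpolated, rejected if non-decreasing anywhere (a flat segment cannot
define a bound), never extrapolated, and per-gantry/per-configuration
(fabricated acrylic dimensions differ between rooms). Ratios outside
[0.2, 0.8] are flagged as insensitive but still returned. Output
constancy is a ±3 % band on the ≥ 20-day campaign mean of each plateau
chamber signal.

Note an intrinsic edge property of this band construction: a WET fault of
exactly ±1 mm places the daily ratio *at* the band limit, so under
symmetric noise its detection probability is ~50 % by construction;
faults of 1.5 mm and beyond are detected essentially always at realistic
noise (0.5 % CV). The daily check is therefore a guarantee against
errors clearly exceeding 1 mm, not a razor edge at 1 mm.

## Daily evaluation and trends

Daily exports carry net counts, irradiation time, temperature and
pressure. Vented ionization chambers are corrected by
k_TP = ((273.15+T)/(273.15+T_ref)) · (P_ref/P) with defaults
T_ref = 20 °C, P_ref = 101.325 kPa; diodes are density-insensitive
(k_TP = 1). The exact vendor count-processing formula is proprietary, so
net-counts × k_TP is the package's declared signal definition, and the
open CSV dialects (versioned headers, strict schemas) replace the vendor
export format. Records with implausible environment values (T outside
10–40 °C, P outside 80–110 kPa) are rejected.

Verdicts: positioning/centering pass iff signal ≥ mean-based threshold;
falling inside the 1σ band is annotated but never blocking — the band is
confidence information, not a limit. Range and output verdicts are
exhaustive and mutually exclusive. The trend store is an append-only CSV
keyed by (date, gantry, config); re-appending a stored day is refused.
Trend summaries report COV (100·sd/mean, sample sd) and min/max percent
deviations per detector and configuration; diode COVs exceed chamber
COVs because the small aperture amplifies positional noise.

## Synthetic data

The generator emulates exactly the statistical model the framework
assumes: per-day offsets bivariate normal with mean (μx, μy) and common
spread σ_setup (so radial offsets are Rice by construction; an
unequal-axis mode exists for robustness probing but nothing is asserted
on it), signals from the aperture-integrated model at the five couch
positions, multiplicative noise with configurable CV (default 0.5 %,
consistent with observed chamber day-to-day variability), and a
complementary-error-function falloff for the range-ratio sweep
(ratio(w) = ratio0·erfc((w−2.5)/3)/erfc(−2.5/3), defaults chosen to keep
the standard 0/1/2/4 mm sweep inside the sensitive [0.2, 0.8] band).
The falloff form is openly an invention — in the clinic this curve is
measured — and only its monotonicity and detectability properties are
relied upon. Fault-injection knobs: linear output drift, WET shift,
fixed extra displacement of one diode.

What passing tests do **not** show about real data: the generator has no
beam-delivery spot-position jitter distinct from setup error, no diode
sensitivity degradation with accumulated dose, no inter-detector
correlation beyond the shared daily displacement, and Gaussian noise with
a single CV for all detectors. Campaign-recovery results therefore
validate the estimation chain in-distribution, not the physical
assumptions themselves.

Default study conditions used by the tests: 20-day campaigns at
μ = (0.5, 0.2) mm, σ_setup = 0.25 mm, 0.5 % noise (replicated 500× for
coverage checks; 1000-day campaigns for consistency checks); all
generators are deterministic under a fixed seed.

## Known limitations

* Spot sigma is an input from commissioning, never estimated from the
  QA measurements themselves.
* Offsets beyond 3 mm are rejected, not estimated.
* No Bayesian/ML Rice fitting and no drift model for Δ̄; recalibration
  cadence is an operational policy outside the package.
* The vendor's absolute count formula is approximated by net counts ×
  k_TP; absolute dosimetry (TRS-398) and imaging-chain QA are out of
  scope.
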