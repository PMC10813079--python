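# Methods

## Scope and model

`stenoshear` estimates the maximum shear stress τmax in a stenosed artery
without running CFD, using only scalar descriptors available from routine
non-invasive imaging and flow measurement. The model has two stages.

**Baseline correlation.** For a reference stenosis geometry the peak shear
stress follows a power law in the upstream mean velocity `u` (m/s) and the
degree of stenosis `r = (Ac/A0)^0.5`:

    τ0 = α · u^β · r^γ,    α = 24.21 Pa·(s/m)^β, β = 1.346, γ = −3.385.

τ0 is strictly increasing in `u` and, since γ < 0, strictly decreasing in
`r` (tighter throats give higher stress). The constants are configuration
with these fixed defaults; the package never refits them.

**Shape corrections.** Departures of a measured stenosis from the
reference geometry are absorbed by three multiplicative coefficients read
from tables of CFD results, each indexed by velocity (10 nodes,
0.053–0.529 m/s) and one dimensionless shape parameter:

- β1(u, k), vessel scale `k = Dh,inlet / Dh0` with `Dh0 = 3.83` mm, tabulated
  at k ∈ {0.50, 0.75, 1.00, 1.25}. Smaller vessels concentrate the jet and
  raise stress (β1 > 1 for k < 1).
- β2(u, z), dimensionless stenosis length `z = l / (k·Dh0)`, tabulated at
  z ∈ {1.04, …, 4.17}. Shorter, sharper stenoses accelerate flow faster
  (β2 > 1 for z < 4.17).
- β3(u, w), throat flattening `w = dh,throat / (k·Dh)` with `Dh = 1.15` mm
  (the circular throat of the degree-0.3 reference), tabulated at
  w ∈ {0.70, 0.86, 0.96, 1.00}. Its influence is small except for strongly
  flattened throats, so when the throat lumen is not measured β3 defaults
  to 1 and the prediction carries a `beta3_defaulted` flag.

The reference constants come from a 4 mm idealised vessel with a 16 mm
stenosis: the size/length tables were generated against its degree-0.4
variant (throat Dh 1.53 mm), the flattening table against its degree-0.3
variant (throat Dh 1.15 mm). The corrected prediction is the product
τmax = τ0·β1·β2·β3, with every clamp/extrapolation surfaced as a
provenance flag on the prediction and logged as a warning.

## Interpolation and extrapolation

- **In-table queries** use shape-preserving piecewise cubic interpolation
  (PCHIP), along the velocity axis first and then along the shape axis.
  PCHIP is exact at every tabulated node and cannot overshoot the
  bracketing node values — important on 4-node shape axes where an
  unconstrained cubic spline can ring. The axis order is exposed as a
  config switch (`velocity_first`); on these grids the two orders agree to
  well under 1 %.
- **Scale extrapolation.** Real vessels routinely fall outside the
  tabulated k range (the packaged carotid case has k ≈ 1.98). β1 is then
  extrapolated with a per-velocity power law a·k^b fitted by log-log least
  squares over the four tabulated k nodes; every fit's R² exceeds 0.999.
  This recovers the published worked-example coefficients
  (0.6179/0.6436/0.6829) to better than 0.2 %.
- **Clamping.** Velocities outside 0.053–0.529 m/s clamp to the nearest
  table row (the coefficients flatten with velocity, so this is mild and
  conservative); z above 4.17 clamps to β2 = 1 (longer stenoses are
  milder); z below 1.04 and w outside 0.70–1.00 clamp to the nearest
  column. Every clamp sets a flag.

## Risk classification and critical velocity

Predictions are thresholded at 150 Pa by default, a widely used onset
level for shear-induced red-cell damage; the boundary case counts as
at-risk (the conservative screening choice) and the threshold is
configurable. The threshold is applied to the predicted maximum
(mid-jet) stress, matching how the worked example used it, although the
literature value is usually quoted for wall shear stress.

The critical velocity u\* is the root of τmax(u) = threshold over
u ∈ [0.01, 2.0] m/s, found with Brent's bracketed method (τmax is strictly
increasing in u, so the root is unique; convergence is verified to an
excess below 1e−4 of the threshold). If even 2 m/s does not reach the
threshold the case is reported as "no risk in range"; if 0.01 m/s already
exceeds it, the floor is returned with a flag. When all correction factors
are 1 the result matches the closed-form inversion
u\* = (threshold/(α·r^γ))^(1/β) to <0.1 %.

## Hemolysis fraction

The released-hemoglobin fraction uses a population-balance description of
blood: red cells exist as single cells (number concentration ms, size L0)
and as agglomerates represented by three quadrature nodes (weights wᵢ,
sizes Lᵢ). Only single cells are damaged, so

    ΔHb/Hb = H · ms·L0³ / (ms·L0³ + Σᵢ wᵢ·Lᵢ³),

which is bounded in [0, H], equals H when all cells are single, 0 when
none are, and is invariant under common rescaling of all concentrations or
of all lengths. The single-cell damage level H comes from an upstream
power-law damage model whose constitutive form (and residence-time
dependence) is outside this package's scope; H is therefore an input, and
the function is exposed purely in terms of its arguments.

## Units and interfaces

Clinical units at every interface — mm, mm², mL/s — with velocities in m/s
and stresses in Pa; conversion to SI happens exactly once inside the
functions that need it. Flow↔velocity conversion assumes a circular
cross-section with diameter equal to the hydraulic diameter unless an
explicit area is supplied; this reproduces measured flow/velocity pairs to
<2 %, and a measured velocity and flow that disagree by more than 2 %
(configurable) are rejected as inconsistent. Cohorts are plain CSV, one
row per (case, flow condition); reports are emitted as CSV (stresses to
0.1 Pa) and full-precision JSON.

## Synthetic cohorts

`FixtureSpec`/`generate_fixture_cohort` draw reproducible cohorts
uniformly over the validity region of the correction tables: inlet
hydraulic diameter 2–10 mm, degree of stenosis 0.2–0.8, stenosis length
4–20 mm, upstream velocity 0.05–0.53 m/s. Half the cases (by default)
carry a measured throat diameter, drawn between 70 % and 100 % of the
equal-area circular throat (degree × inlet diameter) to emulate realistic
lumen flattening. The generator emulates the scalar inputs a screening
cohort would provide — it does not emulate imaging noise, intra-observer
variability in where a stenosis "begins", or correlations between degree
and length in real plaques, so passing tests demonstrate the pipeline's
correctness and determinism on in-range inputs, not clinical accuracy.

## Known limitations and open choices

- **The stenosis-length discrepancy.** For the packaged carotid case the
  length formula applied to the printed dimensions (l = 10 mm, k ≈ 1.98)
  gives z ≈ 1.32, whereas the published worked-example β2 values
  (1.14–1.25) imply a substantially larger effective z. The published
  account does not state which length entered the tables. The package
  computes z strictly from its defining formula and keeps the published
  coefficients as reference data (`ica_case.REFERENCE`); the demo prints
  both side by side. Consequence: for vessels whose diameter changes
  sharply across the stenosis, the onset-to-maximum distance may
  understate the effective stenosis length and overstate β2.
- The correction tables were generated at fixed degrees of stenosis (0.4
  for scale/length, 0.3 for flattening) but are applied at arbitrary
  degree through τ0, exactly as the worked example does at degree 0.29;
  the multiplicative, separable form of the correction is assumed, not
  validated for simultaneous large deviations in k, z and w.
- Steady-flow model: no pulsatility; the baseline correlation was built
  for quasi-steady conditions where time-averaged and steady wall shear
  differ little.
- No spatial fields: the package predicts the scalar peak stress and a
  risk class, not where in the vessel the threshold is exceeded or the
  exposed fluid volume.
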