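# Methods

## Stage models and their assumptions

The compaction cycle is modeled as four quasi-static stages evaluated at
steady state, with run-level responses (the mean over the ~50 tablets measured
per run). All lengths are in mm, densities in g/cm³, pressures in MPa and
forces in kN; the Kawakita force is (πD²/4 mm²) × (1/b MPa) → N, reported in
kN. Tablet and fill volumes use the convex-tablet formula
V = πD²t/4 + (πh/6)(3D²/4 + h²) for D-tooling with cup depth h, and relative
densities are ρ = W/(ρ_t V). Hardness readings are converted to tensile
strength with Pitt's formula for convex tablets,
σ_t = (10F/πD²)/(2.84H/D − 0.126H/t + 3.15t/D + 0.01) with overall thickness
H = t + 2h; the rendering ambiguity of the source expression was resolved to
this standard grouping. Below their onset densities the Kawakita force,
elastic recovery and tensile strength evaluate to zero rather than raising, so
optimizer exploration of the parameter space stays well defined; the Kawakita
singularity (degree of compression reaching the total compressibility a) is an
error in strict mode and a large finite clamp inside the fitter.

Tablet density uses the multiplicative unloading convention
ρ_tablet = ρ_in-die(1 − ε); the alternative 1/(1+ε) thickness-strain
convention is not used. The filling-efficacy family contains the legacy
two-parameter linear form (η = 1 − ξ₁n_T/n_F + ξ₂t_fill/D) behind a flag and
defaults to the second-order form in n_F/n_T and t_fill/D; the weight stage is
fitted in η (not W) because the two are algebraically equivalent at run level
and η isolates the die-filling physics from the bulk-density stage.

## Coupling to mixing and the model library

Concentration and mixing time are normalized onto [0, ∞) by
X = (c/(c_max − c))^rX, Y = (t/(t_max − t))^rY with c_max = 2% w/w (lubricant)
or 0.2% w/w (glidant) and t_max = 60 min. Total imparted shear is treated as
interchangeable with mixing time (batch blending at fixed speed), so only
t_mix is exposed. The exponents rX, rY ∈ (0, 10] are shared across all coupled
parameter functions of a stage — the only convention under which the library's
published parameter counts are reproducible (e.g. the (9,3,3) compaction
triple has 1 + 4 + 4 + 2 = 11 free parameters). Inputs within 10⁻⁹ of the
normalization bound are rejected as singular; designs sample strictly inside
the ranges.

The fifteen constrained variants and the admissible pair library (self-pairs,
pairs with the constant variant, and the constant with everything: 43 of 225)
are enumerated exactly. Compaction restricts attention to first-degree
variants and holds either a or 1/b constant: the triple library is
{(9,i,j)} ∪ {(i,9,j)} over the 25 restricted pair patterns (41 triples, a
superset of every published combination; the exact enumeration used originally
is not recorded, so the two-pattern rule is adopted as the natural closure).
The analytic corner limits are f(0,0) = f(∞,0) = f(0,∞) = p₄ for every
variant; the joint diagonal limit is p₁/q₁ for the first-degree family and
(p₁ + p₄(q₅+q₆))/(q₁+q₅+q₆) for the second-degree family, where XY and the
squared terms share the leading degree.

## Estimation and selection

The lower problem minimizes the run-level sum of squared errors per stage
(bulk density in kg/m³, η dimensionless, force in kN, tablet density
dimensionless, strength in MPa) under: positivity of all rational
coefficients, explored in log₁₀ space over (10⁻⁸, 10⁴]; unit-interval bounds
for relative quantities (a, ε₀, packing fraction and the onset densities),
applied to the whole parameter function over the campaign (values at the runs
plus the corner limits) via penalty residuals that vanish at any feasible
optimum; exponents and the recovery exponent n in (0, 10]. The global stage
screens 24×n_starts Latin-hypercube probes by raw cost and refines the best
n_starts (default 32) with bounded trust-region least squares, stopping early
at the measurement-resolution floor or after a patience budget without
improvement; everything is seeded. The weight stage is linear in ξ and fitted
by ordinary least squares over its five-member family.

The upper problem ranks combinations by AIC = n ln(SSE/n) + 2Np, plus the
second-order correction 2Np(Np+1)/(n−Np−1) when n < 30 (the n = 30 boundary is
uncorrected). Two numerical policies sit on top:

- **SSE floor.** SSE below 10⁻¹⁰ × SST is indistinguishable from perfect at
  measurement resolution, so ranking evaluates the criterion at the floor and
  ties resolve to fewer parameters (then lexicographic label). Without this, a
  noise-free campaign would rank its generating model against its own
  generalizations by meaningless trailing digits. Each result also stores its
  exact AIC, recomputable from (SSE, n, Np).
- **Warm-start cascade.** Combinations are fitted in order of increasing Np,
  each warm-started from the best simpler fits (a constant embeds exactly into
  any variant via p₄ = c, p₁ = c·q₁), which enforces the nesting property that
  a more general model never fits worse.

Sequential campaign fitting runs bulk density → weight → compaction →
recovery → strength. The staged onset bounds use the point estimate from the
stage upstream: the lower corner limit of the fitted ρ_c function bounds
ρ_c,ε, whose estimate bounds ρ_c,σ, each minus a slack of 0.01 because
published estimates sit within printing precision of their bound. Overfitting
is flagged post hoc when any coefficient exceeds 10³ × max(1, |p₄|) within its
function (threshold configurable); flagged fits stay in the ranking but are
skipped when naming the best model. Bootstrap uncertainty is case resampling
of whole runs (B = 1000 default, percentile 95% intervals), each resample
refitted from the point estimate plus a few fresh starts.

## Sensitivity analysis

First-order Sobol indices of the integrated stage models use a Saltelli-type
plan (`scipy.stats.sobol_indices`) with independent uniform inputs, N = 2¹⁴ by
default. Input ranges default to the campaign ranges; relative densities span
a realistic compaction window (in-die 0.4–0.9, tablet 0.5–0.9) since the
ranges behind the published table are not stated — consequently only the
analytically forced entries (an inactive input's 0, a sole active input's 1)
are treated as exact, and the remaining entries as qualitative.

## Synthetic campaigns

The generator emulates the two reference campaigns: Latin-hypercube designs
(scipy QMC) over concentration, mixing time, turret speed and dosing position
(20 runs for the lubricant campaign, 30 for the glidant campaign, at the
stated ranges), pushed through the published fitted models. Blend true density
is the inverse-mass-weighted mixture of 10% acetaminophen, the excipient and
microcrystalline cellulose, with component densities as configuration values
(1.293/1.56/1.09/2.2 g/cm³ for APAP/MCC/MgSt/CS — typical grades, not fitted
quantities). The feed-frame speed, not varied experimentally, is fixed at
30 rpm by default. Measurement noise is independent multiplicative Gaussian
per response with default CVs of 1% (densities, weight), 3% (force) and 5%
(hardness) — chosen so the published goodness-of-fit range (R² ≈ 0.7–0.99) is
attainable. Each downstream response is generated from the measured (noisy)
value of its upstream predictor, so a zero-noise campaign is an exact fixed
point of the fitting pipeline; tablet-level tables resample around run values
with the same CVs. Out-of-die density is clipped to never exceed in-die
density when noise is applied.

One deliberate deviation from the reference press setting: the generator
presses to a fixed in-die thickness of 3.2 mm (lubricant) or 4.0 mm (glidant)
rather than 2.44 mm, because under the published packing-fraction and
filling-efficacy models the stated dosing ranges at 2.44 mm imply in-die
relative densities well above 1 at the high-fill/high-concentration corner of
the design box. The chosen thicknesses keep the whole box below ρ ≈ 0.96.
Nothing downstream depends on the constant — the fitting pipeline reads the
per-run in-die thickness from the run table.

What passing tests on these campaigns do show: the estimator is an exact fixed
point at zero noise, the library machinery and selection behave as specified,
and recovery degrades gracefully with noise. What they cannot show: agreement
with the undeposited experimental data, realistic error correlation
structures (noise here is independent across responses and runs), or press
dynamics outside steady state.

## Known limitations

- At the default noise levels the weak glidant tensile signal is frequently
  absorbed by simpler nested models on parsimony grounds — the same AIC
  behavior the framework's post hoc overfit rule exists to counterbalance;
  selection results on noisy small campaigns should be read as rankings, not
  verdicts.
- Problem sizes in the test suite and acceptance checks are scaled (reduced
  multi-start budgets, 10 replicate campaigns) as the package's default smoke
  configuration; production fits should use the default 32 starts or more.
- Combined lubricant + glidant blends, ejection force, pre-compression
  density as a response, drug release, and continuous-blender shear models
  are out of scope.
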