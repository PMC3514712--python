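# Methods

## Shape model and superimposition

A specimen is a configuration of k homologous landmarks in d dimensions
(k ≥ 3, d ∈ {2, 3}; the reference use case is k = 18 left-side cranial
landmarks in 3D). Generalized Procrustes Analysis removes the non-shape
similarity parameters:

1. center each configuration at its centroid;
2. scale to unit centroid size (full Procrustes fitting; centroid size is
   `sqrt(Σᵢ ‖xᵢ − x̄‖²)`, in mm);
3. rotate each configuration to the current consensus by the SVD (Kabsch)
   solution, constrained to proper rotations — reflections are excluded
   because left/right anatomical homology is not mirror-symmetric;
4. re-estimate the consensus as the coordinate-wise mean, re-centered and
   rescaled to unit size; iterate 3–4 until the consensus moves less than
   `tol` in root-sum-square.

After convergence every aligned shape is projected orthogonally onto the
affine hyperplane tangent to the unit sphere at the consensus. All
downstream statistics operate on these tangent coordinates; the Procrustes
distance between two shapes from one superimposition is the Euclidean norm
of their flattened coordinate difference.

Assumptions: shape variation is small relative to the curvature of shape
space (so the tangent approximation is good — amply true for within-species
cranial data), and configurations are complete (missing landmarks are an
error, not imputed).

## Predictors

Three size variables enter on fixed analysis scales: brain size as the cube
root of endocranial volume (mm), chondrocranial length as the
hormion–opisthocranion interlandmark distance measured on *raw* (pre-GPA)
coordinates (mm), and overall size as the natural-log centroid size
(dimensionless). Natural log is the standard allometry convention. Predictor
shifts between groups are always expressed on the analysis scale when they
multiply regression coefficients, and as percent of the reference mean on
the raw scale (volume, mm, centroid size) when reported descriptively.

## Pooled-within-stratum regression

Shape is regressed on one scalar predictor with both sides centered by
stratum (sex) means, giving a single pooled slope `β` (k × d, Procrustes
units per predictor unit). This removes mean sexual dimorphism from the
slope without modelling sex-specific allometries. Derived quantities:

* **percent variance explained** = 100 · Σ‖x̃ᵢβ‖² / Σ‖Ỹᵢ‖², with both sums
  over stratum-centered tangent coordinates — identical to 100·(1 − RSS/TSS)
  of per-coordinate simple OLS;
* **projection scores** = ⟨Yᵢ − consensus, β/‖β‖⟩, computed from
  *uncentered* deviations so individual scores (dimorphism included) lie
  along the pooled axis, in Procrustes units;
* **predicted shape change** for a predictor shift Δx = |Δx|·‖β‖, the
  Procrustes distance between the predictions at x and x + Δx.

Significance: the predictor is permuted within strata, the superimposition
held fixed (it does not depend on the predictor, so re-running GPA per
permutation would change nothing but run time). The statistic is the
predicted sum of squares; p = (1 + #{perm ≥ obs}) / (n_perm + 1), so the
smallest attainable p is 1/(n_perm + 1) and p = 0 is impossible.

## Group contrasts and the funneling comparison

All specimens entering a contrast (reference and perturbed group) are
superimposed jointly — Procrustes distance between group means is only
defined in a common shape space. The effect vector is `alt mean − ref mean`
in tangent coordinates; its norm is the contrast distance; group labels are
permuted for the p-value with the same add-one convention. The distance
estimator is upward-biased by sampling noise (‖·‖ of a noisy mean
difference); no bias correction is applied, matching standard practice, and
the bias is quantified in the tests.

The funneling comparison confronts a mutant contrast with the normal
covariation structure: predicted distance = |measured predictor shift| ·
‖β‖, reported with the observed/predicted ratio and the angle between the
effect vector and the regression vector oriented by the sign of the shift
(a negative shift should displace shapes along −β). The regression is
fitted on the normal (wildtype) specimens within the joint superimposition,
so both vectors live in one space. Angles are never computed across
superimpositions of different species: with large mean-shape differences
the same coordinate displacement can mean different biology, so
cross-species comparison is left to side-by-side visualization.

## Thin-plate spline grids

Deformation grids use the 2D biharmonic TPS with kernel U(r) = r² log r:
the exact interpolant solving the bordered system [[K, P], [Pᵀ, 0]], with
bending energy Σ_dims wᵀKw (zero iff the map is affine). 3D shapes are
first projected orthogonally onto a viewing plane (axis pair or arbitrary
normal); grids warp a grid_n × grid_n lattice over the reference bounding
box padded 10%. Because real shape differences are visually tiny, the
deformation is magnified by an explicit, user-supplied factor recorded in
every output; no default exaggeration is hidden.

## Synthetic data generator

The generator draws populations from exactly the model class the analysis
assumes — by design, so that parameter-recovery tests are meaningful:

    shape_i = template + Σ_e slope_e (x_{ie} − mean_e) V_e
              + sex_offset·1[male] + ε_i,      ε_i ~ N(0, noise_sd² I)

followed by a per-specimen nuisance similarity transform (uniform random
proper rotation, translation, and a scale of base_scale — or exp(latent)
when an effect is flagged as the log-size latent — times optional jitter).
Latents are independent normals on their analysis scales. Effect vectors
are stored unit-norm, orthogonal to the similarity directions at the
template (translations, scaling, infinitesimal rotations), and mutually
orthogonalised, so nominal slopes survive GPA and variance fractions add.
Seeding: one `SeedSequence` per dataset spawns one child per specimen, so
specimen i depends only on (seed, i) and growing n preserves earlier
specimens.

The built-in template is an 18-landmark 3D half-cranium-like configuration
with standard cranial landmark names at fixed, plausible coordinates; it
carries no anatomical authority and exists for determinism and for named
landmark predictors.

Default study conditions (`mouse_study_spec`) emulate a wildtype-mouse
regime: n = 48, predictor coefficients of variation 0.048 (brain, mean
7.66 mm cube-root volume), 0.024 (chondrocranial length, mean set to the
template's scaled hormion–opisthocranion distance ≈ 9.83 mm) and 0.017
(log centroid size, mean ln 30), with per-coordinate tangent noise
noise_sd = 0.006. With 3k − 7 = 47 effective shape dimensions the noise
floor is ≈ 47·(0.006)² ≈ 1.7·10⁻³ Procrustes variance, and the slopes
(0.0261, 0.0519, 0.2389 per analysis unit) were set once from the error
budget so each predictor explains a low-single-digit to ~10% share of total
variance — the regime the method is designed for. The chondro vector's
separation/doming mix is calibrated so one mm of the latent changes the
measured hormion–opisthocranion distance by one mm.

What the generator does **not** emulate: correlated latents (real size
measures co-vary; here they are independent, so e.g. the measured
chondrocranial length inherits extra variance from overall scale and its
CV exceeds the latent's 0.024), non-linear or landmark-heteroscedastic
effects, digitization error structure, and any real anatomical covariance.
Passing recovery tests therefore demonstrates correctness of the estimators
under the assumed model, not robustness to violations of it.

## Numerical choices

* GPA convergence: tol = 1e-10 on consensus change, max_iter = 100 — far
  below data noise at negligible cost; non-convergence returns a flagged
  result with a warning rather than raising.
* Degenerate rotation SVDs are made deterministic by a sign convention
  (largest-magnitude element of each left singular vector positive); a
  reflection optimum is handled by flipping the smallest singular direction.
* Angles use the 2·atan2(‖û−ŵ‖, ‖û+ŵ‖) form, exact near 0° and 180° where
  arccos loses precision.
* TPS systems are solved densely; collinear or duplicate control points are
  rejected by an explicit rank/uniqueness check; tiny negative bending
  energies from round-off are clamped to zero.
* CSV IO parses floats in round-trip mode; the TPS format writes 6 decimal
  places (its conventional precision), CSV full precision.
* Coefficient of variation uses the n−1 standard deviation.

## Test design

Noiseless identity tests (exact recovery of the generating vector, funneling
ratio 1, angle 0) run in a small-effect regime (slope × predictor spread
~10⁻⁴–10⁻⁵) with the nuisance rotation disabled: projection onto the
unit-size sphere makes large effects intrinsically non-linear — the
deviation is O((slope·spread)²) — and a random per-dataset rotation would
make coefficient frames incomparable. Where frames must be compared under
random rotations, the estimated coefficients are rotated into the template
frame via the consensus-to-template Procrustes rotation.

Statistical checks use deliberately modest problem sizes chosen for tight
Monte-Carlo bounds at desk scale: permutation-calibration runs 500 null
replicates (n = 24, n_perm = 199) against the exact binomial 99% interval;
noisy funneling recovery runs 200 replicates at n = 100 normals / 30
mutants with noise_sd = 0.002 (chosen a priori so distance bias and slope
inflation are each a few percent); angle convergence uses n ∈ {25, 100,
400}. The funneling ratio always uses the *measured* predictor shift
between the realized groups, as the method defines it — using the nominal
simulation shift would add predictor-sampling noise that the real analysis
never sees.

## Known limitations

* Tangent-space statistics assume small shape variation; gross shape
  differences (cross-species) would need curved-space methods.
* Projection scores use the pooled vector; sex-specific allometries are out
  of model.
* The contrast distance has an uncorrected upward noise bias, relevant for
  very small groups.
* Semilandmarks, missing-landmark imputation and 3D TPS warps are out of
  scope; grids are 2D projections.
* Permutation p-values are conditional on the observed superimposition;
  uncertainty in the consensus itself is not propagated.
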