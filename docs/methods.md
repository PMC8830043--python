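# Methods

## Problem setting

In multi-center surface-based morphometry, two vertex-wise maps are compared
between patient groups and controls: cortical thickness (mm) and cortical
mean diffusivity (cMD, mm²/s) sampled inside the gray-matter ribbon. cMD is
sensitive to microstructural disorganization and can change over a wider
territory than macroscopic thinning; the pipeline quantifies that
dissociation. Because real multi-center MRI cannot ship with the code, the
package includes a first-class phantom generator so each stage — and the
pipeline as a whole — is validated against known ground truth.

## Diffusion tensor fit

Per voxel, ordinary least squares on the log signal:

    ln S(g, b) = ln S0 − b gᵀ D g

with design columns `[1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz,
−2b gy gz]`. This is the default behavior of standard DTI fitting tools, is
deterministic, and is exact to machine precision on noiseless data (a
property the tests assert). Choices:

- Non-positive signals are clamped to `1e−6 · S0` (S0 = median b=0 signal)
  so the log exists; affected voxels are flagged `clamped`.
- MD is the raw trace/3 without eigenvalue clipping; negative-definite fits
  are flagged for QC but not altered.
- The protocol must contain ≥1 b=0 volume and ≥6 non-collinear b>0 unit
  directions; a rank-deficient gradient scheme is a hard error naming the
  defect. b-values are fully configurable (acquisitions differ per scanner).
- Motion/eddy correction and diffusion→anatomical registration are out of
  scope; an optional 4×4 affine is accepted and applied at sampling time.

## Ribbon sampling and thickness

The cMD volume is sampled by trilinear interpolation at ribbon midpoints
`m_v = w_v + ½(p_v − w_v)` between *corresponding* white/pial vertices.
The alternative reading — casting along the white-surface normal — is
equivalent when white/pial meshes share vertex correspondence (as FreeSurfer
pairs do, and as the phantoms do by construction), so the corresponding-
vertex midpoint is implemented. Points outside the volume, or whose 8-voxel
interpolation support touches an invalid voxel, become *missing* and stay
missing through smoothing; downstream statistics drop them listwise per
vertex and only analyze vertices with ≥90% subject coverage.

Thickness is the Euclidean distance `‖p_v − w_v‖`. Vertex areas are
barycentric (one third of each incident triangle), so they sum exactly to
the mesh area and make cluster areas additive.

## Geodesic Gaussian smoothing

Vertex maps are smoothed on the surface (never volumetrically — that is the
point of surface-based cMD: no CSF/white-matter partial-volume mixing), with
weights `exp(−d²/2σ²)`, `σ = FWHM/√(8 ln 2)`, `d` the Dijkstra shortest
edge-path distance in mm, truncated at 3σ and renormalized per vertex.
Default FWHM is 15 mm for both metrics. Edge-graph geodesics overestimate
true geodesic distances by up to ~15% anisotropically, but at σ much larger
than the mean edge length the realized impulse-response FWHM is within a few
percent of nominal (asserted at 15% tolerance on a 2562-vertex mesh).
Missing vertices are excluded from numerator and denominator, so a constant
map is exactly invariant regardless of missingness.

The smoothing operator is a sparse row-stochastic matrix that can be
precomputed once per mesh/FWHM and reused — the Monte Carlo null and the
per-subject smoothing in the pipeline share it.

## ComBat harmonization

cMD is harmonized across scanners with parametric ComBat
(normal/inverse-gamma priors; the reference formulation, deterministic):

    y_ijv = α_v + x_jᵀβ_v + γ_iv + δ_iv ε_ijv

1. α, β, per-site γ̂ by least squares with site indicators constrained to a
   subject-weighted zero sum; pooled residual scale σ̂_v.
2. Standardize: `z_ijv = (y_ijv − α̂_v − x_jᵀβ̂_v)/σ̂_v`.
3. Method-of-moments hyperpriors per site: γ̄, τ̄² from the vertex spread of
   γ̂; inverse-gamma (λ̄, θ̄) from the vertex spread of the per-site
   residual variances.
4. Empirical-Bayes recursion
   `γ*_iv = (n_i τ̄² γ̂_iv + δ*² γ̄_i)/(n_i τ̄² + δ*²)`,
   `δ*²_iv = (θ̄_i + ½Σ_j (z_ijv − γ*_iv)²)/(n_i/2 + λ̄_i − 1)`
   iterated to max-change < 1e−6 (cap 100 iterations; typically < 10).
5. Adjust: `y* = σ̂ (z − γ*_i)/δ*_i + α̂ + xᵀβ̂` — the modeled biological
   component is untouched by construction.

Biological covariates default to group, age, sex, handedness (the GLM
variables). Thickness is deliberately **not** harmonized: site enters the
thickness GLM as a nuisance covariate instead, while the MD GLM omits site
because ComBat already removed it — both defaults are configurable.
Vertices with missing values are excluded from hyperprior estimation, get a
complete-case location/scale fit where possible, and are flagged. Sites with
fewer than two subjects, or a single site overall, are hard errors. The
fitted model serializes to JSON for reuse on new data from known sites.

## Vertex-wise inference

Per-vertex OLS with a single contrast; `t = cᵀβ̂ / √(σ̂² cᵀ(XᵀX)⁻¹c)`,
two-sided p from Student t with n−p d.o.f. Zero-residual (exact) fits are
flagged degenerate with p = NaN rather than p = 0. Cluster inference follows
the FreeSurfer-style recipe:

- forming threshold on the two-sided vertex p (defaults: 0.001 whole-group,
  0.05 subgroup/correlation), suprathreshold components split by t sign so
  opposite effects never merge;
- the null distribution of the maximum cluster area comes from Monte Carlo
  simulation (default 10,000 repeats): white noise per vertex, smoothed with
  the *analysis* kernel, re-standardized per repeat to unit variance across
  vertices, thresholded identically. On phantoms the analysis kernel is the
  true smoothness, so no residual-FWHM estimation is needed (a residual-
  smoothness estimator would be the natural extension for real data);
- cluster-wise FWE p by the add-one rule `(1 + #{null ≥ area})/(n_sims+1)`,
  never exactly zero; significance at p_fwe < 0.05.

Whole-cortex (single-mesh) correction with two-sided forming thresholds is
the default; per-hemisphere analyses are just separate meshes.

Cohen's d is computed on nuisance-residualized data (residualized on the
covariates excluding group, fitted over both groups; configurable to raw).
The net effect size is `|d_MD| − |d_thickness|` restricted to the union of
either metric's FWE-significant vertices: absolute values are compared
because thickness effects are negative (thinning) while MD effects are
positive (elevation), and the sign convention makes "MD effect larger"
positive.

## Phantom world

The phantom is a sphere, not a brain. This is deliberate: every quantity
under test (ribbon geometry, vertex areas, connectivity, correspondence) is
preserved while regions and ground truth stay exact. Defaults:

| parameter | default | rationale |
|---|---|---|
| white radius | 50 mm | human-brain length scale |
| thickness | 3 mm | typical cortical thickness |
| ribbon MD | 0.8×10⁻³ mm²/s | literature-typical cortical gray value |
| WM eigenvalues | (1.7, 0.3, 0.3)×10⁻³ | typical white-matter tensor |
| DWI voxel | 2.7 mm iso | study-like DWI grid (1 mm used where the test needs sub-ribbon voxels) |
| S0 | 1000 | arbitrary signal units |
| MD vertex noise | 0.06×10⁻³ mm²/s | ≈7.5% of baseline, realistic repeatability |
| thickness vertex noise | 0.3 mm | typical scan-rescan spread |
| cohort | 52/31/32 patients + 89 controls, 4 sites | study-like composition |

Disease effects are geodesic caps: a *core* (thinning + MD elevation), a
wider *halo* (MD elevation only — microstructural damage beyond atrophy),
and optionally a *thickness-only* control cap used to verify the net-effect
sign convention (the two-region core/halo structure cannot express it).
Severity (a CDR-plus-NACC-FTLD-SB-like 0–24 score, 0 for controls) scales
both effects linearly via `severity_slope`; the mild subgroup is selected on
a stored global stage of 0.5. Site effects follow the ComBat generative
model: an additive MD shift plus a multiplicative scale on the residual,
injected before DWI synthesis. DWI noise is Rician (Gaussian on two
quadrature channels), since magnitude MR data is Rician; sigma defaults to 0
so exactness tests stay exact.

What a green test does *not* establish: the sphere has no gyral geometry, no
partial-volume mixing at tissue boundaries, no susceptibility/eddy
artefacts, and cross-subject correspondence is exact rather than the product
of spherical registration. Results on real data inherit the error of those
upstream steps.

`simulate_cohort` always returns ground-truth and observed vertex maps;
per-subject 4-D DWI volumes are synthesized only on request (`with_dwi=True`)
because a full-size cohort of volumes is gigabytes of memory for no testing
benefit — the DWI path is exercised end-to-end on small cohorts.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng(seed)`; every
  simulation and the Monte Carlo null are bit-reproducible given the seed,
  and analysis manifests record config, input hashes, exclusion counts and
  the seed so a run can be reproduced byte-for-byte.
- Reduced Monte Carlo repeats (≥100) are allowed for testing with a warning;
  the 10,000-repeat default is kept for real analyses.
- Harmonization removes the *systematic* part of a site shift; with
  realistic shift sizes (≈5–10% of the data scale) residual site-mean
  differences are at the 10⁻³ relative level, driven by empirical-Bayes
  shrinkage of per-vertex estimation noise. Very large shifts (tens of
  percent) leave proportionally larger residuals.
- Cluster-wise FWE calibration uses a z-field null against t-statistic data;
  at the residual d.o.f. of the shipped analyses (≥30) the approximation is
  conservative to within the asserted 0.08 bound at nominal 0.05.
- Known limitations: edge-graph (not exact polyhedral) geodesics; no TFCE or
  permutation inference; no longitudinal/mixed models; no spherical
  registration (shared topology stands in for it); thickness harmonization
  intentionally unsupported in the defaults.
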