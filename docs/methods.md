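# Methods note

This note records what the package computes, the parameter defaults and the
reasons behind them, what the synthetic city does and does not emulate, and
the numerical decisions that are easy to get silently wrong.

## 1. Data model

All analysis happens on a **fishnet grid**: rasters (observed or simulated)
are aggregated to square cells by averaging the pixels whose centers fall in
each cell. Layers must be co-registered (identical transform and shape);
reprojection/resampling is out of scope. A cell is kept only if at least
`min_valid_fraction` (default 0.5) of its pixels are valid **in every
layer**, so all statistics share one common support. Cell size defaults to
500 m — large enough that each cell averages many 30 m-class pixels, small
enough to resolve a core/periphery gradient across a ~30 km domain.

GeoTIFF I/O is implemented on `tifffile` with the standard georeferencing
tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA). Only
projected CRSs and axis-aligned transforms are accepted; geographic
(degree-unit) rasters and rotated transforms are rejected with explicit
errors because kernel distances and cell areas are computed in meters.

## 2. Impact decomposition

With β the impervious fraction and NPP_fv the time-constant full-vegetation
productivity:

- `NPP_h = (1 − β) · NPP_fv`
- `NPP_dir = [β(t0) − β(t1)] · NPP_fv`
- `NPP_ind = NPP(t1) − (1 − β(t1)) · NPP_fv`

The identity `NPP_dir + NPP_ind = NPP(t1) − NPP(t0)` holds exactly wherever
NPP(t₀) equals its land-cover expectation; the residual
`NPP(t0) − (1 − β(t0))·NPP_fv` is carried through as a diagnostic column
(`npp_t0_residual`) rather than hidden.

NPP_fv is either supplied as a column or **estimated** as the mean NPP(t₀)
of unurbanized reference cells (β(t₀) ≤ `beta_threshold`, default 0.05)
within `neighborhood_radius` (default 5000 m) of each cell, falling back to
the global reference mean where the neighborhood is empty, and failing
loudly if no reference cell exists anywhere. The locality matters: NPP_fv
varies with soil/climate across a domain, and a global mean would alias that
gradient into NPP_ind.

Known error budget: the estimation error of NPP_fv enters NPP_ind as
`(1 − β(t1)) · (fv_true − fv_est)`, i.e. it is *largest where β is small*.
On the default synthetic city this reduces the correlation between the GWR
coefficient surface and the true LST sensitivity from ≈0.97 (decomposing
with the true baseline) to ≈0.68 (estimated baseline). This is a property of
the decomposition itself, not of the implementation, and is why the
summary statistics for NPP_ind are restricted to cells with NPP_ind > 0 by
convention, where the signal dominates.

## 3. Spatial autocorrelation

**Global Moran's I** `I = (n/W0) · zᵀWz / zᵀz` with queen contiguity and
row-standardized weights by default (each neighbor set is the 8 surrounding
cells; row standardization makes the spatial lag a neighbor mean).
Inference is reported three ways: z-scores under the normality and under the
randomization (Cliff–Ord) variance, and a permutation pseudo p-value
`(#{|I_perm − E(I)| ≥ |I_obs − E(I)|} + 1) / (n_perm + 1)` (two-sided around
E(I) = −1/(n−1), default 999 permutations, floor 1/1000). The permutation p
is the headline number; the analytic variances are cross-checks.

**Local Moran's I** `I_i = (z_i/m₂) · Σ_j w_ij z_j` with m₂ = Σz²/n, so that
Σ_i I_i = I·W0 exactly (tested to 1e−8). Significance uses *conditional*
permutation: the value at i is held fixed and the remaining n−1 values are
permuted among the neighbors, with one shared set of permutation prefixes
across cells (seed-reproducible, O(n_perm·k) per cell). LISA classes are
assigned by the quadrant of (z_i, lag_i) — HH, LL, LH, HL — with "NS"
whenever p_i ≥ α (default α = 0.05, strict inequality required for
significance). Cells with no neighbors get NaN statistics and class NS.

## 4. Regression

**OLS baseline** via statsmodels with classical standard errors; rank
deficiency is reported naming a collinear column.

**GWR** solves, at every cell, the weighted least-squares problem with
bi-square kernel weights `w = (1 − (d/b)²)²` for d < b. The bandwidth is
adaptive: b_i is the distance to the k-th nearest observation (the
regression point included at distance 0), so the kernel tightens where data
are dense. Diagnostics follow the standard GWR formulary: hat diagonal
`h_ii = x_i (XᵀW_iX)⁻¹ x_iᵀ w_ii`, effective parameters tr(S),
`AIC = 2n ln σ̂ + n ln 2π + n + tr(S)`, internally studentized residuals,
local pseudo-R², and local coefficient standard errors via the sandwich
`(XᵀWX)⁻¹ XᵀW²X (XᵀWX)⁻¹ σ²`.

**Bandwidth selection — the one deliberate deviation.** The neighbor count
k is chosen by golden-section search over integers (with an exhaustive-grid
option and a cache; the profile is returned for inspection). The default
criterion is **AICc**, `2n ln σ̂ + n ln 2π + n(n + tr S)/(n − 2 − tr S)`, not
the plain trace-form AIC, because the plain form is structurally degenerate
for selection: its penalty grows only linearly in tr(S) while σ̂ keeps
falling, so on heterogeneous data the profile decreases monotonically into
the smallest admissible bandwidth (k ≈ p+2), overfitting catastrophically
(coefficient-recovery correlation 0.63 on the default city, vs 0.97 under
AICc, which has a proper interior minimum). This is the textbook reason GWR
software optimizes AICc while often labeling it "AIC". Plain `aic` and
leave-one-out `cv` remain selectable. The AIC *statistic reported for model
comparison* stays the trace form, and the OLS/GWR comparison uses the
ΔAIC > 3 rule (verdicts "GWR preferred" / "OLS preferred" /
"indistinguishable"); the ~2-unit convention mismatch between the
statsmodels OLS AIC and the trace-form GWR AIC is negligible against the
thousands-of-units differences the rule acts on.

Numerically, all n local solves are batched as normal equations
(`(XᵀW_iX)` assembled via kernel-matrix matvecs, batched inversion with a
per-location fallback); singular local designs are flagged NaN and the fit
aborts if more than `max_fail_fraction` (default 10%) fail. A full
3600-cell fit with bandwidth search runs in seconds.

## 5. The synthetic city

Defaults define the reference experiment: a 60 × 60 grid of 500 m cells
(3600 cells, a 30 km domain) — large enough for stable permutation inference
and spatially varying coefficients, small enough that the whole pipeline
runs in seconds.

Generated fields:

- **β(t₀), β(t₁)**: logistic radial urban core,
  `β(r) = β_max / (1 + exp((r − core_radius)/core_softness))`, with
  β_max 0.35 → 0.85 between epochs (an intensifying, fixed-footprint city);
  core_radius 7 km, softness 2.5 km.
- **NPP_fv**: smooth Gaussian random field (mean 600, sd 40 gC m⁻² yr⁻¹,
  correlation length ~3 cells) — productivity varies with environment, not
  with urbanization.
- **LST**: `base + uhi_amplitude·β + noise` (22 °C + 6 °C amplitude,
  σ = 0.3 °C) — an urban heat island proportional to urbanization intensity.
- **γ(x)**: Gaussian radial profile of the LST sensitivity of the indirect
  effect, +25 gC m⁻² K⁻¹ in the core falling to −10 far out (scale 6 km):
  urban vegetation benefits from warming, remote vegetation is
  water-limited and loses. This built-in sign change is what makes a global
  slope meaningless and a local model necessary.
- **NPP(t₀) = (1 − β₀)·NPP_fv + ε** and
  **NPP(t₁) = (1 − β₁)·NPP_fv + γ·(LST₁ − mean LST₁) + ε** (σ_ε = 5).

Two construction choices are load-bearing. The indirect effect exists only
at t₁, so the decomposition identity's precondition (NPP(t₀) equals its
land-cover expectation) holds by construction and the noise-free identity is
exact. And NPP responds to the *realized* (noisy) LST, not the noiseless UHI
surface, so regressing NPP_ind on observed LST has no errors-in-variables
attenuation — important in the periphery where β (and hence the systematic
LST signal) is flat.

What the generator does **not** emulate: multi-sensor resolution mismatch,
retrieval error structure in LST or spectral unmixing of β, seasonal
compositing, urban growth by footprint expansion (only intensification),
terrain, water bodies, and cloud/gap masks. It is a test harness with known
truth, not an earth-system simulation; none of its numeric outputs should be
compared against any real city.

## 6. Open design decisions and limitations

- The Moran permutation test permutes values freely (global) or
  conditionally (local); both assume exchangeability, which a strong trend
  surface violates — p-values on such data are anticonservative, which is
  acceptable here because the test is used as a clustering detector.
- Bandwidth search assumes a unimodal criterion profile; when the evaluated
  profile is not unimodal the minimum over evaluated points is returned with
  a warning (this happens on the realistic estimated-baseline path, where
  baseline noise flattens the profile).
- The GWR standard errors are the conventional local-sandwich approximation;
  they ignore bandwidth-selection uncertainty, as is standard.
- `estimate_npp_fv` assumes NPP_fv is time-constant between epochs; a real
  analysis over decades would need a climate detrending step.
- The pipeline is single-CPU and in-memory; the O(n²) distance matrix in GWR
  limits practical grids to a few tens of thousands of cells.
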