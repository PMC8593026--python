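# urbannpp

Decompose the impact of urbanization on vegetation productivity into its
**direct** (land-cover replacement) and **indirect** (growth-environment)
components, test both for spatial clustering, and model the indirect
component's dependence on land surface temperature with geographically
weighted regression — all on a regular fishnet grid, from GeoTIFF inputs or
from a built-in synthetic city generator.

## The science

Net primary productivity (NPP, gC m⁻² yr⁻¹) falls when impervious surface
replaces vegetation, but urban environments can simultaneously *enhance* the
growth of the vegetation that remains (longer growing seasons under the urban
heat island, irrigation, CO₂ and nitrogen fertilization). Observed NPP change
between two epochs t₀ and t₁ mixes both effects. With β the impervious
surface fraction of a cell and NPP_fv the hypothetical productivity of that
cell under full vegetation cover (assumed time-constant), the package
computes:

```
NPP_h   = (1 − β) · NPP_fv                 hypothetical NPP, land cover only
NPP_dir = [β(t0) − β(t1)] · NPP_fv         direct impact of new impervious surface
NPP_ind = NPP(t1) − (1 − β(t1)) · NPP_fv   indirect impact (growth environment)
```

Where NPP(t₀) equals its land-cover expectation (1 − β(t₀))·NPP_fv, these
close exactly: `NPP_dir + NPP_ind = NPP(t1) − NPP(t0)`.

The spatial analysis then asks two questions:

1. **Is the impact spatially clustered?** Global Moran's I with analytic
   (normality and randomization) and permutation inference; local Moran's I
   with conditional permutation and LISA cluster classes (HH / LL / LH / HL /
   not significant).
2. **Does temperature explain the indirect impact, and does the relationship
   vary over space?** A global OLS baseline of NPP_ind on LST, against a GWR
   with a bi-square kernel and an adaptive (k-nearest-neighbor) bandwidth
   selected by corrected AIC:

```
β(u_i, v_i) = (Xᵀ W_i X)⁻¹ Xᵀ W_i y,     w_ij = [1 − (d_ij / b_i)²]²  for d_ij < b_i
```

Models are compared on adjusted R² and AIC with the ΔAIC > 3 rule.

Because matching real multi-sensor imagery is out of scope, the package
ships a fully synthetic city generator (logistic urban core in β, an urban
heat island in LST, a smooth NPP_fv field, and a radially varying LST
sensitivity γ(x) of the indirect effect) whose ground-truth surfaces make
every stage testable.

## Worked example

One YAML config drives the full pipeline:

```yaml
# city.yml
simulate:
  grid_n: 60        # 60 x 60 cells of 500 m -> 3600-cell fishnet
  seed: 42
n_perm: 999
seed: 42
output_dir: run
```

```bash
urbannpp run --config city.yml
urbannpp report --run run
```

The report (written to `run/report.md`) from this exact config:

```
## Global Moran's I
variable        I       E_I     z_norm     z_rand  p_norm  p_perm
  npp_t1 0.989910 -0.000278 116.873159 116.869132     0.0   0.001
 beta_t1 0.994819 -0.000278 117.452573 117.457511     0.0   0.001
  lst_t1 0.941143 -0.000278 111.117126 111.121439     0.0   0.001
 npp_dir 0.994561 -0.000278 117.422139 117.428884     0.0   0.001
 npp_ind 0.900008 -0.000278 106.261942 106.262115     0.0   0.001

## LISA class counts
- npp_t1_class: NS=1891, HH=858, LL=851, LH=0, HL=0 (total 3600)
- lst_t1_class: NS=1703, HH=815, LL=1081, LH=0, HL=1 (total 3600)
- npp_ind_class: NS=2052, HH=781, LL=767, LH=0, HL=0 (total 3600)

## Indirect impact (cells with npp_ind > 0)
 grid_count      min        max      mean
       2932 0.000204 122.997287 33.938415

## OLS (global regression)
     term  coefficient  std_error    t_value      p_value
intercept  -133.412501   8.075360 -16.520935 3.716781e-59
   lst_t1     6.818741   0.347862  19.601880 2.272676e-81

## Model comparison
 adj_r2_ols  adj_r2_gwr      aic_ols      aic_gwr     delta_aic       verdict
   0.096236    0.947318 34006.072544 23684.927723 -10321.144821 GWR preferred
```

The pattern to read off: every surface is strongly positively
autocorrelated (permutation p = 0.001, the floor at 999 permutations); LST
clusters high (HH) and NPP clusters low (LL) in the urban core; 2932 of 3600
cells show a positive indirect impact (mean +33.9 gC m⁻²); and the local
model massively outperforms the global one (adjusted R² 0.947 vs 0.096,
ΔAIC ≈ −10321) because the LST sensitivity genuinely varies over space —
which is exactly how the city was generated.

All intermediate products are plain CSV in the output directory (`grid.csv`,
`moran_summary.csv`, `lisa_cells.csv`, `gwr_cells.csv`, …) plus a
`manifest.json` recording the config hash, seed, package version, and
per-stage timings. Each stage is also available as its own subcommand
(`urbannpp simulate / decompose / moran / lisa / gwr`) and as a library API
(`generate_city`, `aggregate_to_fishnet`, `add_impacts`,
`permutation_test_global`, `local_morans_i`, `GWRegressor`, …). `GWRegressor`
follows the scikit-learn estimator protocol; the first two columns of `X`
are the projected cell coordinates in meters.

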