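"""Synthetic-city generator: raster stacks with known ground truth.

The real inputs of the analysis (Landsat-derived NPP, impervious-surface
fraction and LST over an actual city) are not redistributable, so this
module emulates their joint statistical structure on a metric grid:

* an impervious-surface fraction ``beta`` decaying logistically with
  distance from an urban core, intensifying between two time points;
* an LST field carrying an urban-heat-island signal proportional to beta;
* a full-vegetation NPP baseline ``NPP_fv`` (smooth, time-constant);
* observed NPP built from the land-cover identity
  ``NPP_h = (1 - beta) * NPP_fv`` plus, at the later time point, an
  indirect growth response ``gamma(x) * (LST - mean LST)`` whose local
  coefficient ``gamma`` varies smoothly in space (positive in the core,
  negative at the periphery).

Because NPP at t0 carries no indirect term, the direct/indirect
decomposition identity holds exactly in the truth surfaces whenever the
NPP noise is switched off. The generator is the package's test bed: every
downstream statistic can be checked against the truth surfaces it emits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError
from .raster import GridTransform, RasterLayer, write_raster

OBSERVABLE_LAYERS = ("beta_t0", "beta_t1", "lst_t0", "lst_t1", "npp_t0", "npp_t1")
TRUTH_LAYERS = ("npp_fv_true", "gamma_true", "npp_dir_true", "npp_ind_true")


@dataclass
class SyntheticCityConfig:
    """Parameters of the synthetic city.

    Units: meters for all distances, fractions in [0, 1] for beta,
    gC m-2 yr-1 for NPP quantities, degrees C for LST, and
    gC m-2 degC-1 for the local LST coefficient gamma.
    """

    grid_n: int = 60
    cell_size: float = 500.0
    core_center: tuple[float, float] | None = None  # (row, col), defaults to center
    core_radius: float = 7000.0
    core_softness: float = 2500.0
    beta_max_t0: float = 0.35
    beta_max_t1: float = 0.85
    npp_fv_mean: float = 600.0
    npp_fv_sd: float = 40.0
    lst_base: float = 22.0
    uhi_amplitude: float = 6.0
    gamma_core: float = 25.0
    gamma_far: float = -10.0
    gamma_scale: float = 6000.0
    noise_sd_npp: float = 5.0
    noise_sd_lst: float = 0.3
    seed: int = 0
    crs: str = "EPSG:32648"
    origin: tuple[float, float] = (600000.0, 2800000.0)

    def validate(self) -> None:
        if not isinstance(self.grid_n, (int, np.integer)) or self.grid_n < 8:
            raise ConfigError(f"grid_n must be an integer >= 8, got {self.grid_n}")
        if self.cell_size <= 0:
            raise ConfigError(f"cell_size must be > 0, got {self.cell_size}")
        if not 0 <= self.beta_max_t0 <= self.beta_max_t1 <= 1:
            raise ConfigError(
                "beta_max_t0/beta_max_t1 must satisfy 0 <= beta_max_t0 <= beta_max_t1 <= 1, "
                f"got {self.beta_max_t0}, {self.beta_max_t1}"
            )
        for name in ("core_radius", "core_softness", "gamma_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("npp_fv_sd", "noise_sd_npp", "noise_sd_lst"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.npp_fv_mean < 0:
            raise ConfigError(f"npp_fv_mean must be >= 0, got {self.npp_fv_mean}")


@dataclass
class SyntheticCity:
    """Generated layers plus the ground-truth surfaces."""

    config: SyntheticCityConfig
    layers: dict[str, RasterLayer]
    truth: dict[str, RasterLayer]

    def all_layers(self) -> dict[str, RasterLayer]:
        return {**self.layers, **self.truth}


def generate_city(config: SyntheticCityConfig) -> SyntheticCity:
    """Generate all observable layers and truth surfaces for one city."""
    config.validate()
    n = int(config.grid_n)
    rng = np.random.default_rng(config.seed)
    transform = GridTransform(
        x0=config.origin[0], y0=config.origin[1], dx=config.cell_size, dy=config.cell_size
    )

    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    if config.core_center is None:
        cr = cc = (n - 1) / 2.0
    else:
        cr, cc = config.core_center
    # Euclidean distance between cell centers, in meters
    d = np.hypot(rows - cr, cols - cc) * config.cell_size

    def logistic(z: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-z))

    shape_fn = logistic((config.core_radius - d) / config.core_softness)
    beta_t0 = np.clip(config.beta_max_t0 * shape_fn, 0.0, 1.0)
    beta_t1 = np.clip(config.beta_max_t1 * shape_fn, 0.0, 1.0)

    # smooth, strictly positive full-vegetation baseline
    if config.npp_fv_sd > 0:
        white = rng.standard_normal((n, n))
        smooth = gaussian_filter(white, sigma=3.0, mode="reflect")
        smooth /= max(smooth.std(), 1e-12)
        npp_fv = np.maximum(config.npp_fv_mean + config.npp_fv_sd * smooth, 0.0)
    else:
        rng.standard_normal((n, n))  # keep the draw order stable across configs
        npp_fv = np.full((n, n), float(config.npp_fv_mean))

    lst_t0 = config.lst_base + config.uhi_amplitude * beta_t0 \
        + config.noise_sd_lst * rng.standard_normal((n, n))
    lst_t1 = config.lst_base + config.uhi_amplitude * beta_t1 \
        + config.noise_sd_lst * rng.standard_normal((n, n))

    gamma = (config.gamma_core - config.gamma_far) * np.exp(
        -(d ** 2) / (2.0 * config.gamma_scale ** 2)
    ) + config.gamma_far

    eps0 = config.noise_sd_npp * rng.standard_normal((n, n))
    eps1 = config.noise_sd_npp * rng.standard_normal((n, n))

    npp_ind_true = gamma * (lst_t1 - lst_t1.mean())
    npp_dir_true = (beta_t0 - beta_t1) * npp_fv
    npp_t0 = (1.0 - beta_t0) * npp_fv + eps0
    npp_t1 = (1.0 - beta_t1) * npp_fv + npp_ind_true + eps1

    def layer(values: np.ndarray) -> RasterLayer:
        return RasterLayer(values=values, transform=transform, crs=config.crs)

    layers = {
        "beta_t0": layer(beta_t0),
        "beta_t1": layer(beta_t1),
        "lst_t0": layer(lst_t0),
        "lst_t1": layer(lst_t1),
        "npp_t0": layer(npp_t0),
        "npp_t1": layer(npp_t1),
    }
    truth = {
        "npp_fv_true": layer(npp_fv),
        "gamma_true": layer(gamma),
        "npp_dir_true": layer(npp_dir_true),
        "npp_ind_true": layer(npp_ind_true),
    }
    return SyntheticCity(config=config, layers=layers, truth=truth)


def write_city(city: SyntheticCity, directory: str | Path) -> dict:
    """Write one GeoTIFF per layer plus a JSON manifest; return the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "crs": city.config.crs,
        "cell_size": city.config.cell_size,
        "grid_n": int(city.config.grid_n),
        "seed": int(city.config.seed),
        "layers": {},
        "truth_layers": {},
    }
    for name, lyr in city.layers.items():
        fname = f"{name}.tif"
        write_raster(lyr, directory / fname)
        manifest["layers"][name] = fname
    for name, lyr in city.truth.items():
        fname = f"{name}.tif"
        write_raster(lyr, directory / fname)
        manifest["truth_layers"][name] = fname
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
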