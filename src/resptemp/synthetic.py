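"""Synthetic observing-system world with known ground truth.

Generates everything the downstream stages consume — monthly 1-degree
temperature, shortwave radiation, GPP, respiration and NEE fields, a biome
label map, tower footprints and noisy CO2 observation tables — from a
seeded configuration, so parameter recovery can be checked against known
truth without any external data.

The world is a deliberately minimal emulation of the real inputs' structure:

* temperature follows a latitudinal lapse plus a seasonal cycle with small
  cell-level noise, giving the joint space-time gradient the pooled
  Arrhenius regression exploits;
* each biome respires with its own activation energy and baseline rate; the
  baseline carries lognormal spatial heterogeneity;
* GPP is light-use-efficiency scaled shortwave radiation modulated by a
  seasonal greenness factor (radiation is the first-order driver);
* each tower observation sees the flux field through a Gaussian spatial
  kernel confined to its own month;
* observations are the transported NEE plus background and fossil constants
  and i.i.d. Gaussian noise in ppm.

Defaults mimic the study geometry at desk scale: a 20 x 40 cell grid, 48
months, 44 towers, three labelled biomes plus "other".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import sparse

from . import constants as c
from .adjustment import adjust_respiration
from .exceptions import ConfigurationError, ParameterError
from .grids import gridded_field
from .transport import OBS_COLUMNS, FootprintOperator


@dataclass(frozen=True)
class BiomeSpec:
    """One labelled biome: a lat/lon box with its true Arrhenius parameters."""

    name: str
    ea_ev: float                  # true activation energy, eV
    re_ref: float                 # baseline respiration at T_ref, umol m-2 s-1
    box: tuple[float, float, float, float]   # lat_min, lat_max, lon_min, lon_max

    def contains(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        lat0, lat1, lon0, lon1 = self.box
        return (lat >= lat0) & (lat < lat1) & (lon >= lon0) & (lon < lon1)


DEFAULT_BIOMES = (
    BiomeSpec("cropland", 0.38, 3.0, (30.0, 40.0, -100.0, -85.0)),
    BiomeSpec("enf", 0.50, 2.0, (42.0, 50.0, -100.0, -75.0)),
    BiomeSpec("dbf-mixed", 0.53, 2.6, (30.0, 42.0, -85.0, -60.0)),
)


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of the synthetic world. All defaults are the study
    conditions; see docs/methods.md for the reasoning behind each value."""

    lat_min: float = 30.0
    lat_max: float = 50.0
    lon_min: float = -100.0
    lon_max: float = -60.0
    n_months: int = 48            # four years of monthly fields

    biomes: tuple[BiomeSpec, ...] = DEFAULT_BIOMES
    other_ea: float = 0.45        # eV, for unlabelled cells
    other_re_ref: float = 1.5     # umol m-2 s-1

    # temperature climatology
    t_mean: float = 288.0         # K at the southern edge
    t_lapse: float = 0.6          # K per degree latitude
    t_amplitude: float = 12.0     # K, seasonal half-range
    t_peak_month: int = 6         # July (0-based month-of-year)
    t_cell_sigma: float = 0.3     # K, cell-month noise

    # baseline-respiration spatial heterogeneity (lognormal sigma)
    re_ref_sigma: float = 0.10

    # shortwave radiation and GPP
    sw_mean: float = 250.0        # W m-2 at the southern edge
    sw_seasonal: float = 150.0    # W m-2 seasonal half-range
    sw_lat_slope: float = 1.5     # W m-2 per degree latitude
    sw_floor: float = 50.0        # W m-2, below which GPP shuts off
    lue: float = 0.02             # umol m-2 s-1 per W m-2
    greenness_base: float = 0.3
    greenness_amplitude: float = 0.7

    # observing network
    n_towers: int = 44
    footprint_peak: float = 0.05  # ppm per (umol m-2 s-1), kernel maximum
    footprint_length: float = 2.5  # degrees, Gaussian decay length
    footprint_cutoff: float = 3.0  # kernel support radius in decay lengths
    background_ppm: float = 400.0
    fossil_ppm: float = 1.5
    noise_ppm: float = 0.5

    seed: int = 1234

    def __post_init__(self) -> None:
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ConfigurationError("empty grid extent")
        if self.n_months < 12:
            raise ConfigurationError(f"n_months must be >= 12, got {self.n_months}")
        if self.noise_ppm < 0:
            raise ConfigurationError("observation noise sigma must be >= 0")
        if self.other_re_ref <= 0 or any(b.re_ref <= 0 for b in self.biomes):
            raise ConfigurationError("all baseline respiration rates must be positive")
        for a in range(len(self.biomes)):
            for b in range(a + 1, len(self.biomes)):
                if _boxes_overlap(self.biomes[a].box, self.biomes[b].box):
                    raise ConfigurationError(
                        f"biome boxes overlap: {self.biomes[a].name} / {self.biomes[b].name}"
                    )

    @property
    def lat(self) -> np.ndarray:
        return np.arange(self.lat_min + 0.5, self.lat_max, 1.0)

    @property
    def lon(self) -> np.ndarray:
        return np.arange(self.lon_min + 0.5, self.lon_max, 1.0)


def _boxes_overlap(a, b) -> bool:
    return (a[0] < b[1] and b[0] < a[1]) and (a[2] < b[3] and b[2] < a[3])


@dataclass
class SyntheticTruth:
    """Ground-truth record returned by :func:`generate_world`."""

    config: WorldConfig
    temperature: xr.DataArray
    sw: xr.DataArray
    gpp: xr.DataArray
    re: xr.DataArray
    nee: xr.DataArray
    re_ref_field: xr.DataArray    # (lat, lon) baseline respiration
    biome_map: xr.DataArray       # (lat, lon) integer codes
    biome_labels: dict[int, str]
    biome_truth: dict[str, dict[str, float]]
    towers: pd.DataFrame          # site_id, lat, lon
    footprints: FootprintOperator
    obs_clean: pd.DataFrame
    obs: pd.DataFrame             # clean + Gaussian noise

    def domain_mask(self, domain: str) -> np.ndarray | None:
        """(lat, lon) selector for a named domain; the full continent is None."""
        if domain == "north-america":
            return None
        codes = {v: k for k, v in self.biome_labels.items()}
        if domain not in codes:
            raise ConfigurationError(f"unknown domain {domain!r}; have {sorted(codes)}")
        return np.asarray(self.biome_map.values == codes[domain])

    @property
    def domains(self) -> list[str]:
        return ["north-america"] + [n for n in self.biome_labels.values() if n != "other"]


def generate_world(cfg: WorldConfig) -> SyntheticTruth:
    """Build the full synthetic world deterministically from ``cfg.seed``.

    Independent random layers (temperature noise, baseline heterogeneity,
    tower placement, observation noise) draw from spawned child generators,
    so the deterministic climatological structure is identical across seeds.
    """
    lat, lon = cfg.lat, cfg.lon
    nlat, nlon, nt = len(lat), len(lon), cfg.n_months
    ss = np.random.SeedSequence(cfg.seed)
    rng_t, rng_ref, rng_tow, rng_obs = (np.random.default_rng(s) for s in ss.spawn(4))

    # biome map
    biome_map = np.zeros((nlat, nlon), dtype=int)
    labels = {0: "other"}
    lat2d, lon2d = np.meshgrid(lat, lon, indexing="ij")
    for k, spec in enumerate(cfg.biomes, start=1):
        inside = spec.contains(lat2d, lon2d)
        biome_map[inside] = k
        labels[k] = spec.name
    ea_by_code = {0: cfg.other_ea, **{k: b.ea_ev for k, b in enumerate(cfg.biomes, 1)}}
    ref_by_code = {0: cfg.other_re_ref, **{k: b.re_ref for k, b in enumerate(cfg.biomes, 1)}}

    months = np.arange(nt)
    season = np.cos(2.0 * np.pi * (months % 12 - cfg.t_peak_month) / 12.0)

    # temperature: lapse + seasonal cycle + cell noise
    t_clim = (cfg.t_mean
              - cfg.t_lapse * np.abs(lat2d - cfg.lat_min)[None, :, :]
              + cfg.t_amplitude * season[:, None, None])
    temperature = t_clim + rng_t.normal(0.0, cfg.t_cell_sigma, size=(nt, nlat, nlon))

    # shortwave and GPP
    sw = (cfg.sw_mean
          - cfg.sw_lat_slope * (lat2d - cfg.lat_min)[None, :, :]
          + cfg.sw_seasonal * season[:, None, None])
    sw = np.clip(sw, 0.0, None) * np.ones((nt, 1, 1))
    greenness = np.clip(cfg.greenness_base + cfg.greenness_amplitude * season, 0.0, None)
    gpp = cfg.lue * sw * greenness[:, None, None]
    gpp[sw < cfg.sw_floor] = 0.0

    # respiration: Arrhenius with per-biome parameters and heterogeneous baseline
    ea_map = np.vectorize(ea_by_code.get)(biome_map).astype(float)
    ref_map = np.vectorize(ref_by_code.get)(biome_map).astype(float)
    re_ref_field = ref_map * np.exp(rng_ref.normal(0.0, cfg.re_ref_sigma, size=(nlat, nlon)))
    re = re_ref_field[None, :, :] * np.exp(
        -(ea_map[None, :, :] / c.K_B) * (1.0 / temperature - 1.0 / c.T_REF)
    )
    nee = re - gpp

    # towers and footprints
    tower_lat = rng_tow.uniform(cfg.lat_min + 0.5, cfg.lat_max - 0.5, cfg.n_towers)
    tower_lon = rng_tow.uniform(cfg.lon_min + 0.5, cfg.lon_max - 0.5, cfg.n_towers)
    towers = pd.DataFrame({
        "site_id": [f"T{i + 1:02d}" for i in range(cfg.n_towers)],
        "lat": tower_lat,
        "lon": tower_lon,
    })
    footprints = _build_footprints(cfg, lat2d, lon2d, towers)

    # observations: transported NEE + background + fossil (+ noise)
    nee_field = gridded_field(nee, lat, lon, c.UNITS_FLUX, name="nee")
    clean = footprints.transport(nee_field)
    site_rep = np.repeat(towers["site_id"].to_numpy(), nt)
    time_rep = np.tile(months, cfg.n_towers)
    obs_clean = _obs_table(site_rep, time_rep, clean + cfg.background_ppm + cfg.fossil_ppm,
                           cfg.background_ppm, cfg.fossil_ppm)
    noise = rng_obs.normal(0.0, cfg.noise_ppm, size=len(obs_clean)) if cfg.noise_ppm > 0 \
        else np.zeros(len(obs_clean))
    obs = _obs_table(site_rep, time_rep, obs_clean["raw_ppm"].to_numpy() + noise,
                     cfg.background_ppm, cfg.fossil_ppm)

    biome_truth = {
        labels[k]: {"ea": ea_by_code[k], "re_ref": ref_by_code[k]} for k in labels
    }
    return SyntheticTruth(
        config=cfg,
        temperature=gridded_field(temperature, lat, lon, c.UNITS_TEMPERATURE, name="temperature"),
        sw=gridded_field(sw, lat, lon, c.UNITS_SW, name="sw"),
        gpp=gridded_field(gpp, lat, lon, c.UNITS_FLUX, name="gpp"),
        re=gridded_field(re, lat, lon, c.UNITS_FLUX, name="re"),
        nee=nee_field,
        re_ref_field=xr.DataArray(re_ref_field, dims=("lat", "lon"),
                                  coords={"lat": lat, "lon": lon},
                                  attrs={"units": c.UNITS_FLUX}, name="re_ref"),
        biome_map=xr.DataArray(biome_map, dims=("lat", "lon"),
                               coords={"lat": lat, "lon": lon}, name="biome"),
        biome_labels=labels,
        biome_truth=biome_truth,
        towers=towers,
        footprints=footprints,
        obs_clean=obs_clean,
        obs=obs,
    )


def _obs_table(site, time_index, raw, background, fossil) -> pd.DataFrame:
    """Observation table; the biospheric column is the exact residual of the
    raw signal after background and fossil removal."""
    df = pd.DataFrame({
        "obs_id": [f"{s}_{m:03d}" for s, m in zip(site, time_index)],
        "site_id": site,
        "time_index": time_index,
        "raw_ppm": np.asarray(raw, float),
        "background_ppm": background,
        "fossil_ppm": fossil,
    })
    df["biospheric_ppm"] = df["raw_ppm"] - df["background_ppm"] - df["fossil_ppm"]
    return df[OBS_COLUMNS]


def _build_footprints(cfg: WorldConfig, lat2d, lon2d, towers: pd.DataFrame) -> FootprintOperator:
    """Gaussian kernels around each tower, supported only in the obs month."""
    nlat, nlon = lat2d.shape
    ncell = nlat * nlon
    nt = cfg.n_months
    cutoff2 = (cfg.footprint_cutoff * cfg.footprint_length) ** 2
    rows, cols, vals = [], [], []
    for s, (tlat, tlon) in enumerate(zip(towers["lat"], towers["lon"])):
        d2 = (lat2d - tlat) ** 2 + (lon2d - tlon) ** 2
        keep = d2 <= cutoff2
        cell_idx = np.flatnonzero(keep.ravel())
        w = cfg.footprint_peak * np.exp(-d2.ravel()[cell_idx] / (2.0 * cfg.footprint_length**2))
        for m in range(nt):
            rows.append(np.full(cell_idx.size, s * nt + m))
            cols.append(m * ncell + cell_idx)
            vals.append(w)
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(cfg.n_towers * nt, nt * ncell),
    )
    return FootprintOperator(mat, (nt, nlat, nlon))


# -- pseudo-model ensembles --------------------------------------------------

@dataclass(frozen=True)
class PseudoModel:
    """One synthetic 'model': truth fluxes with a known, invertible bias."""

    model_id: str
    gpp: xr.DataArray
    re: xr.DataArray
    nee: xr.DataArray
    dea_true: float               # applied Ea bias, eV
    alpha_true: float             # applied baseline scale
    gpp_factor: float = 1.0


def generate_biased_ensemble(
    truth: SyntheticTruth,
    biases: Sequence[tuple[float, float]],
    gpp_factors: Sequence[float] | None = None,
) -> list[PseudoModel]:
    """Pseudo-models whose respiration is truth transformed by a known
    (dEa, alpha) bias; optimizing them against the truth observations should
    recover the negated bias. GPP may optionally be scaled per model.
    """
    if gpp_factors is None:
        gpp_factors = [1.0] * len(biases)
    models = []
    for i, ((dea, alpha), gf) in enumerate(zip(biases, gpp_factors)):
        if alpha <= 0:
            raise ParameterError(f"alpha_true must be positive, got {alpha}")
        re_b = adjust_respiration(truth.re, truth.temperature, dea, alpha)
        gpp_b = truth.gpp * gf if gf != 1.0 else truth.gpp.copy()
        models.append(PseudoModel(
            model_id=f"M{i + 1:02d}",
            gpp=gpp_b,
            re=re_b,
            nee=re_b - gpp_b,
            dea_true=float(dea),
            alpha_true=float(alpha),
            gpp_factor=float(gf),
        ))
    return models


def sample_observations(
    truth: SyntheticTruth,
    n: int,
    rng: np.random.Generator | int,
    noise_ppm: float | None = None,
) -> tuple[pd.DataFrame, FootprintOperator]:
    """Draw ``n`` observations by resampling (tower, month) rows of the base
    design with replacement, each with a fresh noise realization.

    Returns the observation table together with the matching row-subset
    footprint operator.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if noise_ppm is None:
        noise_ppm = truth.config.noise_ppm
    idx = rng.integers(0, len(truth.obs_clean), size=n)
    base = truth.obs_clean.iloc[idx].reset_index(drop=True)
    noise = rng.normal(0.0, noise_ppm, size=n) if noise_ppm > 0 else np.zeros(n)
    obs = _obs_table(base["site_id"].to_numpy(), base["time_index"].to_numpy(),
                     base["raw_ppm"].to_numpy() + noise,
                     truth.config.background_ppm, truth.config.fossil_ppm)
    return obs, truth.footprints.rows(idx)


def simulate_ensemble_points(
    ea_opt_true: float,
    n_models: int,
    rng: np.random.Generator | int,
    ea_range: tuple[float, float] = (0.3, 0.9),
    noise_ea: float = 0.03,
    noise_dea: float = 0.03,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Ea, dEa) scatter for ensemble zero-crossing recovery studies.

    By construction the adjustment that brings a model with original
    sensitivity Ea to the ensemble optimum is dEa = Ea_opt - Ea; noise is
    added to both axes (errors-in-variables). Returns
    ``(ea_observed, dea_observed, ea_true)``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ea_true = rng.uniform(*ea_range, size=n_models)
    dea_true = ea_opt_true - ea_true
    return (ea_true + rng.normal(0.0, noise_ea, n_models),
            dea_true + rng.normal(0.0, noise_dea, n_models),
            ea_true)


def small_world_config(**overrides) -> WorldConfig:
    """A fast miniature configuration for examples and quick checks."""
    base = dict(
        lat_min=38.0, lat_max=46.0, lon_min=-92.0, lon_max=-80.0,
        n_months=24, n_towers=6,
        biomes=(
            BiomeSpec("cropland", 0.38, 3.0, (38.0, 42.0, -92.0, -86.0)),
            BiomeSpec("enf", 0.50, 2.0, (42.0, 46.0, -92.0, -86.0)),
            BiomeSpec("dbf-mixed", 0.53, 2.6, (38.0, 44.0, -86.0, -80.0)),
        ),
    )
    base.update(overrides)
    return WorldConfig(**base)
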