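"""Footprint transport operator and explanatory-power evaluation.

A transport footprint is the linear sensitivity of one tower CO2 observation
(ppm) to the surface flux (umol m-2 s-1) in every grid cell and month. The
operator is stored as a sparse matrix H of shape (n_obs, n_time*n_lat*n_lon)
so that transported signals are plain mat-vec products: y = H @ flux.ravel().

Observation tables carry, per observation, the raw CO2 mixing ratio and its
background and fossil components; the biospheric signal is their exact
difference. Adding back the transported photosynthetic uptake isolates the
respiratory component of the observed variability:

    y_resp = (raw - background - fossil) + H(GPP)

with GPP stored as a positive uptake magnitude, so NEE = RE - GPP and
H(NEE) + H(GPP) = H(RE).

Explanatory power is the squared Pearson correlation between a transported
signal and a reference — sign- and scale-invariant, which is what makes GPP
alone (sign-opposed to CO2 enhancement) and shortwave radiation (different
units) usable as explainers. A regression-based R^2 (1 - RSS/TSS) is also
available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import sparse

from .exceptions import (
    CoverageError,
    GridMismatchError,
    ParameterError,
    UndefinedR2Error,
)

OBS_COLUMNS = ["obs_id", "site_id", "time_index", "raw_ppm", "background_ppm", "fossil_ppm", "biospheric_ppm"]


class FootprintOperator:
    """Sparse linear map from gridded cell-month fluxes to per-observation ppm."""

    def __init__(self, matrix: sparse.spmatrix, grid_shape: tuple[int, int, int],
                 validate: bool = True):
        self.matrix = sparse.csr_matrix(matrix)
        self.grid_shape = tuple(int(s) for s in grid_shape)
        if self.matrix.shape[1] != int(np.prod(self.grid_shape)):
            raise GridMismatchError(
                f"operator has {self.matrix.shape[1]} columns but grid {self.grid_shape} "
                f"has {int(np.prod(self.grid_shape))} cell-months"
            )
        if validate:
            self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ParameterError("footprint sensitivities must be non-negative")
        counts = np.diff(self.matrix.indptr)
        if np.any(counts == 0):
            raise ParameterError("every observation must have at least one footprint entry")

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    # -- algebra ------------------------------------------------------------
    def transport(self, flux) -> np.ndarray:
        """Transported signal in ppm; NaN flux cells contribute nothing."""
        values = np.asarray(flux.values if isinstance(flux, xr.DataArray) else flux, float)
        if values.shape != self.grid_shape:
            raise GridMismatchError(f"flux shape {values.shape} != grid {self.grid_shape}")
        return self.matrix @ np.nan_to_num(values, nan=0.0).ravel()

    def rows(self, idx: np.ndarray) -> "FootprintOperator":
        """Sub-operator for a subset (or resample) of observations."""
        return FootprintOperator(self.matrix[np.asarray(idx)], self.grid_shape, validate=False)

    def domain_coverage(self, mask_flat: np.ndarray) -> float:
        """Total sensitivity mass over a flattened cell-month selector."""
        cols = np.flatnonzero(mask_flat)
        return float(np.abs(self.matrix[:, cols]).sum())

    # -- I/O ----------------------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        coo = self.matrix.tocoo()
        nt, nlat, nlon = self.grid_shape
        t, rem = np.divmod(coo.col, nlat * nlon)
        i, j = np.divmod(rem, nlon)
        return pd.DataFrame(
            {"obs_index": coo.row, "time_index": t, "lat_index": i,
             "lon_index": j, "sensitivity": coo.data}
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame, grid_shape: tuple[int, int, int],
                   n_obs: int | None = None) -> "FootprintOperator":
        nt, nlat, nlon = grid_shape
        col = (table["time_index"].to_numpy() * nlat * nlon
               + table["lat_index"].to_numpy() * nlon
               + table["lon_index"].to_numpy())
        row = table["obs_index"].to_numpy()
        if n_obs is None:
            n_obs = int(row.max()) + 1
        mat = sparse.coo_matrix(
            (table["sensitivity"].to_numpy(float), (row, col)),
            shape=(n_obs, nt * nlat * nlon),
        )
        return cls(mat, grid_shape)

    def save(self, table_path, sidecar_path) -> None:
        # %.17g round-trips float64 exactly through text
        self.to_table().to_csv(table_path, index=False, float_format="%.17g")
        Path(sidecar_path).write_text(
            json.dumps({"grid_shape": list(self.grid_shape), "n_obs": self.n_obs}, indent=2)
        )

    @classmethod
    def load(cls, table_path, sidecar_path) -> "FootprintOperator":
        meta = json.loads(Path(sidecar_path).read_text())
        table = pd.read_csv(table_path, float_precision="round_trip")
        return cls.from_table(table, tuple(meta["grid_shape"]), meta["n_obs"])


def transport_signal(footprints: FootprintOperator, flux) -> np.ndarray:
    """Functional form of :meth:`FootprintOperator.transport`."""
    return footprints.transport(flux)


# -- observation tables ------------------------------------------------------

def biospheric_signal(obs: pd.DataFrame) -> np.ndarray:
    """Biospheric CO2 signal: raw minus background minus fossil (exact)."""
    return (obs["raw_ppm"] - obs["background_ppm"] - obs["fossil_ppm"]).to_numpy(float)


def respiratory_component(obs: pd.DataFrame, footprints: FootprintOperator, gpp) -> np.ndarray:
    """Respiratory component of observed CO2 variability (ppm).

    Adds the transported photosynthetic uptake back onto the biospheric
    signal; with NEE = RE - GPP this isolates H(RE) plus observation noise.
    """
    if gpp is None:
        raise ParameterError("a GPP field is required to form the respiratory component")
    if len(obs) != footprints.n_obs:
        raise GridMismatchError(
            f"obs table has {len(obs)} rows but operator expects {footprints.n_obs}"
        )
    return biospheric_signal(obs) + footprints.transport(gpp)


def filter_obs_outliers(obs: pd.DataFrame, z_threshold: float = 3.0) -> pd.DataFrame:
    """Optional z-score outlier filter on the biospheric signal (off by default
    in every pipeline path; retained for screening gross mismatches)."""
    y = biospheric_signal(obs)
    z = (y - y.mean()) / y.std(ddof=1)
    return obs.loc[np.abs(z) <= z_threshold].reset_index(drop=True)


# -- explanatory power -------------------------------------------------------

def explanatory_power(signal: np.ndarray, reference: np.ndarray,
                      method: str = "correlation") -> float:
    """Coefficient of determination between a transported signal and a reference.

    ``method="correlation"`` (default): squared Pearson correlation,
    invariant under affine transforms with nonzero scale of either argument.
    ``method="regression"``: 1 - RSS/TSS of the signal as a direct predictor.
    """
    signal = np.asarray(signal, float)
    reference = np.asarray(reference, float)
    if signal.shape != reference.shape:
        raise GridMismatchError("signal and reference lengths differ")
    if signal.size < 3:
        raise UndefinedR2Error(f"need >= 3 observations, got {signal.size}")
    if np.std(signal) == 0 or np.std(reference) == 0:
        raise UndefinedR2Error("explanatory power undefined for zero-variance input")
    if method == "correlation":
        return float(np.corrcoef(signal, reference)[0, 1] ** 2)
    if method == "regression":
        rss = float(np.sum((reference - signal) ** 2))
        tss = float(np.sum((reference - reference.mean()) ** 2))
        return 1.0 - rss / tss
    raise ParameterError(f"unknown method {method!r}")


def sw_benchmark(footprints: FootprintOperator, sw, reference: np.ndarray,
                 method: str = "correlation") -> float:
    """Explanatory power of shortwave radiation transported as a pseudo-flux.

    Serves as the minimum benchmark ("SW gate"): models whose GPP does not
    out-explain incident radiation carry no usable flux information.
    """
    values = np.asarray(sw.values if isinstance(sw, xr.DataArray) else sw, float)
    if np.nanstd(values) == 0:
        raise UndefinedR2Error("a constant radiation field carries no variability")
    return explanatory_power(footprints.transport(sw), reference, method=method)


@dataclass(frozen=True)
class EvalResult:
    """Explanatory power of one model's GPP and NEE against observations."""

    model_id: str
    r2_gpp: float
    r2_nee: float
    r2_sw: float
    delta_r2: float               # r2_nee - r2_gpp
    pass_sw_gate_gpp: bool
    pass_sw_gate_nee: bool

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "r2_gpp": self.r2_gpp,
            "r2_nee": self.r2_nee,
            "r2_sw": self.r2_sw,
            "delta_r2": self.delta_r2,
            "pass_sw_gate_gpp": self.pass_sw_gate_gpp,
            "pass_sw_gate_nee": self.pass_sw_gate_nee,
        }


def evaluate_model(model_id: str, gpp, nee, footprints: FootprintOperator,
                   obs: pd.DataFrame, sw=None, sw_gate: float | None = None,
                   method: str = "correlation") -> EvalResult:
    """Evaluate how well a model's transported GPP and NEE explain observations.

    Either an SW field (gate computed here) or a precomputed numeric gate
    must be supplied.
    """
    y = biospheric_signal(obs)
    if sw_gate is None:
        if sw is None:
            raise ParameterError("supply either an SW field or a numeric sw_gate")
        sw_gate = sw_benchmark(footprints, sw, y, method=method)
    r2_gpp = explanatory_power(footprints.transport(gpp), y, method=method)
    r2_nee = explanatory_power(footprints.transport(nee), y, method=method)
    return EvalResult(
        model_id=model_id,
        r2_gpp=r2_gpp,
        r2_nee=r2_nee,
        r2_sw=float(sw_gate),
        delta_r2=r2_nee - r2_gpp,
        pass_sw_gate_gpp=r2_gpp > sw_gate,
        pass_sw_gate_nee=r2_nee > sw_gate,
    )


def coverage_check(footprints: FootprintOperator, mask_flat: np.ndarray) -> None:
    if footprints.domain_coverage(mask_flat) == 0:
        raise CoverageError("footprints carry no sensitivity to the requested domain")
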