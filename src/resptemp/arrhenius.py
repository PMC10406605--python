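"""Arrhenius model of ecosystem respiration and its pooled estimator.

Ecosystem respiration RE (umol m-2 s-1) responds to air temperature T (K) as

    RE(T) = RE_ref * exp[-(Ea / kB) * (1/T - 1/T_ref)]

with activation energy Ea (eV), baseline rate RE_ref at T_ref = 283.15 K and
Boltzmann constant kB. Taking logs makes the model linear in
x = (1/T - 1/T_ref), so (Ea, RE_ref) are estimated by ordinary least squares
pooled over all retained cell-months of a domain — spatial and temporal
temperature variability enter one regression ("space for time").

The apparent Q10 — the factor by which respiration rises over a 10 K
warming — follows from linearising ln RE in T at temperature T:

    Q10(Ea, T) = exp(Ea * 10 / (kB * T^2))
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import xarray as xr
from scipy import stats

from .constants import DT10, K_B, T_REF
from .exceptions import DomainError, ParameterError, SingularFitError
from .grids import broadcast_spatial_mask, valid_mask


@dataclass(frozen=True)
class ArrheniusParams:
    """Parameters of the Arrhenius respiration response.

    ``t_ref`` and ``k_b`` are fixed constants of the analysis; they are kept
    on the record for transparency but may not be overridden.
    """

    ea: float                     # activation energy, eV
    re_ref: float                 # baseline respiration at t_ref, umol m-2 s-1
    t_ref: float = T_REF          # K, fixed
    k_b: float = K_B              # eV K-1, fixed

    def __post_init__(self) -> None:
        if not self.re_ref > 0:
            raise ParameterError(f"re_ref must be positive, got {self.re_ref}")
        if self.t_ref != T_REF:
            raise ParameterError(f"t_ref is fixed at {T_REF} K")
        if self.k_b != K_B:
            raise ParameterError("k_b is fixed at the CODATA literal")


@dataclass(frozen=True)
class ArrheniusFit:
    """Result of the pooled log-linear regression."""

    params: ArrheniusParams
    se_ea: float                  # eV
    se_ln_re_ref: float           # dimensionless (log space)
    n_used: int
    n_filtered: int
    r2_fit: float

    def to_dict(self) -> dict:
        return {
            "ea": self.params.ea,
            "re_ref": self.params.re_ref,
            "se_ea": self.se_ea,
            "se_ln_re_ref": self.se_ln_re_ref,
            "n_used": self.n_used,
            "n_filtered": self.n_filtered,
            "r2_fit": self.r2_fit,
        }


@dataclass(frozen=True)
class Q10Value:
    """Apparent Q10 at a stated temperature."""

    q10: float
    at_t: float
    dt10: float = DT10

    @property
    def rounded(self) -> float:
        """One-decimal, half-up rounding used in report tables."""
        return float(Decimal(repr(self.q10)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FilteredRespiration:
    """Respiration field with non-positive / near-zero values masked out."""

    field: xr.DataArray
    n_retained: int
    n_filtered: int
    all_filtered: bool = field(default=False)


def respiration(params: ArrheniusParams, temperature) -> np.ndarray | float:
    """Evaluate the Arrhenius respiration response at temperature(s) in K."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t[np.isfinite(t)] <= 0):
        raise DomainError("temperature must be positive (kelvin)")
    out = params.re_ref * np.exp(-(params.ea / K_B) * (1.0 / t - 1.0 / T_REF))
    if np.isscalar(temperature) or np.ndim(temperature) == 0:
        return float(out)
    return out


def filter_respiration(re: xr.DataArray, eps: float = 0.01) -> FilteredRespiration:
    """Mask cell-months whose respiration is negative or close to zero (<= eps)."""
    if eps < 0:
        raise ParameterError(f"eps must be non-negative, got {eps}")
    values = np.asarray(re.values, dtype=float)
    valid = np.isfinite(values)
    drop = valid & (values <= eps)
    out = values.copy()
    out[drop] = np.nan
    n_filtered = int(drop.sum())
    n_retained = int(valid.sum()) - n_filtered
    return FilteredRespiration(
        field=re.copy(data=out),
        n_retained=n_retained,
        n_filtered=n_filtered,
        all_filtered=(n_retained == 0),
    )


def fit_arrhenius(
    re: xr.DataArray,
    temperature: xr.DataArray,
    domain_mask: np.ndarray | None = None,
    eps: float | None = None,
    area_weights: np.ndarray | None = None,
) -> ArrheniusFit:
    """Pooled estimate of (Ea, RE_ref) for one domain.

    Parameters
    ----------
    re
        Respiration field; pass ``eps`` to apply the non-positive-flux filter
        here, or ``eps=None`` if the field is already masked.
    temperature
        Air temperature field on the same grid, K.
    domain_mask
        Optional (lat, lon) boolean selector (biome or continent).
    area_weights
        Optional (lat, lon) weights for an area-weighted regression.
        Defaults to the unweighted pooled fit.
    """
    if re.shape != temperature.shape:
        raise SingularFitError("respiration and temperature grids differ in shape")

    n_filtered = 0
    if eps is not None:
        filtered = filter_respiration(re, eps)
        re = filtered.field
        n_filtered = filtered.n_filtered

    sel = valid_mask(re) & valid_mask(temperature)
    sel &= broadcast_spatial_mask(domain_mask, re.shape)
    t = np.asarray(temperature.values, float)[sel]
    y = np.log(np.asarray(re.values, float)[sel])
    if t.size < 3 or np.unique(t).size < 2:
        raise SingularFitError(
            f"need >= 3 cell-months with >= 2 distinct temperatures, got n={t.size}"
        )
    x = 1.0 / t - 1.0 / T_REF

    if area_weights is None:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        se_slope, se_intercept = res.stderr, res.intercept_stderr
        r2 = res.rvalue**2
    else:
        w3 = np.broadcast_to(np.asarray(area_weights, float)[None, :, :], re.shape)[sel]
        slope, intercept, se_slope, se_intercept, r2 = _weighted_line(x, y, w3)

    return ArrheniusFit(
        params=ArrheniusParams(ea=-slope * K_B, re_ref=float(np.exp(intercept))),
        se_ea=float(se_slope * K_B),
        se_ln_re_ref=float(se_intercept),
        n_used=int(t.size),
        n_filtered=int(n_filtered),
        r2_fit=float(r2),
    )


def _weighted_line(x, y, w):
    """Weighted least squares y = a + b x; returns (b, a, se_b, se_a, r2)."""
    w = w / w.sum()
    xm = np.sum(w * x)
    ym = np.sum(w * y)
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    if sxx == 0:
        raise SingularFitError("no temperature spread under the supplied weights")
    b = sxy / sxx
    a = ym - b * xm
    resid = y - a - b * x
    n = x.size
    s2 = np.sum(w * resid**2) * n / (n - 2)
    se_b = np.sqrt(s2 / (sxx * n))
    se_a = np.sqrt(s2 * (1.0 / n + xm**2 / (sxx * n)))
    syy = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - np.sum(w * resid**2) / syy if syy > 0 else np.nan
    return b, a, se_b, se_a, r2


def ea_to_q10(ea: float, temperature: float = T_REF) -> Q10Value:
    """Apparent Q10 implied by activation energy ``ea`` (eV) at ``temperature`` (K)."""
    if temperature <= 0:
        raise DomainError("temperature must be positive (kelvin)")
    return Q10Value(q10=float(np.exp(ea * DT10 / (K_B * temperature**2))), at_t=float(temperature))


def q10_to_ea(q10: float, temperature: float = T_REF) -> float:
    """Inverse of :func:`ea_to_q10`; returns Ea in eV."""
    if q10 <= 0:
        raise ParameterError(f"q10 must be positive, got {q10}")
    if temperature <= 0:
        raise DomainError("temperature must be positive (kelvin)")
    return float(np.log(q10) * K_B * temperature**2 / DT10)
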