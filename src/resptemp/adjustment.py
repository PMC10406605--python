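"""Adjustment of modelled respiration against atmospheric CO2 variability.

A model's respiration field is adjusted with two parameters — an activation
energy shift dEa (eV) and a baseline scale alpha (dimensionless, > 0):

    RE*(T) = RE(T) * alpha * exp[-(dEa / kB) * (1/T - 1/T_ref)]

(dEa, alpha) are estimated per model and per domain by least squares between
the transported adjusted respiration, H(RE*), and the respiratory component
of the observed CO2 variability. The problem is solved over (dEa, ln alpha),
which keeps alpha positive without constraints, from three starts in dEa to
avoid local minima. Asymptotic standard errors come from the Jacobian at the
optimum.

For biome-specific estimation the adjustment applies only to cells of the
target biome; all other cells keep their original respiration, and all
observations enter the objective through their partial sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import least_squares

from .constants import K_B, T_REF
from .exceptions import ParameterError
from .grids import broadcast_spatial_mask, check_same_grid, valid_mask
from .transport import FootprintOperator, coverage_check, respiratory_component


@dataclass(frozen=True)
class AdjustmentResult:
    """Optimal (dEa, alpha) for one model over one domain."""

    model_id: str
    domain: str
    dea: float                    # eV
    alpha: float                  # dimensionless, > 0
    objective: float              # sum of squared residuals, ppm^2
    n_obs: int
    converged: bool
    dea_se: float                 # eV
    alpha_se: float

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "domain": self.domain,
            "dea": self.dea,
            "alpha": self.alpha,
            "objective": self.objective,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "dea_se": self.dea_se,
            "alpha_se": self.alpha_se,
        }


def arrhenius_shift_factor(temperature, dea: float) -> np.ndarray:
    """exp[-(dEa/kB) (1/T - 1/T_ref)], the temperature-sensitivity shift."""
    t = np.asarray(temperature.values if isinstance(temperature, xr.DataArray) else temperature, float)
    return np.exp(-(dea / K_B) * (1.0 / t - 1.0 / T_REF))


def adjust_respiration(re: xr.DataArray, temperature: xr.DataArray, dea: float,
                       alpha: float, domain_mask: np.ndarray | None = None) -> xr.DataArray:
    """Apply the (dEa, alpha) adjustment inside a domain, identity outside."""
    if not alpha > 0:
        raise ParameterError(f"alpha must be positive, got {alpha}")
    check_same_grid(re, temperature)
    inside = broadcast_spatial_mask(domain_mask, re.shape)
    factor = alpha * arrhenius_shift_factor(temperature, dea)
    out = np.asarray(re.values, float).copy()
    out[inside] = out[inside] * factor[inside]
    return re.copy(data=out)


def optimize_adjustment(
    re: xr.DataArray,
    temperature: xr.DataArray,
    gpp: xr.DataArray,
    footprints: FootprintOperator,
    obs: pd.DataFrame,
    domain_mask: np.ndarray | None = None,
    model_id: str = "model",
    domain: str = "north-america",
    starts: tuple[float, ...] = (-0.3, 0.0, 0.3),
    weights: np.ndarray | None = None,
    ftol: float = 1e-12,
) -> AdjustmentResult:
    """Estimate (dEa, alpha) for one model by matching transported respiration
    to the respiratory component of observed CO2 variability.

    The respiratory component is formed with this model's *own* GPP, so GPP
    bias propagates into the target consistently with how the model would be
    used. Non-convergence is flagged on the result, not raised.
    """
    check_same_grid(re, temperature, gpp)
    y = respiratory_component(obs, footprints, gpp)
    if len(y) < 10:
        raise ParameterError(f"need >= 10 observations, got {len(y)}")

    inside = broadcast_spatial_mask(domain_mask, re.shape) & valid_mask(re)
    coverage_check(footprints, inside.ravel())

    re_flat = np.nan_to_num(np.asarray(re.values, float), nan=0.0).ravel()
    x_exp = ((1.0 / np.asarray(temperature.values, float) - 1.0 / T_REF) / K_B).ravel()
    in_flat = inside.ravel()

    h_in = footprints.matrix[:, in_flat].tocsr()
    re_in = re_flat[in_flat]
    x_in = x_exp[in_flat]
    base_out = footprints.matrix @ np.where(in_flat, 0.0, re_flat)

    sqrt_w = np.sqrt(weights) if weights is not None else None

    def residuals(p):
        dea, ln_alpha = p
        sig = base_out + h_in @ (re_in * np.exp(ln_alpha - dea * x_in))
        r = sig - y
        return r * sqrt_w if sqrt_w is not None else r

    best = None
    for dea0 in starts:
        sol = least_squares(residuals, x0=[dea0, 0.0], method="lm",
                            ftol=ftol, xtol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol

    dea, ln_alpha = best.x
    n = len(y)
    ssr = float(2.0 * best.cost)
    # asymptotic covariance from the Jacobian at the optimum
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * (ssr / max(n - 2, 1))
        dea_se = float(np.sqrt(max(cov[0, 0], 0.0)))
        ln_alpha_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        dea_se = ln_alpha_se = np.nan
    alpha = float(np.exp(ln_alpha))
    return AdjustmentResult(
        model_id=model_id,
        domain=domain,
        dea=float(dea),
        alpha=alpha,
        objective=ssr,
        n_obs=n,
        converged=bool(best.status > 0),
        dea_se=dea_se,
        alpha_se=alpha * ln_alpha_se,   # delta method on ln alpha
    )
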