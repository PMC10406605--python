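"""Ensemble synthesis: the zero-adjustment optimum across models.

Across an ensemble, the adjustment dEa each model needs is linearly and
negatively related to the model's original activation energy Ea. Both axes
carry estimation error, so the line

    dEa = intercept + slope * Ea

is fitted by orthogonal distance regression (scipy.odr) with equal error
variances on both axes. The ensemble-optimal activation energy is where the
line crosses dEa = 0 (no adjustment needed):

    Ea_opt = -intercept / slope

with a 1-sigma uncertainty propagated from the (intercept, slope)
covariance by the delta method. Prediction intervals around the line
combine the parameter covariance with the residual scatter. One-tailed Z
tests compare an estimate against a reference value (e.g. the 0.65 eV
plot-scale sensitivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

with warnings.catch_warnings():
    # the paper-cited ODR implementation; scipy deprecates the module upstream
    warnings.simplefilter("ignore", DeprecationWarning)
    from scipy import odr as scipy_odr

from .exceptions import NoOptimumError, SingularFitError, ParameterError

_LINE = scipy_odr.Model(lambda beta, x: beta[0] * x + beta[1])  # slope, intercept


@dataclass(frozen=True)
class EnsembleFit:
    """ODR line through (Ea, dEa) points and its zero crossing."""

    slope: float
    intercept: float
    cov: np.ndarray               # 2x2 covariance of (slope, intercept)
    ea_opt: float                 # eV
    sigma_opt: float              # eV, 1 sigma
    n_models: int
    resid_var: float              # vertical residual variance (n-2 dof)
    x_mean: float
    excluded_ids: tuple[str, ...] = field(default_factory=tuple)

    def line(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, float)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "cov": self.cov.tolist(),
            "ea_opt": self.ea_opt,
            "sigma_opt": self.sigma_opt,
            "n_models": self.n_models,
            "resid_var": self.resid_var,
            "excluded_ids": list(self.excluded_ids),
        }


@dataclass(frozen=True)
class ZTestResult:
    z: float
    p: float
    null: float
    estimate: float
    se: float
    tail: str


def odr_fit(ea: np.ndarray, dea: np.ndarray,
            excluded_ids: tuple[str, ...] = (),
            min_abs_slope: float = 1e-3) -> EnsembleFit:
    """Fit the dEa-vs-Ea line by orthogonal distance regression.

    ``excluded_ids`` is carried on the result for provenance only; callers
    exclude gated models *before* calling (no leakage into the fit).
    """
    ea = np.asarray(ea, float)
    dea = np.asarray(dea, float)
    if ea.size != dea.size:
        raise SingularFitError("ea and dea lengths differ")
    if ea.size < 3:
        raise SingularFitError(f"need >= 3 models, got {ea.size}")
    if np.unique(ea).size < 2:
        raise SingularFitError("degenerate input: all Ea values equal")

    beta0 = np.polyfit(ea, dea, 1)
    out = scipy_odr.ODR(scipy_odr.Data(ea, dea), _LINE, beta0=list(beta0)).run()
    slope, intercept = out.beta
    cov = out.cov_beta * out.res_var   # scipy scales cov_beta by 1/res_var

    if abs(slope) < min_abs_slope:
        raise NoOptimumError(
            f"|slope| = {abs(slope):.2e} < {min_abs_slope}; zero crossing unstable"
        )
    ea_opt = -intercept / slope
    # delta method: grad of (-a/b) wrt (b=slope, a=intercept)
    grad = np.array([intercept / slope**2, -1.0 / slope])
    sigma_opt = float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    resid = dea - (intercept + slope * ea)
    resid_var = float(np.sum(resid**2) / max(ea.size - 2, 1))
    return EnsembleFit(
        slope=float(slope),
        intercept=float(intercept),
        cov=cov,
        ea_opt=float(ea_opt),
        sigma_opt=sigma_opt,
        n_models=int(ea.size),
        resid_var=resid_var,
        x_mean=float(ea.mean()),
        excluded_ids=tuple(excluded_ids),
    )


def prediction_interval(fit: EnsembleFit, ea_query, level: float = 0.95
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric prediction band around the fitted line at query Ea values.

    Combines the (slope, intercept) covariance with the residual variance;
    the quantile is Student-t with n - 2 degrees of freedom.
    """
    if not 0.0 < level < 1.0:
        raise ParameterError(f"level must lie in (0, 1), got {level}")
    x = np.asarray(ea_query, float)
    center = fit.line(x)
    var_line = (fit.cov[1, 1] + 2.0 * x * fit.cov[0, 1] + x**2 * fit.cov[0, 0])
    half = stats.t.ppf(0.5 + level / 2.0, df=max(fit.n_models - 2, 1)) \
        * np.sqrt(np.clip(fit.resid_var + var_line, 0.0, None))
    return center - half, center + half


def z_compare(estimate: float, se: float, null: float, tail: str = "one") -> ZTestResult:
    """Z test of ``estimate`` against ``null``; one-tailed tests the
    alternative that the estimate is below the null."""
    if se <= 0:
        raise ParameterError(f"se must be positive, got {se}")
    z = (null - estimate) / se
    if tail == "one":
        p = float(stats.norm.sf(z))
    elif tail == "two":
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ParameterError(f"tail must be 'one' or 'two', got {tail!r}")
    return ZTestResult(z=float(z), p=p, null=null, estimate=estimate, se=se, tail=tail)
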