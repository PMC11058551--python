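"""Maximum-likelihood fitting of the Weibull proportional-hazards model.

The model for a right-censored subject i with covariates (x_i, z_i),
observed time t_i and event indicator d_i has log-likelihood contribution

    d_i * (ln g + (g - 1) * ln t_i + lp_i) - exp(lp_i) * t_i**g

with lp_i = b0 + b1*x_i + b2*z_i and shape g > 0. Positivity of the shape
is enforced by optimizing ln g. The fitter is a damped Newton-Raphson on
the analytic gradient and Hessian; the covariance matrix is the inverse
observed information at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .dgm import Cohort, WeibullOutcomeModel

__all__ = [
    "FitResult",
    "WaldSummary",
    "weibull_ph_loglik",
    "fit_weibull_ph",
    "wald_hr_test",
    "wald_summary",
    "predict_survival",
]

COEF_NAMES = ("intercept", "exposure", "confounder")

_GRAD_TOL = 1e-8
_RELL_TOL = 1e-12
_MAX_ITER = 200


class NoEventsError(ValueError):
    """Raised when a cohort contains no observed events."""


class NotConvergedError(RuntimeError):
    """Raised when a downstream computation requires a converged fit."""


@dataclass(frozen=True)
class FitResult:
    """MLE of the Weibull PH model on the (beta, ln gamma) scale."""

    coefficients: np.ndarray  # (intercept, exposure, confounder)
    log_gamma: float
    covariance: np.ndarray  # over (coefficients, log_gamma), or (3,3) if shape fixed
    loglik: float
    converged: bool
    n_events: int
    n_subjects: int
    n_iter: int = 0
    gamma_fixed: bool = False
    message: str = ""

    @property
    def gamma(self) -> float:
        return math.exp(self.log_gamma)

    @property
    def se(self) -> np.ndarray:
        """Standard errors for (coefficients[, log_gamma])."""
        return np.sqrt(np.diag(self.covariance))

    def se_gamma(self) -> float:
        """Delta-method SE for gamma itself."""
        if self.gamma_fixed:
            return 0.0
        return float(self.gamma * self.se[3])

    def to_dict(self) -> dict:
        d = {
            "coefficients": {n: float(b) for n, b in zip(COEF_NAMES, self.coefficients)},
            "gamma": self.gamma,
            "log_gamma": self.log_gamma,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_events": self.n_events,
            "n_subjects": self.n_subjects,
            "se": {n: float(s) for n, s in zip(COEF_NAMES, self.se[:3])},
        }
        if not self.gamma_fixed:
            d["se"]["log_gamma"] = float(self.se[3])
        return d

    def summary(self, level: float = 0.95) -> str:
        """Plain-text fit report."""
        lines = [
            "Weibull proportional-hazards fit "
            f"(n={self.n_subjects}, events={self.n_events}, "
            f"loglik={self.loglik:.4f}, converged={self.converged})",
            f"{'term':<12}{'coef':>10}{'se':>10}{'HR':>10}"
            f"{'ci_low':>10}{'ci_high':>10}{'z':>9}{'p':>10}",
        ]
        for idx, name in enumerate(COEF_NAMES):
            w = wald_summary(float(self.coefficients[idx]), float(self.se[idx]), level)
            lines.append(
                f"{name:<12}{w.estimate:>10.4f}{w.se:>10.4f}{w.hr:>10.4f}"
                f"{w.ci_low:>10.4f}{w.ci_high:>10.4f}{w.z:>9.3f}{w.p_two_sided:>10.4g}"
            )
        shape_se = "fixed" if self.gamma_fixed else f"se(ln g)={self.se[3]:.4f}"
        lines.append(f"shape gamma = {self.gamma:.4f} ({shape_se})")
        return "\n".join(lines)


@dataclass(frozen=True)
class WaldSummary:
    """Wald test and CI for one log-hazard-ratio coefficient."""

    estimate: float
    se: float
    z: float
    p_two_sided: float
    hr: float
    ci_low: float
    ci_high: float
    level: float

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "p_two_sided": self.p_two_sided,
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
        }


def _design(cohort: Cohort):
    t = np.asarray(cohort.time, dtype=float)
    if np.any(t <= 0):
        raise ValueError("all observed times must be positive")
    d = np.asarray(cohort.event, dtype=float)
    X = np.column_stack(
        [
            np.ones(len(cohort)),
            np.asarray(cohort.x, dtype=float),
            np.asarray(cohort.z, dtype=float),
        ]
    )
    return t, d, X


def weibull_ph_loglik(
    coefficients: Sequence[float], log_gamma: float, cohort: Cohort
) -> float:
    """Right-censored Weibull PH log-likelihood at the given parameters."""
    t, d, X = _design(cohort)
    beta = np.asarray(coefficients, dtype=float)
    g = math.exp(log_gamma)
    lp = X @ beta
    logt = np.log(t)
    ll = d * (log_gamma + (g - 1.0) * logt + lp) - np.exp(lp) * t**g
    return float(np.sum(ll))


def _ll_grad_hess(theta, t, d, X, logt, fixed_log_gamma=None):
    """Log-likelihood, gradient and Hessian at theta = (beta[, ln gamma])."""
    if fixed_log_gamma is None:
        beta, eta = theta[:3], theta[3]
    else:
        beta, eta = theta, fixed_log_gamma
    g = math.exp(eta)
    lp = X @ beta
    w = np.exp(lp)
    u = t**g
    wu = w * u
    glogt = g * logt

    ll = float(np.sum(d * (eta + (g - 1.0) * logt + lp) - wu))

    resid = d - wu
    grad_beta = X.T @ resid
    if fixed_log_gamma is None:
        grad_eta = float(np.sum(d * (1.0 + glogt) - wu * glogt))
        grad = np.append(grad_beta, grad_eta)
    else:
        grad = grad_beta

    Hbb = -(X * wu[:, None]).T @ X
    if fixed_log_gamma is None:
        hbe = -(X * (wu * glogt)[:, None]).sum(axis=0)
        hee = float(np.sum(glogt * resid - wu * glogt**2))
        H = np.empty((4, 4))
        H[:3, :3] = Hbb
        H[:3, 3] = hbe
        H[3, :3] = hbe
        H[3, 3] = hee
    else:
        H = Hbb
    return ll, grad, H


def fit_weibull_ph(
    cohort: Cohort,
    level: float = 0.95,
    fixed_gamma: Optional[float] = None,
    max_iter: int = _MAX_ITER,
) -> FitResult:
    """Fit the Weibull PH model by damped Newton-Raphson.

    Parameters
    ----------
    cohort
        Right-censored sample with binary exposure and confounder.
    level
        Retained for interface symmetry; CIs are produced by
        :func:`wald_hr_test` at any level from the stored covariance.
    fixed_gamma
        If given, the shape is held at this value and only the three
        regression coefficients are estimated (exponential sub-model for
        ``fixed_gamma=1``). The default estimates the shape.
    """
    t, d, X = _design(cohort)
    n_events = int(d.sum())
    if n_events == 0:
        raise NoEventsError("cohort contains no events; the model is not identifiable")
    logt = np.log(t)

    fixed_eta = None if fixed_gamma is None else math.log(fixed_gamma)
    n_par = 4 if fixed_eta is None else 3
    # exponential moment start: overall event rate, no covariate effects
    theta = np.zeros(n_par)
    theta[0] = math.log(n_events / float(t.sum()))

    ll, grad, H = _ll_grad_hess(theta, t, d, X, logt, fixed_eta)
    converged = False
    message = "max iterations reached"
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < _GRAD_TOL:
            converged = True
            message = "gradient below tolerance"
            break
        try:
            step = np.linalg.solve(H, grad)  # Newton step is theta - step
        except np.linalg.LinAlgError:
            ridge = 1e-8 * (1.0 + np.abs(np.diag(H)))
            step = np.linalg.solve(H - np.diag(ridge), grad)
        # damped update: halve until the log-likelihood does not decrease
        scale = 1.0
        for _ in range(40):
            candidate = theta - scale * step
            try:
                with np.errstate(over="ignore", invalid="ignore"):
                    ll_new, grad_new, H_new = _ll_grad_hess(
                        candidate, t, d, X, logt, fixed_eta
                    )
            except OverflowError:
                ll_new = -math.inf
            if math.isfinite(ll_new) and ll_new >= ll - 1e-13 * abs(ll):
                break
            scale *= 0.5
        else:
            message = "line search failed"
            break
        rel_change = abs(ll_new - ll) / (abs(ll) + 1.0)
        theta, ll, grad, H = candidate, ll_new, grad_new, H_new
        if rel_change < _RELL_TOL and np.max(np.abs(grad)) < 1e-4:
            converged = True
            message = "log-likelihood change below tolerance"
            break

    try:
        cov = np.linalg.inv(-H)
        if converged and np.any(np.diag(cov) <= 0):
            converged = False
            message = "information matrix not positive definite"
    except np.linalg.LinAlgError:
        cov = np.full((n_par, n_par), np.nan)
        converged = False
        message = "information matrix singular"

    return FitResult(
        coefficients=theta[:3].copy(),
        log_gamma=float(theta[3]) if fixed_eta is None else fixed_eta,
        covariance=cov,
        loglik=ll,
        converged=converged,
        n_events=n_events,
        n_subjects=len(cohort),
        n_iter=n_iter,
        gamma_fixed=fixed_eta is not None,
        message=message,
    )


def wald_summary(estimate: float, se: float, level: float = 0.95) -> WaldSummary:
    """Wald z test and CI on the hazard-ratio scale from (estimate, se)."""
    if not se > 0:
        raise ValueError(f"se must be positive, got {se}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = estimate / se
    p = 2.0 * stats.norm.sf(abs(z))
    crit = stats.norm.ppf(0.5 + level / 2.0)  # exact quantile, not 1.96

    def _exp(v: float) -> float:  # wild estimates from near-separated fits
        try:
            return math.exp(v)
        except OverflowError:
            return math.inf

    return WaldSummary(
        estimate=float(estimate),
        se=float(se),
        z=float(z),
        p_two_sided=float(p),
        hr=_exp(estimate),
        ci_low=_exp(estimate - crit * se),
        ci_high=_exp(estimate + crit * se),
        level=level,
    )


def wald_hr_test(fit: FitResult, coefficient: int = 1, level: float = 0.95) -> WaldSummary:
    """Wald test for one coefficient of a converged fit (default: exposure)."""
    if not fit.converged:
        raise NotConvergedError(
            f"fit did not converge ({fit.message}); Wald inference refused"
        )
    est = float(fit.coefficients[coefficient])
    se = float(np.sqrt(fit.covariance[coefficient, coefficient]))
    return wald_summary(est, se, level)


def predict_survival(
    model_or_fit: Union[WeibullOutcomeModel, FitResult], times, x: int, z: int
) -> np.ndarray:
    """Model-based survival probabilities S(t | x, z) on a time grid.

    Accepts either the generating outcome model or a fitted result;
    S(t) = exp(-exp(lp) * t**gamma) is non-increasing with S(0) = 1.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if isinstance(model_or_fit, FitResult):
        b0, b1, b2 = model_or_fit.coefficients
        gamma = model_or_fit.gamma
    else:
        b0, b1, b2 = model_or_fit.beta0, model_or_fit.beta1, model_or_fit.beta2
        gamma = model_or_fit.gamma
    lp = b0 + b1 * x + b2 * z
    return np.exp(-np.exp(lp) * times**gamma)
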