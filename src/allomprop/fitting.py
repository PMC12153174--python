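"""Nonlinear least-squares fitting of the component models.

Covers the four steps that turn raw tree measurements into the fitted
system used by the Monte Carlo propagation:

1. unweighted nonlinear least squares for each component model form, with
   log-linearised OLS starting values;
2. bootstrap parameter ensembles (resampling unit = tree, so correlated
   stem-profile rows move together) approximating the joint sampling
   distribution of the coefficients;
3. grouped residual summaries — observations ordered by observed value and
   cut into equal-sized sequential groups of at least 25 — giving per-group
   mean prediction and residual SD;
4. least-squares fits of the power / bell residual-SD functions to those
   group summaries.

Scalar conversion factors (wood specific gravity, carbon fraction) are
summarised as sample means with standard errors of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (
    DEFAULT_SEGMENTATION_DBH,
    PARAM_CLASSES,
    PARAM_NAMES,
    VarianceFnParams,
)

__all__ = [
    "FitError",
    "EnsembleError",
    "FitResult",
    "ParameterEnsemble",
    "ResidualGroups",
    "ScalarMeanEstimate",
    "fit_model",
    "bootstrap_ensemble",
    "group_residuals",
    "fit_variance_fn",
    "se_of_mean",
]

#: Convergence tolerance on relative parameter change and max iterations.
XTOL = 1e-8
MAX_NFEV = 200 * 10  # generous evaluation budget for <=4-parameter problems

ALLOMETRIC_COLUMNS = ("tree_id", "D_cm", "H_m", "y")
PROFILE_COLUMNS = ("tree_id", "h_m", "H_m", "R")


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge."""


class EnsembleError(RuntimeError):
    """Too many bootstrap refits failed."""


@dataclass
class FitResult:
    """Point estimate of one component model with fit diagnostics."""

    form: str
    theta: np.ndarray
    param_names: tuple[str, ...]
    n_obs: int
    sse: float
    r_squared: float
    residuals: np.ndarray = field(repr=False)

    @property
    def params(self):
        """Typed parameter object for the fitted form."""
        return PARAM_CLASSES[self.form](*self.theta)

    def residual_summary(self) -> dict[str, float]:
        r = self.residuals
        return {
            "min": float(np.min(r)),
            "mean": float(np.mean(r)),
            "max": float(np.max(r)),
            "sd": float(np.std(r, ddof=1)),
        }


@dataclass
class ParameterEnsemble:
    """Bootstrap sample of parameter vectors for one component model."""

    component: str
    form: str
    point: np.ndarray
    draws: np.ndarray  # (B, p)
    seed: Optional[int] = None
    n_retried: int = 0

    @property
    def n_draws(self) -> int:
        return int(self.draws.shape[0])

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def cov(self) -> np.ndarray:
        return np.cov(self.draws, rowvar=False)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One parameter vector drawn uniformly from the ensemble rows."""
        return self.draws[rng.integers(self.n_draws)]


@dataclass
class ResidualGroups:
    """Equal-sized sequential residual groups (ordered by observed value)."""

    y_hat_mean: np.ndarray
    residual_sd: np.ndarray
    sizes: np.ndarray
    single_group: bool = False

    @property
    def n_groups(self) -> int:
        return int(self.sizes.size)


@dataclass(frozen=True)
class ScalarMeanEstimate:
    """Sample mean with its standard error (wood specific gravity, carbon
    fraction)."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")

    @classmethod
    def from_sample(cls, values: Sequence[float]) -> "ScalarMeanEstimate":
        x = np.asarray(values, dtype=float)
        n = x.size
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        return cls(mean=float(np.mean(x)), se=se_of_mean(sd, n), n=n)


def se_of_mean(sd: float, n: int) -> float:
    """Standard error of a sample mean, ``sd / sqrt(n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return float(sd) / float(np.sqrt(n))


def _is_profile_form(form: str) -> bool:
    return form == "ratio"


def _design(form: str, data: pd.DataFrame):
    if _is_profile_form(form):
        return np.asarray(data["h_m"], float), np.asarray(data["H_m"], float), np.asarray(
            data["R"], float
        )
    return np.asarray(data["D_cm"], float), np.asarray(data["H_m"], float), np.asarray(
        data["y"], float
    )


def _predict(form: str, theta, x1, x2):
    """Raw model kernels without parameter validation.

    The optimiser may transiently explore parameter values the typed
    parameter classes reject (e.g. a <= 0); the formulas themselves remain
    evaluable there, so fitting uses unchecked kernels and validity is
    enforced on the converged estimate.
    """
    theta = np.asarray(theta, dtype=float)
    if form == "power":
        a, b, c = theta
        return a * x1**b * x2**c
    if form == "segmented":
        a, b, c, b1 = theta
        k = DEFAULT_SEGMENTATION_DBH
        return np.where(
            x1 < k,
            a * x1**b * x2**c,
            a * k ** (b - b1) * x1**b1 * x2**c,
        )
    if form == "exp_decay":
        a, b, c, b1 = theta
        return a * x1**b * x2**c * np.exp(-b1 * x1)
    if form == "ratio":
        alpha, beta = theta
        base = 1.0 - (1.0 - x1 / x2) ** alpha
        return np.sign(base) * np.abs(base) ** beta
    raise ValueError(f"unknown model form {form!r}")


def _start_values(form: str, x1, x2, y) -> np.ndarray:
    """Log-linearised OLS starts for the power-type forms; (2, 1) for the
    ratio curve. The damping coefficient of the exponential-decay form starts
    at 0; the upper-segment exponent of the segmented form starts at b (a
    start on the plain power law), which keeps the initial model continuous
    and well inside the basin of attraction."""
    if form == "ratio":
        return np.array([2.0, 1.0])
    mask = y > 0
    X = np.column_stack(
        [np.ones(mask.sum()), np.log(x1[mask]), np.log(x2[mask])]
    )
    beta, *_ = np.linalg.lstsq(X, np.log(y[mask]), rcond=None)
    a = float(np.exp(beta[0]))
    b, c = float(beta[1]), float(beta[2])
    if form == "power":
        return np.array([a, b, c])
    if form == "exp_decay":
        return np.array([a, b, c, 0.0])
    if form == "segmented":
        return np.array([a, b, c, b])
    raise ValueError(f"unknown model form {form!r}")


def fit_model(
    form: str,
    data: pd.DataFrame,
    start: Optional[Sequence[float]] = None,
    fixed: Optional[dict[str, float]] = None,
) -> FitResult:
    """Fit one component model by unweighted nonlinear least squares.

    ``data`` uses the flat schemas ``(tree_id, D_cm, H_m, y)`` for the
    allometric forms and ``(tree_id, h_m, H_m, R)`` for the ratio form.
    ``fixed`` pins named parameters at given values (they are excluded from
    the optimisation), which is occasionally useful for degenerate checks.
    Reported R^2 is the pseudo-R^2 ``1 - SSE/SST``.
    """
    x1, x2, y = _design(form, data)
    return _fit_arrays(form, x1, x2, y, start=start, fixed=fixed)


def _fit_arrays(
    form: str,
    x1: np.ndarray,
    x2: np.ndarray,
    y: np.ndarray,
    start: Optional[Sequence[float]] = None,
    fixed: Optional[dict[str, float]] = None,
) -> FitResult:
    names = PARAM_NAMES[form]
    n = y.size
    if n < len(names) + 1:
        raise FitError(f"need at least {len(names) + 1} observations, got {n}")
    theta0 = np.asarray(start, float) if start is not None else _start_values(form, x1, x2, y)
    fixed = dict(fixed or {})
    free_idx = [i for i, nm in enumerate(names) if nm not in fixed]
    full0 = theta0.copy()
    for i, nm in enumerate(names):
        if nm in fixed:
            full0[i] = fixed[nm]

    def expand(free: np.ndarray) -> np.ndarray:
        theta = full0.copy()
        theta[free_idx] = free
        return theta

    def resid(free: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            yhat = _predict(form, expand(free), x1, x2)
        yhat = np.nan_to_num(yhat, nan=1e9, posinf=1e9, neginf=-1e9)
        return yhat - y

    sol = least_squares(
        resid, full0[free_idx], method="lm", xtol=XTOL, ftol=XTOL, gtol=XTOL,
        max_nfev=MAX_NFEV,
    )
    if not sol.success:
        raise FitError(
            f"{form} fit did not converge: status={sol.status} {sol.message!r} "
            f"nfev={sol.nfev}"
        )
    theta = expand(sol.x)
    res = y - _predict(form, theta, x1, x2)
    sse = float(np.sum(res**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return FitResult(
        form=form,
        theta=theta,
        param_names=names,
        n_obs=n,
        sse=sse,
        r_squared=r2,
        residuals=res,
    )


def bootstrap_ensemble(
    form: str,
    data: pd.DataFrame,
    n_boot: int = 2500,
    seed: Optional[int] = None,
    component: str = "",
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 10,
) -> ParameterEnsemble:
    """Bootstrap the joint sampling distribution of a model's coefficients.

    The resampling unit is the TREE: for stem-profile data all rows of a
    resampled tree enter together, because within-tree ratio observations
    are strongly correlated. Each resample is refit starting from the
    full-data point estimate; a failed refit redraws the resample (up to
    ``max_retries`` times) so the ensemble size stays exact.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    point = fit_model(form, data)
    if rng is None:
        rng = np.random.default_rng(seed)
    tree_ids = data["tree_id"].to_numpy()
    unique_ids, inverse = np.unique(tree_ids, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    sorted_inverse = inverse[order]
    starts = np.searchsorted(sorted_inverse, np.arange(unique_ids.size))
    ends = np.searchsorted(sorted_inverse, np.arange(unique_ids.size), side="right")
    x1, x2, y = _design(form, data)
    x1s, x2s, ys = x1[order], x2[order], y[order]
    n_trees = unique_ids.size

    lengths = ends - starts
    draws = np.empty((n_boot, point.theta.size))
    n_retried = 0
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            pick = rng.integers(n_trees, size=n_trees)
            L = lengths[pick]
            rows = np.repeat(starts[pick], L) + (
                np.arange(L.sum()) - np.repeat(np.cumsum(L) - L, L)
            )
            try:
                fit = _fit_arrays(form, x1s[rows], x2s[rows], ys[rows], start=point.theta)
                if fit.theta[0] <= 0:
                    raise FitError("non-positive scale coefficient in refit")
                draws[b] = fit.theta
                break
            except FitError:
                n_retried += 1
                if attempt == max_retries:
                    raise EnsembleError(
                        f"bootstrap refit {b} failed after {max_retries} redraws"
                    )
    if n_retried > 0.01 * n_boot * max_retries:
        raise EnsembleError(f"excessive bootstrap refit failures: {n_retried}")
    return ParameterEnsemble(
        component=component or form,
        form=form,
        point=point.theta,
        draws=draws,
        seed=seed,
        n_retried=n_retried,
    )


def group_residuals(
    data: pd.DataFrame,
    form: str,
    theta: Sequence[float],
    min_group: int = 25,
    order_by: str = "observed",
) -> ResidualGroups:
    """Per-group mean prediction and residual SD for the variance-function fit.

    Observations are ordered by observed value (component ``y`` or ratio
    ``R``) and cut into ``Q = floor(n / min_group)`` equal-sized sequential
    groups; the remainder is absorbed into the last group. With fewer than
    ``2 * min_group`` observations a single-group result is returned with a
    warning.

    ``order_by="predicted"`` orders on the fitted values instead. Ordering on
    the observed scale follows the published procedure but selects on the
    residual noise (group SDs then mix in the spread of predictions at a
    given observed value), so calibration studies that compare the fitted
    SD function against a known generating process should order on the
    predicted scale, where group membership is independent of the noise.
    """
    if order_by not in ("observed", "predicted"):
        raise ValueError("order_by must be 'observed' or 'predicted'")
    x1, x2, y = _design(form, data)
    n = y.size
    yhat_all = _predict(form, np.asarray(theta, float), x1, x2)
    order = np.argsort(y if order_by == "observed" else yhat_all, kind="stable")
    y, yhat = y[order], yhat_all[order]
    res = y - yhat
    if n < 2 * min_group:
        warnings.warn(
            f"only {n} observations; returning a single residual group",
            stacklevel=2,
        )
        return ResidualGroups(
            y_hat_mean=np.array([yhat.mean()]),
            residual_sd=np.array([np.std(res, ddof=1)]),
            sizes=np.array([n]),
            single_group=True,
        )
    q = n // min_group
    bounds = [(i * min_group, (i + 1) * min_group if i < q - 1 else n) for i in range(q)]
    return ResidualGroups(
        y_hat_mean=np.array([yhat[s:e].mean() for s, e in bounds]),
        residual_sd=np.array([np.std(res[s:e], ddof=1) for s, e in bounds]),
        sizes=np.array([e - s for s, e in bounds]),
    )


def _fit_curve(
    fun: Callable[[np.ndarray], np.ndarray], u0: np.ndarray, label: str
) -> np.ndarray:
    sol = least_squares(fun, u0, method="lm", xtol=XTOL, ftol=XTOL, gtol=XTOL,
                        max_nfev=MAX_NFEV)
    if not sol.success:
        raise FitError(f"{label} variance-function fit did not converge: {sol.message!r}")
    return sol.x


def fit_variance_fn(groups: ResidualGroups, form: str) -> tuple[VarianceFnParams, dict]:
    """Least-squares fit of a residual-SD function to group summaries.

    Power form ``phi1 * ybar**phi2`` (log-linear start); bell form
    ``phi1 * phi2**((ybar - phi3)**2)`` (positivity enforced through a log
    reparameterisation of phi1 and phi2). Returns the fitted parameters and
    a dict with R^2 and RMSE of the group-level fit.
    """
    ybar = groups.y_hat_mean
    sd = groups.residual_sd
    n_min = 2 if form == "power" else 4  # 2 groups saturate the power form exactly
    if groups.n_groups < n_min:
        raise FitError(f"{form} variance function needs >= {n_min} groups")
    if form == "power":
        X = np.column_stack([np.ones(ybar.size), np.log(ybar)])
        beta, *_ = np.linalg.lstsq(X, np.log(np.maximum(sd, 1e-300)), rcond=None)
        u0 = np.array([beta[0], beta[1]])  # (ln phi1, phi2)

        def resid(u):
            return np.exp(u[0]) * ybar ** u[1] - sd

        u = _fit_curve(resid, u0, "power")
        params = VarianceFnParams("power", float(np.exp(u[0])), float(u[1]))
        fitted = params.phi1 * ybar**params.phi2
    elif form == "bell":
        i_max = int(np.argmax(sd))
        phi3_0 = float(ybar[i_max])
        phi1_0 = float(sd[i_max])
        dev2 = (ybar - phi3_0) ** 2
        mask = dev2 > 0
        slope = float(
            np.sum(dev2[mask] * np.log(np.maximum(sd[mask], 1e-300) / phi1_0))
            / np.sum(dev2[mask] ** 2)
        )
        u0 = np.array([np.log(phi1_0), min(slope, -1e-6), phi3_0])  # (ln phi1, ln phi2, phi3)

        def resid(u):
            return np.exp(u[0]) * np.exp(u[1] * (ybar - u[2]) ** 2) - sd

        u = _fit_curve(resid, u0, "bell")
        params = VarianceFnParams(
            "bell", float(np.exp(u[0])), float(np.exp(u[1])), float(u[2])
        )
        fitted = params.phi1 * params.phi2 ** ((ybar - params.phi3) ** 2)
    else:
        raise ValueError(f"unknown variance-function form {form!r}")
    sse = float(np.sum((sd - fitted) ** 2))
    sst = float(np.sum((sd - sd.mean()) ** 2))
    stats = {
        "r_squared": 1.0 - sse / sst if sst > 0 else 1.0,
        "rmse": float(np.sqrt(sse / sd.size)),
    }
    return params, stats
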