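"""Allometric model forms and residual-variance functions for white pine.

The compatible prediction system is built from four regression forms that
map tree size (dbh ``D`` in cm, total height ``H`` in m) to stem/crown
components, plus two heteroscedastic residual-SD functions fitted to grouped
residuals:

* power law            ``y = a * D**b * H**c``                 (whole-stem
  outside-bark volume, branch biomass, aboveground biomass)
* segmented power law  ``y = a * D**b * H**c`` below the segmentation
  diameter ``k`` and ``y = a * k**(b-b1) * D**b1 * H**c`` above it, continuous
  at ``D = k`` (bark volume and bark biomass; ``k`` = 22.86 cm for white pine)
* exponential decay    ``y = a * D**b * H**c * exp(-b1*D)``    (inside-bark
  stem volume)
* volume ratio         ``R(h) = (1 - (1 - h/H)**alpha)**beta`` (cumulative
  share of stem volume below height ``h``)

Residual SD as a function of the predicted value:

* power form  ``sigma = phi1 * yhat**phi2``        (volume/biomass components)
* bell form   ``sigma = phi1 * phi2**((yhat-phi3)**2)`` (ratio components;
  peaks at ``yhat = phi3`` when ``phi2 < 1``)

All prediction functions are vectorised over numpy arrays and return the
deterministic conditional mean; stochastic perturbation lives in
:mod:`allomprop.propagate`. Units follow field convention with no conversion
layer: D in cm, heights in m, volumes in m^3, masses in kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DEFAULT_SEGMENTATION_DBH",
    "PowerLawParams",
    "SegmentedParams",
    "ExpDecayParams",
    "RatioParams",
    "VarianceFnParams",
    "COMPONENT_FORMS",
    "COMPONENT_VARIANCE_FORMS",
    "VOLUME_COMPONENTS",
    "BIOMASS_COMPONENTS",
    "RATIO_COMPONENTS",
    "InvalidParameterError",
    "predict_power",
    "predict_segmented",
    "predict_exp_decay",
    "predict_ratio",
    "predict_component",
    "residual_sd",
]

#: White-pine segmentation diameter for the segmented power law, cm (9 in).
DEFAULT_SEGMENTATION_DBH = 22.86


class InvalidParameterError(ValueError):
    """Raised when a parameter set produces non-finite predictions."""


@dataclass(frozen=True)
class PowerLawParams:
    """Coefficients of ``y = a * D**b * H**c``."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise InvalidParameterError(f"power-law scale a must be > 0, got {self.a}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)


@dataclass(frozen=True)
class SegmentedParams:
    """Coefficients of the segmented power law with join diameter ``k`` (cm).

    The two branches agree at ``D = k`` by construction:
    ``a * k**(b-b1) * k**b1 = a * k**b``.
    """

    a: float
    b: float
    c: float
    b1: float
    k: float = DEFAULT_SEGMENTATION_DBH

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise InvalidParameterError(f"segmented scale a must be > 0, got {self.a}")
        if not self.k > 0:
            raise InvalidParameterError(f"segmentation diameter k must be > 0, got {self.k}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.b1], dtype=float)


@dataclass(frozen=True)
class ExpDecayParams:
    """Coefficients of ``y = a * D**b * H**c * exp(-b1*D)``."""

    a: float
    b: float
    c: float
    b1: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise InvalidParameterError(f"exp-decay scale a must be > 0, got {self.a}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.b1], dtype=float)


@dataclass(frozen=True)
class RatioParams:
    """Shape coefficients of the cumulative volume-ratio curve.

    ``R(h) = (1 - (1 - h/H)**alpha)**beta`` with ``R(0) = 0`` and ``R(H) = 1``
    for any ``alpha, beta > 0``; strictly increasing in ``h``.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise InvalidParameterError(
                f"ratio shape parameters must be > 0, got alpha={self.alpha}, beta={self.beta}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta], dtype=float)


@dataclass(frozen=True)
class VarianceFnParams:
    """Residual-SD function: ``power`` or ``bell`` form.

    power: ``sigma(yhat) = phi1 * yhat**phi2`` (requires ``yhat > 0``)
    bell:  ``sigma(yhat) = phi1 * phi2**((yhat - phi3)**2)``
    """

    form: str
    phi1: float
    phi2: float
    phi3: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if self.form not in ("power", "bell"):
            raise InvalidParameterError(f"unknown variance-function form {self.form!r}")
        if not self.phi1 > 0:
            raise InvalidParameterError(f"phi1 must be > 0, got {self.phi1}")
        if self.form == "bell":
            if not self.phi2 > 0:
                raise InvalidParameterError(f"bell phi2 must be > 0, got {self.phi2}")
            if self.phi3 is None:
                raise InvalidParameterError("bell form requires phi3")

    def as_array(self) -> np.ndarray:
        if self.form == "bell":
            return np.array([self.phi1, self.phi2, self.phi3], dtype=float)
        return np.array([self.phi1, self.phi2], dtype=float)


#: Model form used for each component, following the white-pine system.
COMPONENT_FORMS = {
    "TSV_IB": "exp_decay",
    "TSV_BK": "segmented",
    "TSV_OB": "power",
    "B_BK": "segmented",
    "B_BR": "power",
    "B_AG": "power",
    "R_IB": "ratio",
    "R_OB": "ratio",
}

#: Residual-SD function form used for each component.
COMPONENT_VARIANCE_FORMS = {
    "TSV_IB": "power",
    "TSV_BK": "power",
    "TSV_OB": "power",
    "B_BK": "power",
    "B_BR": "power",
    "B_AG": "power",
    "R_IB": "bell",
    "R_OB": "bell",
}

VOLUME_COMPONENTS = ("TSV_IB", "TSV_BK", "TSV_OB")
BIOMASS_COMPONENTS = ("B_BK", "B_BR", "B_AG")
RATIO_COMPONENTS = ("R_IB", "R_OB")

PARAM_CLASSES = {
    "power": PowerLawParams,
    "segmented": SegmentedParams,
    "exp_decay": ExpDecayParams,
    "ratio": RatioParams,
}

PARAM_NAMES = {
    "power": ("a", "b", "c"),
    "segmented": ("a", "b", "c", "b1"),
    "exp_decay": ("a", "b", "c", "b1"),
    "ratio": ("alpha", "beta"),
}


def _validate_size(dbh, height) -> tuple[np.ndarray, np.ndarray]:
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(dbh <= 0) or np.any(height <= 0):
        raise ValueError("dbh and height must be strictly positive")
    return dbh, height


def _check_finite(y: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(y)):
        raise InvalidParameterError("model prediction is non-finite")
    return y


def predict_power(params: PowerLawParams, dbh, height):
    """Mean of the power-law form ``a * D**b * H**c``."""
    dbh, height = _validate_size(dbh, height)
    y = params.a * dbh**params.b * height**params.c
    return _check_finite(y)


def predict_segmented(params: SegmentedParams, dbh, height):
    """Mean of the segmented power law, continuous at ``D = k``."""
    dbh, height = _validate_size(dbh, height)
    lower = params.a * dbh**params.b * height**params.c
    upper = (
        params.a
        * params.k ** (params.b - params.b1)
        * dbh**params.b1
        * height**params.c
    )
    y = np.where(dbh < params.k, lower, upper)
    return _check_finite(y)


def predict_exp_decay(params: ExpDecayParams, dbh, height):
    """Mean of the exponentially damped power law ``a*D**b*H**c*exp(-b1*D)``."""
    dbh, height = _validate_size(dbh, height)
    y = params.a * dbh**params.b * height**params.c * np.exp(-params.b1 * dbh)
    return _check_finite(y)


def predict_ratio(params: RatioParams, h, height):
    """Cumulative volume ratio ``R(h) = (1-(1-h/H)**alpha)**beta``.

    ``h`` is height along the stem; must lie in ``[0, H]`` (no clamping —
    out-of-domain inputs raise so the caller sees the error).
    """
    h = np.asarray(h, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise ValueError("total height must be strictly positive")
    if np.any(h < 0) or np.any(h > height):
        raise ValueError("stem height h must lie within [0, H]")
    rel = 1.0 - h / height
    y = (1.0 - rel**params.alpha) ** params.beta
    return _check_finite(y)


def predict_component(form: str, theta, dbh=None, height=None, h=None):
    """Dispatch a prediction from a raw parameter vector by form name.

    ``theta`` is an array in the order given by :data:`PARAM_NAMES`. For the
    ratio form pass ``h`` and ``height``; otherwise ``dbh`` and ``height``.
    """
    theta = np.asarray(theta, dtype=float)
    if form == "power":
        return predict_power(PowerLawParams(*theta), dbh, height)
    if form == "segmented":
        return predict_segmented(SegmentedParams(*theta), dbh, height)
    if form == "exp_decay":
        return predict_exp_decay(ExpDecayParams(*theta), dbh, height)
    if form == "ratio":
        return predict_ratio(RatioParams(*theta), h, height)
    raise ValueError(f"unknown model form {form!r}")


def residual_sd(params: VarianceFnParams, y_hat):
    """Residual standard deviation at predicted value ``y_hat``.

    Power form requires ``y_hat > 0``; the bell form is defined everywhere
    and attains its maximum ``phi1`` at ``y_hat = phi3`` when ``phi2 < 1``.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    if not np.all(np.isfinite(y_hat)):
        raise ValueError("y_hat must be finite")
    if params.form == "power":
        if np.any(y_hat <= 0):
            raise ValueError("power-form residual SD requires y_hat > 0")
        sd = params.phi1 * y_hat**params.phi2
    else:
        sd = params.phi1 * params.phi2 ** ((y_hat - params.phi3) ** 2)
    return _check_finite(sd)
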