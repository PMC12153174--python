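"""Implied stem taper, merchantable-height solve, and ratio windows.

Multiplying the whole-stem outside-bark volume model by the cumulative
volume-ratio curve gives stem volume from groundline to height ``h``;
differentiating in ``h`` and dividing by the cross-section constant
0.000078540 (m^3 of a 1 m log per cm^2 of squared diameter) yields an
implied taper function for squared outside-bark diameter::

    d^2(h) = a*D**b*H**c / 0.000078540 / H
             * alpha*beta*(1-h/H)**(alpha-1) * (1-(1-h/H)**alpha)**(beta-1)

Merchantable height is the uppermost stem height at which the taper curve
crosses the merchantable top diameter (default 10.16 cm outside bark); the
merchantable window is the volume-ratio difference between that height and
stump height (default 0.30 m). Trees below the merchantability dbh threshold
(default 12.7 cm) are excluded upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .models import PowerLawParams, RatioParams, predict_ratio

__all__ = [
    "TAPER_CONSTANT",
    "MerchSpec",
    "TaperInputs",
    "NotMerchantableError",
    "taper_d_squared",
    "solve_merch_height",
    "solve_merch_height_batch",
    "merch_ratio_window",
]

#: cm^2 -> m^3/m conversion for squared diameters (pi/4 * 1e-4, field constant).
TAPER_CONSTANT = 0.000078540

#: Relative tip guard: the taper is evaluated on [0, H*(1 - TIP_GUARD)] to
#: avoid the (1-h/H)**(alpha-1) singularity exactly at the tip.
TIP_GUARD = 1e-9


class NotMerchantableError(ValueError):
    """The taper never reaches the merchantable top diameter above stump height."""


@dataclass(frozen=True)
class MerchSpec:
    """Merchantability limits: stump height (m), top diameter outside bark (cm),
    and the minimum dbh (cm) for a tree to enter the merchantable domain."""

    stump_height: float = 0.30
    top_dob: float = 10.16
    min_dbh: float = 12.7

    def __post_init__(self) -> None:
        if not self.stump_height > 0:
            raise ValueError("stump_height must be > 0")
        if not self.top_dob > 0:
            raise ValueError("top_dob must be > 0")
        if self.min_dbh < 0:
            raise ValueError("min_dbh must be >= 0")


@dataclass(frozen=True)
class TaperInputs:
    """Whole-stem outside-bark volume coefficients, outside-bark ratio
    coefficients, and the subject tree's size."""

    vol_params: PowerLawParams
    ratio_params: RatioParams
    dbh: float
    height: float

    def __post_init__(self) -> None:
        if not (self.dbh > 0 and self.height > 0):
            raise ValueError("dbh and height must be strictly positive")


def _d_squared_core(a, b, c, alpha, beta, dbh, height, h):
    """Vectorised taper kernel; no domain checks (callers guard)."""
    rel = 1.0 - h / height
    total_vol = a * dbh**b * height**c
    shape = alpha * beta * rel ** (alpha - 1.0) * (1.0 - rel**alpha) ** (beta - 1.0)
    return total_vol / TAPER_CONSTANT / height * shape


def taper_d_squared(ti: TaperInputs, h):
    """Squared outside-bark stem diameter (cm^2) at height ``h`` (m).

    Valid for ``0 <= h < H``. Depending on the ratio shape the expression is
    singular at the endpoints (``h=0`` for ``beta < 1``; the tip for
    ``alpha < 1``), which is why callers evaluate strictly inside the stem.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h >= ti.height):
        raise ValueError("taper height must satisfy 0 <= h < H")
    p, r = ti.vol_params, ti.ratio_params
    return _d_squared_core(p.a, p.b, p.c, r.alpha, r.beta, ti.dbh, ti.height, h)


def solve_merch_height(ti: TaperInputs, spec: MerchSpec, n_scan: int = 512) -> float:
    """Uppermost stem height at which taper diameter equals ``spec.top_dob``.

    A coarse scan over ``n_scan`` points on (stump_height, H*(1-eps)) locates
    the highest sign change of ``d(h) - top_dob``; Brent's method then
    polishes the root. The uppermost crossing is taken because butt swell can
    produce extra crossings low on the stem for some ratio shapes, and the
    merchantable top is by definition the upper one.

    Raises :class:`NotMerchantableError` when the taper stays below the top
    diameter over the whole span (caller excludes the tree).
    """
    hi = ti.height * (1.0 - TIP_GUARD)
    if spec.stump_height >= hi:
        raise NotMerchantableError("stump height at or above tree tip")
    grid = np.linspace(spec.stump_height, hi, n_scan)
    f = np.sqrt(np.maximum(taper_d_squared(ti, grid), 0.0)) - spec.top_dob
    signs = np.sign(f)
    change = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
    exact = np.nonzero(f == 0.0)[0]
    if change.size == 0:
        if exact.size:
            return float(grid[exact[-1]])
        raise NotMerchantableError(
            "taper never crosses the merchantable top diameter above stump height"
        )
    i = change[-1]
    if exact.size and grid[exact[-1]] > grid[i + 1]:
        return float(grid[exact[-1]])

    def fun(h: float) -> float:
        return float(np.sqrt(taper_d_squared(ti, h)) - spec.top_dob)

    return float(brentq(fun, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-15, maxiter=200))


def solve_merch_height_batch(
    vol_theta,
    ratio_theta,
    dbh,
    height,
    spec: MerchSpec,
    n_scan: int = 256,
    n_bisect: int = 60,
):
    """Vectorised merchantable-height solve for many trees at once.

    Same contract as :func:`solve_merch_height` (uppermost crossing), with a
    shared relative scan grid and bisection refinement. Returns
    ``(h_top, merchantable)`` arrays; non-merchantable trees get ``h_top``
    NaN and ``merchantable`` False instead of raising, so the Monte Carlo
    engine can mark them absent and continue.
    """
    a, b, c = (float(v) for v in np.asarray(vol_theta, dtype=float))
    alpha, beta = (float(v) for v in np.asarray(ratio_theta, dtype=float))
    dbh = np.atleast_1d(np.asarray(dbh, dtype=float))
    height = np.atleast_1d(np.asarray(height, dtype=float))
    hi = height * (1.0 - TIP_GUARD)
    lo = np.full_like(height, spec.stump_height)
    t = np.linspace(0.0, 1.0, n_scan)[:, None]
    grid = lo + t * (hi - lo)  # (n_scan, n_trees)
    f = (
        np.sqrt(
            np.maximum(_d_squared_core(a, b, c, alpha, beta, dbh, height, grid), 0.0)
        )
        - spec.top_dob
    )
    sign_change = np.sign(f[:-1]) * np.sign(f[1:]) < 0
    has_root = sign_change.any(axis=0)
    # uppermost sign change: last True row per column
    idx = (n_scan - 2) - np.argmax(sign_change[::-1], axis=0)
    rows = np.arange(dbh.size)
    lo_h = np.where(has_root, grid[idx, rows], np.nan)
    hi_h = np.where(has_root, grid[np.minimum(idx + 1, n_scan - 1), rows], np.nan)
    f_lo = np.where(has_root, f[idx, rows], 0.0)
    for _ in range(n_bisect):
        mid = 0.5 * (lo_h + hi_h)
        with np.errstate(invalid="ignore"):
            f_mid = (
                np.sqrt(
                    np.maximum(
                        _d_squared_core(a, b, c, alpha, beta, dbh, height, mid), 0.0
                    )
                )
                - spec.top_dob
            )
            take_lo = np.sign(f_mid) == np.sign(f_lo)
        lo_h = np.where(take_lo, mid, lo_h)
        f_lo = np.where(take_lo, f_mid, f_lo)
        hi_h = np.where(take_lo, hi_h, mid)
    h_top = 0.5 * (lo_h + hi_h)
    return h_top, has_root


def merch_ratio_window(params: RatioParams, spec: MerchSpec, h_top, height):
    """Volume-ratio share of the merchantable window, ``R(h_top) - R(stump)``.

    Requires ``stump_height < h_top <= H``; result lies in (0, 1].
    """
    h_top = np.asarray(h_top, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(h_top <= spec.stump_height):
        raise ValueError("merchantable height must exceed stump height")
    if np.any(h_top > height):
        raise ValueError("merchantable height cannot exceed total height")
    return predict_ratio(params, h_top, height) - predict_ratio(
        params, spec.stump_height, height
    )
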