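"""Synthetic model-fitting data and inventory with the assumed structure.

The generator emulates the statistical shape of a white-pine destructive
sample and an FIA-style inventory so the whole pipeline runs self-contained:

* tree sizes from a truncated lognormal dbh distribution (2.54-111.76 cm,
  mean near 31.8 cm) with height following a noisy allometric mean curve
  truncated to 2.68-48.16 m;
* component observations equal to a known "true" model prediction plus
  heteroscedastic noise drawn from the fitted residual-SD functions (power
  form for volumes/biomass, bell form for ratio profiles);
* component datasets drawn as overlapping-but-unequal subsets of one master
  tree pool, mirroring data pooled from partially disjoint source studies;
* an inventory of post-stratified plots with overdispersed tree counts
  (many empty plots), two-size-class expansion factors, and known stratum
  weights.

The default configuration reproduces the study conditions: per-component
sample sizes 2783 (TSV_IB), 2597 (TSV_BK), 3409 (TSV_OB), 392 (B_BK),
338 (B_BR), 239 (B_AG); 39509 / 54757 stem-profile observations for the
inside-/outside-bark ratio curves; WDSG mean 0.338 with SE 0.004 from
n = 96; CF mean 0.507 with SE 0.003 from n = 6; 1124 plots and an expected
864 trees with domain threshold 2.5 cm and merchantability threshold
12.7 cm. True allometric coefficients are frozen constants chosen to land
near the observed component means at the mean tree; residual-SD parameters
default to the fitted white-pine values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .estimate import Inventory
from .models import (
    COMPONENT_FORMS,
    COMPONENT_VARIANCE_FORMS,
    VarianceFnParams,
    predict_component,
    residual_sd,
)

__all__ = [
    "TRUE_PARAMS",
    "TABLE3_VARIANCE_PARAMS",
    "GeneratorConfig",
    "FittingData",
    "generate_fitting_data",
    "generate_inventory",
]

#: Frozen "true" coefficients of the generating system (order matches
#: models.PARAM_NAMES for each form).
TRUE_PARAMS: dict[str, tuple[float, ...]] = {
    "TSV_IB": (6.0e-5, 2.00, 0.95, 0.002),
    "TSV_BK": (1.0e-5, 2.00, 0.85, 1.80),
    "TSV_OB": (8.0e-5, 1.95, 0.93),
    "B_BK": (8.0e-3, 2.00, 0.60, 1.70),
    "B_BR": (1.8e-2, 2.20, 0.30),
    "B_AG": (6.0e-2, 2.10, 0.55),
    "R_IB": (2.80, 0.95),
    "R_OB": (2.90, 0.93),
}

#: Fitted residual-SD coefficients used as the generating noise structure.
TABLE3_VARIANCE_PARAMS: dict[str, tuple[float, ...]] = {
    "TSV_IB": (0.1075, 0.9667),
    "TSV_BK": (0.2898, 1.0904),
    "TSV_OB": (0.1127, 0.7578),
    "R_IB": (0.0470, 0.0012, 0.5603),
    "R_OB": (0.0434, 0.0018, 0.5508),
    "B_BK": (0.4017, 0.8195),
    "B_BR": (1.8372, 0.6593),
    "B_AG": (0.1189, 0.9827),
}

_DEFAULT_SIZES = {
    "TSV_IB": 2783, "TSV_BK": 2597, "TSV_OB": 3409,
    "B_BK": 392, "B_BR": 338, "B_AG": 239,
}
_DEFAULT_PROFILE_OBS = {"R_IB": 39509, "R_OB": 54757}


def _variance_fn(component: str, phis: tuple[float, ...]) -> VarianceFnParams:
    form = COMPONENT_VARIANCE_FORMS[component]
    if form == "bell":
        return VarianceFnParams("bell", phis[0], phis[1], phis[2])
    return VarianceFnParams("power", phis[0], phis[1])


@dataclass
class GeneratorConfig:
    """Everything that defines the synthetic study conditions."""

    true_params: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(TRUE_PARAMS)
    )
    variance_params: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(TABLE3_VARIANCE_PARAMS)
    )
    sample_sizes: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_SIZES))
    profile_obs: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_PROFILE_OBS))
    profile_obs_per_tree: int = 14
    pool_size: int = 3639
    noise_scale: float = 1.0
    #: residual z-deviates truncated at |z| <= 3 (matches the propagation
    #: convention); disable for pure Gaussian noise in calibration studies
    truncate_noise: bool = True
    #: redraw negative volume/biomass observations and clip ratio
    #: observations into (0, 1]; disable to leave the raw noise untouched
    clip_observations: bool = True
    # dbh distribution: lognormal, truncated
    dbh_log_mean: float = 3.33
    dbh_log_sd: float = 0.48
    dbh_min: float = 2.54
    dbh_max: float = 111.76
    # height given dbh: H = h_scale * D**h_exp * exp(eps), truncated
    h_scale: float = 3.0
    h_exp: float = 0.55
    h_log_sd: float = 0.23
    height_min: float = 2.68
    height_max: float = 48.16
    # scalar conversion-factor samples
    wdsg_mean: float = 0.338
    wdsg_sd: float = 0.0392  # gives SE 0.004 at n = 96
    wdsg_n: int = 96
    cf_mean: float = 0.507
    cf_sd: float = 0.00735  # gives SE 0.003 at n = 6
    cf_n: int = 6
    # inventory shape
    n_plots: int = 1124
    target_trees: int = 864
    stratum_weights: tuple[float, ...] = (0.45, 0.35, 0.20)
    stratum_density_shape: tuple[float, ...] = (1.5, 0.8, 0.2)
    nb_dispersion: float = 0.13
    inventory_dbh_min: float = 2.5
    merch_dbh: float = 12.7
    tpha_small: float = 74.97
    tpha_large: float = 14.87
    area_ha: float = 1.8e6
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if abs(sum(self.stratum_weights) - 1.0) > 1e-9:
            raise ValueError("stratum weights must sum to 1")
        if not (self.dbh_min < self.dbh_max and self.height_min < self.height_max):
            raise ValueError("infeasible truncation bounds")

    def variance_fn(self, component: str) -> VarianceFnParams:
        return _variance_fn(component, self.variance_params[component])


@dataclass
class FittingData:
    """Bundle of synthetic fitting datasets for the eight component models
    plus the WDSG and CF scalar samples."""

    frames: dict[str, pd.DataFrame]
    wdsg_sample: np.ndarray
    cf_sample: np.ndarray

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, df in self.frames.items():
            df.to_csv(path / f"{name}.csv", index=False)
        pd.DataFrame({"wdsg": self.wdsg_sample}).to_csv(path / "WDSG.csv", index=False)
        pd.DataFrame({"cf": self.cf_sample}).to_csv(path / "CF.csv", index=False)

    @classmethod
    def from_dir(cls, path) -> "FittingData":
        path = Path(path)
        frames = {}
        for name in COMPONENT_FORMS:
            f = path / f"{name}.csv"
            if not f.exists():
                raise FileNotFoundError(f"missing component dataset {f}")
            frames[name] = pd.read_csv(f)
        return cls(
            frames=frames,
            wdsg_sample=pd.read_csv(path / "WDSG.csv")["wdsg"].to_numpy(),
            cf_sample=pd.read_csv(path / "CF.csv")["cf"].to_numpy(),
        )


def _draw_sizes(
    rng: np.random.Generator, n: int, cfg: GeneratorConfig, dbh_min: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Truncated-lognormal dbh with conditional height (redraw until in range)."""
    lo = cfg.dbh_min if dbh_min is None else dbh_min
    dbh = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        cand = rng.lognormal(cfg.dbh_log_mean, cfg.dbh_log_sd, todo.size)
        ok = (cand >= lo) & (cand <= cfg.dbh_max)
        dbh[todo[ok]] = cand[ok]
        todo = todo[~ok]
    height = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        eps = rng.normal(0.0, cfg.h_log_sd, todo.size)
        cand = cfg.h_scale * dbh[todo] ** cfg.h_exp * np.exp(eps)
        ok = (cand >= cfg.height_min) & (cand <= cfg.height_max)
        height[todo[ok]] = cand[ok]
        todo = todo[~ok]
    return dbh, height


def _truncated_normal(rng: np.random.Generator, size: int, cap: float = 3.0) -> np.ndarray:
    z = rng.standard_normal(size)
    bad = np.abs(z) > cap
    while bad.any():
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(z) > cap
    return z


def _noise(rng: np.random.Generator, size: int, cfg: "GeneratorConfig") -> np.ndarray:
    if cfg.truncate_noise:
        return _truncated_normal(rng, size)
    return rng.standard_normal(size)


def generate_fitting_data(cfg: GeneratorConfig, seed: Optional[int] = None) -> FittingData:
    """Generate the per-component fitting datasets and scalar samples.

    Randomness descends from one seed through named substreams (one per
    dataset), so regenerating with the same seed is byte-identical and
    adding a dataset does not disturb the others. Observations are the true
    model mean plus ``z * sigma(yhat)`` with ``|z| <= 3`` (redrawn while the
    observation would be non-positive), scaled by ``cfg.noise_scale``.
    """
    seed = cfg.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    streams = root.spawn(12)
    pool_rng = np.random.Generator(np.random.PCG64(streams[0]))
    pool_dbh, pool_height = _draw_sizes(pool_rng, cfg.pool_size, cfg)

    frames: dict[str, pd.DataFrame] = {}
    for i, name in enumerate(("TSV_IB", "TSV_BK", "TSV_OB", "B_BK", "B_BR", "B_AG")):
        rng = np.random.Generator(np.random.PCG64(streams[1 + i]))
        n = cfg.sample_sizes[name]
        pick = rng.choice(cfg.pool_size, size=n, replace=False)
        dbh, height = pool_dbh[pick], pool_height[pick]
        yhat = predict_component(
            COMPONENT_FORMS[name], cfg.true_params[name], dbh=dbh, height=height
        )
        sd = residual_sd(cfg.variance_fn(name), yhat) * cfg.noise_scale
        y = yhat + _noise(rng, n, cfg) * sd
        if cfg.clip_observations:
            neg = y <= 0
            while neg.any():
                y[neg] = yhat[neg] + _noise(rng, int(neg.sum()), cfg) * sd[neg]
                neg = y <= 0
        frames[name] = pd.DataFrame(
            {"tree_id": pick, "D_cm": dbh, "H_m": height, "y": y}
        )

    for i, name in enumerate(("R_IB", "R_OB")):
        rng = np.random.Generator(np.random.PCG64(streams[7 + i]))
        target = cfg.profile_obs[name]
        n_trees = max(2, min(cfg.pool_size, int(np.ceil(target / cfg.profile_obs_per_tree))))
        pick = rng.choice(cfg.pool_size, size=n_trees, replace=False)
        per_tree = np.full(n_trees, target // n_trees)
        per_tree[: target % n_trees] += 1  # hit the target count exactly
        n_obs = int(per_tree.sum())
        tree_id = np.repeat(pick, per_tree)
        height = np.repeat(pool_height[pick], per_tree)
        h = height * rng.uniform(0.02, 0.99, size=n_obs)
        rhat = predict_component(
            "ratio", cfg.true_params[name], h=h, height=height
        )
        sd = residual_sd(cfg.variance_fn(name), rhat) * cfg.noise_scale
        r = rhat + _noise(rng, n_obs, cfg) * sd
        if cfg.clip_observations:
            r = np.clip(r, 1e-4, 1.0)
        frames[name] = pd.DataFrame(
            {"tree_id": tree_id, "h_m": h, "H_m": height, "R": r}
        )

    wdsg_rng = np.random.Generator(np.random.PCG64(streams[9]))
    cf_rng = np.random.Generator(np.random.PCG64(streams[10]))
    wdsg = cfg.wdsg_mean + cfg.wdsg_sd * cfg.noise_scale * _truncated_normal(
        wdsg_rng, cfg.wdsg_n
    )
    cf = cfg.cf_mean + cfg.cf_sd * cfg.noise_scale * _truncated_normal(cf_rng, cfg.cf_n)
    return FittingData(frames=frames, wdsg_sample=wdsg, cf_sample=cf)


def generate_inventory(cfg: GeneratorConfig, seed: Optional[int] = None) -> Inventory:
    """Generate a post-stratified plot sample with overdispersed tree counts.

    Plots are assigned to strata in proportion to the stratum weights; the
    per-plot tree count is negative-binomial with stratum-specific means
    scaled so the expected total matches ``cfg.target_trees`` (empty plots
    are common, as in a real inventory). Expansion factors follow a
    two-size-class design: ``tpha_small`` below the merchantability
    threshold and ``tpha_large`` at or above it.
    """
    seed = cfg.seed if seed is None else seed
    root = np.random.SeedSequence(seed, spawn_key=(101,))
    rng = np.random.Generator(np.random.PCG64(root))
    weights = np.asarray(cfg.stratum_weights, dtype=float)
    n_strata = weights.size
    for _ in range(100):
        stratum_idx = rng.choice(n_strata, size=cfg.n_plots, p=weights)
        if np.all(np.bincount(stratum_idx, minlength=n_strata) >= 2):
            break
    else:
        raise RuntimeError("could not place at least 2 plots in every stratum")

    shape = np.asarray(cfg.stratum_density_shape, dtype=float)
    expected_per_plot = float(np.sum(weights * shape))
    lam = shape * (cfg.target_trees / (cfg.n_plots * expected_per_plot))
    k = cfg.nb_dispersion
    lam_plot = lam[stratum_idx]
    counts = rng.negative_binomial(k, k / (k + lam_plot))

    plot_ids = np.arange(cfg.n_plots)
    plots = pd.DataFrame({"plot_id": plot_ids, "stratum_id": stratum_idx})
    strata = pd.DataFrame({"stratum_id": np.arange(n_strata), "weight": weights})

    n_trees = int(counts.sum())
    tree_plot = np.repeat(plot_ids, counts)
    dbh, height = _draw_sizes(rng, n_trees, cfg, dbh_min=cfg.inventory_dbh_min)
    tpha = np.where(dbh < cfg.merch_dbh, cfg.tpha_small, cfg.tpha_large)
    trees = pd.DataFrame(
        {"plot_id": tree_plot, "dbh_cm": dbh, "height_m": height, "tpha": tpha}
    )
    return Inventory(plots=plots, trees=trees, strata=strata, area_ha=cfg.area_ha)
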