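"""Post-stratified population estimation and sampling/model variance split.

Plot observations are per-hectare component totals (tree value times its
expansion factor, summed over the plot's trees; plots with no qualifying
trees contribute an explicit zero). Simple-random-sample estimators are
applied within each post-stratum and combined with known stratum weights
``W_h`` and total area ``A_T``::

    ybar_h  = sum_j y_hj / n_h
    v(ybar_h) = sum_j (y_hj - ybar_h)^2 / (n_h (n_h - 1))
    y       = A_T * sum_h W_h ybar_h
    v(y)    = A_T^2/n * [ sum_h W_h n_h v(ybar_h)
                          + sum_h (1 - W_h) n_h/n v(ybar_h) ]

Under hybrid inference the plot observations are model predictions, so the
Monte Carlo replicates of ``y_(r)`` carry model uncertainty: the reported
estimate is the replicate mean, the sampling variance ``v_y`` the replicate
mean of ``v(y_(r))``, and the model variance ``v_m`` the variance among the
``y_(r)``. The reported effect sizes are the percent increase in standard
error, ``m% = 100 (se_t - se_y)/se_y``, and in sampling-error percent,
``s% = 100 (se_t - se_y)/y``, with ``se_t = sqrt(v_y + v_m)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Inventory",
    "VarianceDecomposition",
    "PostStratifiedDesign",
    "stratum_mean_and_var",
    "population_total",
    "population_variance",
    "expand_trees_to_plots",
    "decompose",
]


@dataclass(frozen=True)
class VarianceDecomposition:
    """Population estimate with its sampling/model variance split."""

    y: float
    v_y: float
    v_m: float

    @property
    def v_t(self) -> float:
        return self.v_y + self.v_m

    @property
    def se_y(self) -> float:
        return float(np.sqrt(self.v_y))

    @property
    def se_t(self) -> float:
        return float(np.sqrt(self.v_t))

    @property
    def m_pct(self) -> float:
        """Percent increase in standard error due to model uncertainty."""
        return 100.0 * (self.se_t - self.se_y) / self.se_y

    @property
    def s_pct(self) -> float:
        """Change in the sampling-error percentage due to model uncertainty."""
        return 100.0 * (self.se_t - self.se_y) / self.y


@dataclass
class Inventory:
    """Forest-inventory sample: plots with post-stratum assignments, trees
    with per-hectare expansion factors, the stratum weight table, and the
    total population area in hectares.

    Schemas: ``plots (plot_id, stratum_id)``; ``trees (plot_id, dbh_cm,
    height_m, tpha)``; ``strata (stratum_id, weight)``.
    """

    plots: pd.DataFrame
    trees: pd.DataFrame
    strata: pd.DataFrame
    area_ha: float

    def design(self) -> "PostStratifiedDesign":
        return PostStratifiedDesign(self.plots, self.strata, self.area_ha)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.plots.to_csv(path / "plots.csv", index=False)
        self.trees.to_csv(path / "trees.csv", index=False)
        self.strata.to_csv(path / "strata.csv", index=False)
        (path / "inventory_meta.json").write_text(
            json.dumps({"area_ha": self.area_ha}, indent=2)
        )

    @classmethod
    def from_dir(cls, path) -> "Inventory":
        path = Path(path)
        meta = json.loads((path / "inventory_meta.json").read_text())
        return cls(
            plots=pd.read_csv(path / "plots.csv"),
            trees=pd.read_csv(path / "trees.csv"),
            strata=pd.read_csv(path / "strata.csv"),
            area_ha=float(meta["area_ha"]),
        )


def stratum_mean_and_var(values) -> tuple[float, float]:
    """Within-stratum sample mean and variance of the mean.

    The variance of the mean uses the ``n_h (n_h - 1)`` divisor; at least
    two plots are required.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("stratum variance undefined for fewer than 2 plots")
    mean = float(x.mean())
    var = float(np.sum((x - mean) ** 2) / (n * (n - 1)))
    return mean, var


def population_total(area_ha: float, weights, stratum_means) -> float:
    """Population total ``A_T * sum_h W_h ybar_h``."""
    w = np.asarray(weights, dtype=float)
    m = np.asarray(stratum_means, dtype=float)
    if w.shape != m.shape:
        raise ValueError("weights and stratum means must align")
    return float(area_ha * np.sum(w * m))


def population_variance(area_ha: float, weights, n_h, stratum_vars, n: int) -> float:
    """Post-stratified variance of the population total."""
    w = np.asarray(weights, dtype=float)
    nh = np.asarray(n_h, dtype=float)
    v = np.asarray(stratum_vars, dtype=float)
    if not (w.shape == nh.shape == v.shape):
        raise ValueError("stratum arrays must align")
    if int(np.sum(nh)) != int(n):
        raise ValueError("stratum plot counts must sum to n")
    return float(
        area_ha**2 / n * (np.sum(w * nh * v) + np.sum((1.0 - w) * nh / n * v))
    )


class PostStratifiedDesign:
    """Plot-to-stratum assignment with known weights and total area.

    Parameters
    ----------
    plots : DataFrame with columns ``plot_id``, ``stratum_id``; one row per
        sample plot, every plot appearing exactly once.
    strata : DataFrame with columns ``stratum_id``, ``weight``; weights must
        sum to 1 and every stratum must contain at least 2 plots.
    area_ha : total population area ``A_T`` in hectares.
    """

    def __init__(self, plots: pd.DataFrame, strata: pd.DataFrame, area_ha: float):
        if plots["plot_id"].duplicated().any():
            raise ValueError("every plot must appear exactly once")
        strata = strata.reset_index(drop=True)
        if abs(float(strata["weight"].sum()) - 1.0) > 1e-9:
            raise ValueError("stratum weights must sum to 1")
        sid_to_idx = {s: i for i, s in enumerate(strata["stratum_id"])}
        try:
            stratum_idx = plots["stratum_id"].map(sid_to_idx).to_numpy()
        except KeyError as e:  # pragma: no cover - mapping returns NaN instead
            raise ValueError(f"plot references unknown stratum {e}")
        if pd.isna(stratum_idx).any():
            raise ValueError("plot references a stratum missing from the table")
        self.plot_ids = plots["plot_id"].to_numpy()
        self.stratum_idx = stratum_idx.astype(int)
        self.weights = strata["weight"].to_numpy(dtype=float)
        self.area_ha = float(area_ha)
        self.n_strata = self.weights.size
        self.n_h = np.bincount(self.stratum_idx, minlength=self.n_strata)
        if np.any(self.n_h < 2):
            raise ValueError("every stratum needs at least 2 plots")
        self.n = int(self.n_h.sum())

    def estimate(self, plot_values) -> tuple[float, float]:
        """Population total and its sampling variance from per-plot values
        aligned with the design's plot order."""
        x = np.asarray(plot_values, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"expected {self.n} plot values, got {x.shape}")
        sums = np.bincount(self.stratum_idx, weights=x, minlength=self.n_strata)
        means = sums / self.n_h
        dev2 = (x - means[self.stratum_idx]) ** 2
        ss = np.bincount(self.stratum_idx, weights=dev2, minlength=self.n_strata)
        variances = ss / (self.n_h * (self.n_h - 1))
        y = population_total(self.area_ha, self.weights, means)
        v = population_variance(self.area_ha, self.weights, self.n_h, variances, self.n)
        return y, v


def expand_trees_to_plots(
    tree_values, trees: pd.DataFrame, plot_ids
) -> np.ndarray:
    """Per-plot per-hectare totals: ``sum_tree value * expansion_factor``.

    ``trees`` needs columns ``plot_id`` and ``tpha`` (trees-per-hectare
    expansion factor). The result aligns with ``plot_ids``; plots with no
    qualifying trees get an explicit 0. A tree referencing an unknown plot
    raises.
    """
    values = np.asarray(tree_values, dtype=float)
    plot_ids = np.asarray(plot_ids)
    pos = {p: i for i, p in enumerate(plot_ids)}
    idx = trees["plot_id"].map(pos)
    if idx.isna().any():
        orphans = trees.loc[idx.isna(), "plot_id"].unique()
        raise ValueError(f"trees reference unknown plots: {orphans[:5]}")
    weighted = values * trees["tpha"].to_numpy(dtype=float)
    return np.bincount(idx.to_numpy(dtype=int), weights=weighted, minlength=plot_ids.size)


def decompose(y_r, v_y_r) -> VarianceDecomposition:
    """Split replicate series into sampling and model variance components.

    ``y = mean(y_r)``, ``v_y = mean(v_y_r)``, and the model variance is the
    variance among the replicate totals with the ``R - 1`` divisor.
    """
    y_r = np.asarray(y_r, dtype=float)
    v_y_r = np.asarray(v_y_r, dtype=float)
    if y_r.size < 2 or y_r.shape != v_y_r.shape:
        raise ValueError("need aligned replicate series of length >= 2")
    y = float(y_r.mean())
    v_y = float(v_y_r.mean())
    v_m = float(np.sum((y_r - y) ** 2) / (y_r.size - 1))
    return VarianceDecomposition(y=y, v_y=v_y, v_m=v_m)
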