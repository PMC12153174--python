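"""Monte Carlo propagation of model error through the prediction system.

Each replicate ``r`` draws, once for the whole population, one parameter
vector per component model (uniformly from its bootstrap ensemble) and one
perturbed wood-specific-gravity and carbon-fraction value
(``mean + z * se`` with a shared truncated-normal ``z``). Residual model
error enters per tree per model as ``yhat + z * sigma_res(yhat)`` with
independent truncated-normal deviates. The per-tree prediction chain is:

1. inside-bark stem volume (exp-decay model) with residual noise;
2. bark volume (segmented model) with residual noise; outside-bark volume
   is their sum;
3. stem-wood biomass = inside-bark volume x WDSG x 1000;
4. bark biomass (segmented model) and branch / aboveground biomass
   (power models), each with residual noise;
5. proportional harmonization of {stem wood, bark, branch} biomass to the
   directly predicted aboveground total; carbon = harmonized biomass x CF;
6. realized specific gravities (harmonized biomass over predicted volume)
   used to convert merchantable volumes to harmonized biomass;
7. for trees at or above the merchantable dbh threshold: merchantable
   height from the implied taper, volume-ratio windows (with bell-form
   residual noise at both bounds, clamped to [0, 1]), merchantable volumes,
   biomass and carbon.

Replicate totals are produced by the post-stratified estimators and the
spread among them is the model variance ``v_m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .estimate import (
    Inventory,
    PostStratifiedDesign,
    VarianceDecomposition,
    decompose,
    expand_trees_to_plots,
)
from .fitting import ParameterEnsemble, ScalarMeanEstimate
from .models import VarianceFnParams, predict_component, residual_sd
from .taper import MerchSpec, solve_merch_height_batch

__all__ = [
    "SimulationConfig",
    "FittedSystem",
    "ReplicateDraw",
    "SimulationResult",
    "REPORT_COMPONENTS",
    "draw_truncated_z",
    "perturbed_prediction",
    "harmonize",
    "draw_replicate",
    "predict_tree_replicate",
    "run_simulation",
]

#: Components of the final report, in the conventional presentation order
#: (merchantable stem, total stem, branches, aboveground).
REPORT_COMPONENTS = (
    "MSV_IB", "MSBH_IB", "MSCH_IB",
    "MSV_BK", "MSBH_BK", "MSCH_BK",
    "MSV_OB", "MSBH_OB", "MSCH_OB",
    "TSV_IB", "TSBH_IB", "TSCH_IB",
    "TSV_BK", "TSBH_BK", "TSCH_BK",
    "TSV_OB", "TSBH_OB", "TSCH_OB",
    "BH_BR", "CH_BR", "B_AG", "C_AG",
)

#: Component models drawing residual noise, in fixed draw order.
_NOISE_MODELS = ("TSV_IB", "TSV_BK", "B_BK", "B_BR", "B_AG")
_MODEL_ORDER = ("TSV_IB", "TSV_BK", "TSV_OB", "B_BK", "B_BR", "B_AG", "R_IB", "R_OB")

#: Minimum dbh (cm) for a tree to enter the prediction domain at all.
MIN_DOMAIN_DBH = 2.5


@dataclass(frozen=True)
class SimulationConfig:
    """Replicate count, truncation bound, seed, and uncertainty switches.

    The boolean switches disable individual uncertainty sources (all active
    by default); with everything off the simulation is deterministic and the
    model variance is exactly zero.
    """

    n_replicates: int = 1500
    z_cap: float = 3.0
    seed: Optional[int] = None
    clamp_negative: bool = True
    parameter_uncertainty: bool = True
    residual_uncertainty: bool = True
    wdsg_uncertainty: bool = True
    cf_uncertainty: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if not self.z_cap > 0:
            raise ValueError("z_cap must be > 0")


@dataclass
class FittedSystem:
    """Everything the Monte Carlo engine needs from the fitting stage."""

    ensembles: dict[str, ParameterEnsemble]
    variance_fns: dict[str, VarianceFnParams]
    wdsg: ScalarMeanEstimate
    cf: ScalarMeanEstimate
    merch_spec: MerchSpec = field(default_factory=MerchSpec)

    def __post_init__(self) -> None:
        missing = [m for m in _MODEL_ORDER if m not in self.ensembles]
        if missing:
            raise ValueError(f"missing component ensembles: {missing}")
        missing = [m for m in _MODEL_ORDER if m not in self.variance_fns]
        if missing:
            raise ValueError(f"missing variance functions: {missing}")

    def point_theta(self, component: str) -> np.ndarray:
        return self.ensembles[component].point


@dataclass(frozen=True)
class ReplicateDraw:
    """Population-level random inputs shared by all trees in one replicate."""

    index: int
    thetas: dict[str, np.ndarray]
    wdsg: float
    cf: float

    def __post_init__(self) -> None:
        if not (self.wdsg > 0 and self.cf > 0):
            raise ValueError("perturbed WDSG and CF must be positive")


def draw_truncated_z(rng: np.random.Generator, size=None, z_cap: float = 3.0):
    """Standard-normal deviates with rejection outside ``|z| <= z_cap``."""
    scalar = size is None
    n = 1 if scalar else int(np.prod(size))
    out = rng.standard_normal(n)
    bad = np.abs(out) > z_cap
    while bad.any():
        out[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(out) > z_cap
    if scalar:
        return float(out[0])
    return out.reshape(size)


def perturbed_prediction(y_hat, vfn: VarianceFnParams, z, clamp_negative: bool = True):
    """Model prediction with residual error, ``yhat + z * sigma_res(yhat)``.

    Negative outcomes are clamped to zero when ``clamp_negative`` (callers
    count them; with the fitted white-pine system and ``|z| <= 3`` none
    arise in practice).
    """
    y_hat = np.asarray(y_hat, dtype=float)
    out = y_hat + np.asarray(z, dtype=float) * residual_sd(vfn, y_hat)
    if clamp_negative:
        out = np.maximum(out, 0.0)
    return out


def harmonize(tsb_ib, tsb_bk, b_br, b_ag):
    """Proportionally scale the three biomass components to sum to ``b_ag``.

    Each component is multiplied by ``b_ag / (tsb_ib + tsb_bk + b_br)``, so
    the outputs sum to the aboveground total exactly while preserving the
    ratios among components.
    """
    tsb_ib = np.asarray(tsb_ib, dtype=float)
    tsb_bk = np.asarray(tsb_bk, dtype=float)
    b_br = np.asarray(b_br, dtype=float)
    b_ag = np.asarray(b_ag, dtype=float)
    total = tsb_ib + tsb_bk + b_br
    if np.any(total <= 0) or np.any(b_ag <= 0):
        raise ValueError("harmonization requires positive component sum and total")
    s = b_ag / total
    return tsb_ib * s, tsb_bk * s, b_br * s


def draw_replicate(
    fitted: FittedSystem, cfg: SimulationConfig, rng: np.random.Generator, index: int = 0
) -> ReplicateDraw:
    """Draw the population-level inputs for one replicate.

    Parameter vectors are drawn independently per model (the component
    models are fitted to different, partially overlapping datasets and their
    errors are treated as independent); WDSG and CF each get one truncated-z
    perturbation shared by every tree in the replicate.
    """
    thetas = {}
    for name in _MODEL_ORDER:
        ens = fitted.ensembles[name]
        thetas[name] = ens.draw(rng) if cfg.parameter_uncertainty else ens.point.copy()
    if cfg.wdsg_uncertainty:
        wdsg = fitted.wdsg.mean + draw_truncated_z(rng, z_cap=cfg.z_cap) * fitted.wdsg.se
    else:
        wdsg = fitted.wdsg.mean
    if cfg.cf_uncertainty:
        cf = fitted.cf.mean + draw_truncated_z(rng, z_cap=cfg.z_cap) * fitted.cf.se
    else:
        cf = fitted.cf.mean
    return ReplicateDraw(index=index, thetas=thetas, wdsg=wdsg, cf=cf)


def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    return np.where(den > 0, np.asarray(num, dtype=float) / np.where(den > 0, den, 1.0), 0.0)


def _predict_trees(
    dbh: np.ndarray,
    height: np.ndarray,
    draw: ReplicateDraw,
    fitted: FittedSystem,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], np.ndarray, dict[str, int]]:
    """Vectorised per-tree component chain for one replicate.

    Returns the component arrays (merchantable entries zero for trees that
    are below the threshold or non-merchantable), the merchantable mask, and
    clamp/exclusion counters.
    """
    n = dbh.size
    counters: dict[str, int] = {}
    forms = {name: fitted.ensembles[name].form for name in _MODEL_ORDER}

    def noisy(name: str, yhat: np.ndarray) -> np.ndarray:
        if not cfg.residual_uncertainty:
            return yhat
        z = draw_truncated_z(rng, size=yhat.shape, z_cap=cfg.z_cap)
        raw = yhat + z * residual_sd(fitted.variance_fns[name], yhat)
        n_neg = int(np.sum(raw < 0))
        if n_neg:
            counters[f"clamped_{name}"] = counters.get(f"clamped_{name}", 0) + n_neg
            if cfg.clamp_negative:
                raw = np.maximum(raw, 0.0)
        return raw

    out: dict[str, np.ndarray] = {}
    # Stem volumes
    tsv_ib = noisy("TSV_IB", predict_component(forms["TSV_IB"], draw.thetas["TSV_IB"], dbh=dbh, height=height))
    tsv_bk = noisy("TSV_BK", predict_component(forms["TSV_BK"], draw.thetas["TSV_BK"], dbh=dbh, height=height))
    tsv_ob = tsv_ib + tsv_bk
    # Biomass: stem wood from volume x WDSG; bark, branch, aboveground direct
    tsb_ib = tsv_ib * draw.wdsg * 1000.0
    tsb_bk = noisy("B_BK", predict_component(forms["B_BK"], draw.thetas["B_BK"], dbh=dbh, height=height))
    b_br = noisy("B_BR", predict_component(forms["B_BR"], draw.thetas["B_BR"], dbh=dbh, height=height))
    b_ag = noisy("B_AG", predict_component(forms["B_AG"], draw.thetas["B_AG"], dbh=dbh, height=height))
    # harmonization; a tree whose perturbed aboveground total was clamped to
    # zero is treated as zero biomass throughout (kept additive, counted)
    total = tsb_ib + tsb_bk + b_br
    degenerate = (b_ag <= 0) | (total <= 0)
    n_deg = int(degenerate.sum())
    if n_deg:
        counters["zero_aboveground"] = n_deg
    s = np.where(degenerate, 0.0, b_ag / np.where(total > 0, total, 1.0))
    b_ag = np.where(degenerate, 0.0, b_ag)
    tsbh_ib, tsbh_bk, bh_br = tsb_ib * s, tsb_bk * s, b_br * s
    tsbh_ob = tsbh_ib + tsbh_bk
    # Carbon via the shared carbon fraction
    out.update(
        TSV_IB=tsv_ib, TSV_BK=tsv_bk, TSV_OB=tsv_ob,
        TSB_IB=tsb_ib, TSB_BK=tsb_bk, B_BR=b_br, B_AG=b_ag,
        TSBH_IB=tsbh_ib, TSBH_BK=tsbh_bk, BH_BR=bh_br, TSBH_OB=tsbh_ob,
        TSCH_IB=tsbh_ib * draw.cf, TSCH_BK=tsbh_bk * draw.cf,
        TSCH_OB=tsbh_ob * draw.cf, CH_BR=bh_br * draw.cf, C_AG=b_ag * draw.cf,
    )
    # Realized specific gravities tie merchantable biomass to harmonized stem
    wdsgh = _safe_div(tsbh_ib, tsv_ib) / 1000.0
    bksgh = _safe_div(tsbh_bk, tsv_bk) / 1000.0
    out["WDSGH"] = wdsgh
    out["BKSGH"] = bksgh

    # Merchantable chain
    spec = fitted.merch_spec
    eligible = dbh >= spec.min_dbh
    msv_ib = np.zeros(n)
    msv_bk = np.zeros(n)
    msv_ob = np.zeros(n)
    merch = np.zeros(n, dtype=bool)
    if eligible.any():
        h_top, solvable = solve_merch_height_batch(
            draw.thetas["TSV_OB"], draw.thetas["R_OB"],
            dbh[eligible], height[eligible], spec,
        )
        # guard: crossing must sit above the stump for a usable window
        usable = solvable & (h_top > spec.stump_height)
        counters["non_merchantable"] = int(np.sum(eligible) - np.sum(usable))
        idx = np.flatnonzero(eligible)[usable]
        if idx.size:
            ht = h_top[usable]
            hgt = height[idx]

            def window(name: str) -> np.ndarray:
                theta = draw.thetas[name]
                r_top = predict_component("ratio", theta, h=ht, height=hgt)
                r_stump = predict_component(
                    "ratio", theta, h=np.full(idx.size, spec.stump_height), height=hgt
                )
                if cfg.residual_uncertainty:
                    vfn = fitted.variance_fns[name]
                    r_top = np.clip(
                        r_top + draw_truncated_z(rng, size=idx.size, z_cap=cfg.z_cap)
                        * residual_sd(vfn, r_top), 0.0, 1.0,
                    )
                    r_stump = np.clip(
                        r_stump + draw_truncated_z(rng, size=idx.size, z_cap=cfg.z_cap)
                        * residual_sd(vfn, r_stump), 0.0, 1.0,
                    )
                return np.clip(r_top - r_stump, 0.0, 1.0)

            dr_ib = window("R_IB")
            dr_ob = window("R_OB")
            mo = tsv_ob[idx] * dr_ob
            mi = tsv_ib[idx] * dr_ib
            n_over = int(np.sum(mi > mo))
            if n_over:
                counters["clamped_MSV_BK"] = n_over
                mi = np.minimum(mi, mo)
            msv_ib[idx] = mi
            msv_ob[idx] = mo
            msv_bk[idx] = mo - mi
            merch[idx] = True
    else:
        counters["non_merchantable"] = 0
    msbh_ib = msv_ib * wdsgh * 1000.0
    msbh_bk = msv_bk * bksgh * 1000.0
    msbh_ob = msbh_ib + msbh_bk
    out.update(
        MSV_IB=msv_ib, MSV_BK=msv_bk, MSV_OB=msv_ob,
        MSBH_IB=msbh_ib, MSBH_BK=msbh_bk, MSBH_OB=msbh_ob,
        MSCH_IB=msbh_ib * draw.cf, MSCH_BK=msbh_bk * draw.cf,
        MSCH_OB=msbh_ob * draw.cf,
    )
    return out, merch, counters


def predict_tree_replicate(
    dbh: float,
    height: float,
    draw: ReplicateDraw,
    fitted: FittedSystem,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, float], bool]:
    """Single-tree component set for one replicate draw.

    Returns the component dict and whether the tree was merchantable;
    merchantable entries are NaN when it was not. Requires ``dbh >= 2.5``.
    """
    if dbh < MIN_DOMAIN_DBH:
        raise ValueError(f"tree dbh {dbh} below the {MIN_DOMAIN_DBH} cm domain threshold")
    comp, merch, _ = _predict_trees(
        np.array([float(dbh)]), np.array([float(height)]), draw, fitted, cfg, rng
    )
    is_merch = bool(merch[0])
    result = {}
    for name, arr in comp.items():
        v = float(arr[0])
        if name.startswith("MS") and not is_merch:
            v = float("nan")
        result[name] = v
    return result, is_merch


@dataclass
class SimulationResult:
    """Replicate series of population totals and sampling variances."""

    y_r: dict[str, np.ndarray]
    v_y_r: dict[str, np.ndarray]
    counters: dict[str, int]
    config: SimulationConfig
    n_trees: int
    n_plots: int

    @property
    def n_replicates(self) -> int:
        return int(next(iter(self.y_r.values())).size)

    def to_frame(self) -> pd.DataFrame:
        """Long replicate table ``(replicate, component, y_r, v_y_r)``."""
        rows = []
        r = np.arange(self.n_replicates)
        for name in REPORT_COMPONENTS:
            rows.append(
                pd.DataFrame(
                    {"replicate": r, "component": name,
                     "y_r": self.y_r[name], "v_y_r": self.v_y_r[name]}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def decompose(self, component: str) -> VarianceDecomposition:
        return decompose(self.y_r[component], self.v_y_r[component])

    def decomposition_table(self) -> pd.DataFrame:
        """Final report: one row per component with the variance split."""
        recs = []
        for name in REPORT_COMPONENTS:
            d = self.decompose(name)
            recs.append(
                {"component": name, "y": d.y, "v_y": d.v_y, "v_m": d.v_m,
                 "v_t": d.v_t, "se_y": d.se_y, "se_t": d.se_t,
                 "m_pct": d.m_pct, "s_pct": d.s_pct}
            )
        return pd.DataFrame(recs)


def run_simulation(
    inventory: Inventory,
    fitted: FittedSystem,
    cfg: SimulationConfig,
) -> SimulationResult:
    """Run the full Monte Carlo over the inventory sample.

    Randomness flows from one seed through replicate-indexed substreams
    (``SeedSequence.spawn``), so results do not depend on evaluation order.
    A failed replicate aborts with its index rather than being skipped.
    """
    design = inventory.design()
    trees = inventory.trees
    dbh = trees["dbh_cm"].to_numpy(dtype=float)
    height = trees["height_m"].to_numpy(dtype=float)
    if np.any(dbh < MIN_DOMAIN_DBH):
        raise ValueError("inventory contains trees below the 2.5 cm domain threshold")
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_replicates)
    y_r = {name: np.empty(cfg.n_replicates) for name in REPORT_COMPONENTS}
    v_y_r = {name: np.empty(cfg.n_replicates) for name in REPORT_COMPONENTS}
    counters: dict[str, int] = {}
    for r in range(cfg.n_replicates):
        rng = np.random.Generator(np.random.PCG64(children[r]))
        try:
            rep = draw_replicate(fitted, cfg, rng, index=r)
            comp, _, ctr = _predict_trees(dbh, height, rep, fitted, cfg, rng)
            for k, v in ctr.items():
                counters[k] = counters.get(k, 0) + v
            for name in REPORT_COMPONENTS:
                plot_vals = expand_trees_to_plots(comp[name], trees, design.plot_ids)
                y, v = design.estimate(plot_vals)
                y_r[name][r] = y
                v_y_r[name][r] = v
        except Exception as exc:
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc
    return SimulationResult(
        y_r=y_r, v_y_r=v_y_r, counters=counters, config=cfg,
        n_trees=dbh.size, n_plots=design.n,
    )
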