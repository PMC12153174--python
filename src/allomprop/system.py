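"""Model/Results interface for the compatible prediction system.

:class:`AllometricSystem` is the model object: it holds the per-component
fitting datasets (and the WDSG/CF scalar samples) plus the merchantability
specification. ``fit()`` estimates all eight component models, builds their
bootstrap parameter ensembles, fits the residual-SD functions to grouped
residuals, and returns a :class:`SystemFit` results object. From a
:class:`SystemFit`, ``propagate(inventory, ...)`` runs the Monte Carlo
error-propagation over an inventory sample and returns
:class:`PropagationResults` carrying the per-component variance
decomposition (estimate, sampling variance, model variance, m%, s%).

Typical use::

    cfg = GeneratorConfig(seed=7)
    data = generate_fitting_data(cfg)
    inventory = generate_inventory(cfg)
    model = AllometricSystem(data)
    fit = model.fit(n_boot=400, seed=1)
    print(fit.summary())
    results = fit.propagate(inventory, n_replicates=300, seed=2)
    print(results.summary())
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .estimate import Inventory
from .fitting import (
    FitResult,
    ParameterEnsemble,
    ScalarMeanEstimate,
    bootstrap_ensemble,
    fit_model,
    fit_variance_fn,
    group_residuals,
)
from .models import COMPONENT_FORMS, COMPONENT_VARIANCE_FORMS, VarianceFnParams
from .propagate import (
    FittedSystem,
    SimulationConfig,
    SimulationResult,
    run_simulation,
)
from .synthdata import FittingData
from .taper import MerchSpec

__all__ = ["AllometricSystem", "SystemFit", "PropagationResults"]


class AllometricSystem:
    """Compatible volume-biomass-carbon model system for one species group.

    Parameters
    ----------
    data : FittingData
        Per-component fitting datasets (flat schemas ``tree_id, D_cm, H_m, y``
        and ``tree_id, h_m, H_m, R``) plus WDSG and CF scalar samples.
    merch_spec : MerchSpec
        Stump height, merchantable top diameter, and minimum merchantable dbh.
    """

    def __init__(self, data: FittingData, merch_spec: MerchSpec = MerchSpec()):
        missing = [c for c in COMPONENT_FORMS if c not in data.frames]
        if missing:
            raise ValueError(f"missing component datasets: {missing}")
        self.data = data
        self.merch_spec = merch_spec

    @classmethod
    def from_dir(cls, path, merch_spec: MerchSpec = MerchSpec()) -> "AllometricSystem":
        return cls(FittingData.from_dir(path), merch_spec)

    def fit(
        self,
        n_boot: int = 2500,
        seed: Optional[int] = None,
        min_group: int = 25,
    ) -> "SystemFit":
        """Fit all component models, ensembles, and variance functions."""
        root = np.random.SeedSequence(seed)
        streams = root.spawn(len(COMPONENT_FORMS))
        fits: dict[str, FitResult] = {}
        ensembles: dict[str, ParameterEnsemble] = {}
        variance_fns: dict[str, VarianceFnParams] = {}
        variance_stats: dict[str, dict] = {}
        for i, (name, form) in enumerate(COMPONENT_FORMS.items()):
            frame = self.data.frames[name]
            fits[name] = fit_model(form, frame)
            rng = np.random.Generator(np.random.PCG64(streams[i]))
            ensembles[name] = bootstrap_ensemble(
                form, frame, n_boot=n_boot, component=name, rng=rng
            )
            groups = group_residuals(frame, form, fits[name].theta, min_group=min_group)
            vfn, stats = fit_variance_fn(groups, COMPONENT_VARIANCE_FORMS[name])
            variance_fns[name] = vfn
            variance_stats[name] = stats
        return SystemFit(
            fits=fits,
            ensembles=ensembles,
            variance_fns=variance_fns,
            variance_stats=variance_stats,
            wdsg=ScalarMeanEstimate.from_sample(self.data.wdsg_sample),
            cf=ScalarMeanEstimate.from_sample(self.data.cf_sample),
            merch_spec=self.merch_spec,
            n_boot=n_boot,
            seed=seed,
        )


class SystemFit:
    """Fitted system: point estimates, bootstrap ensembles, residual-SD
    functions, and the WDSG/CF means with standard errors."""

    def __init__(
        self,
        fits: dict[str, FitResult],
        ensembles: dict[str, ParameterEnsemble],
        variance_fns: dict[str, VarianceFnParams],
        variance_stats: dict[str, dict],
        wdsg: ScalarMeanEstimate,
        cf: ScalarMeanEstimate,
        merch_spec: MerchSpec,
        n_boot: int,
        seed: Optional[int] = None,
    ):
        self.fits = fits
        self.ensembles = ensembles
        self.variance_fns = variance_fns
        self.variance_stats = variance_stats
        self.wdsg = wdsg
        self.cf = cf
        self.merch_spec = merch_spec
        self.n_boot = n_boot
        self.seed = seed

    # -- accessors -------------------------------------------------------
    @property
    def system(self) -> FittedSystem:
        """The propagation engine's view of this fit."""
        return FittedSystem(
            ensembles=self.ensembles,
            variance_fns=self.variance_fns,
            wdsg=self.wdsg,
            cf=self.cf,
            merch_spec=self.merch_spec,
        )

    def params(self, component: str):
        return self.fits[component].params

    # -- reporting -------------------------------------------------------
    def fit_table(self) -> pd.DataFrame:
        """Per-component fit diagnostics (pseudo-R^2 and residual summary)."""
        rows = []
        for name, fit in self.fits.items():
            s = fit.residual_summary()
            rows.append(
                {"component": name, "form": fit.form, "n": fit.n_obs,
                 "r_squared": fit.r_squared, "resid_min": s["min"],
                 "resid_mean": s["mean"], "resid_max": s["max"],
                 "resid_sd": s["sd"]}
            )
        return pd.DataFrame(rows)

    def variance_table(self) -> pd.DataFrame:
        """Fitted residual-SD functions with their group-level fit stats."""
        rows = []
        for name, vfn in self.variance_fns.items():
            st = self.variance_stats.get(name, {})
            rows.append(
                {"component": name, "form": vfn.form, "phi1": vfn.phi1,
                 "phi2": vfn.phi2, "phi3": vfn.phi3,
                 "r_squared": st.get("r_squared", np.nan),
                 "rmse": st.get("rmse", np.nan)}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Readable multi-table summary of the fitted system."""
        lines = ["Compatible volume-biomass-carbon system fit",
                 "=" * 60,
                 f"bootstrap draws per model: {self.n_boot}   seed: {self.seed}",
                 f"WDSG: {self.wdsg.mean:.3f} (se {self.wdsg.se:.4f}, n={self.wdsg.n})",
                 f"CF:   {self.cf.mean:.3f} (se {self.cf.se:.4f}, n={self.cf.n})",
                 "",
                 "Component model fits",
                 self.fit_table().to_string(index=False, float_format=lambda v: f"{v:.4g}"),
                 "",
                 "Residual-SD functions",
                 self.variance_table().to_string(index=False, float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)

    # -- propagation -----------------------------------------------------
    def propagate(
        self,
        inventory: Inventory,
        n_replicates: int = 1500,
        seed: Optional[int] = None,
        **config_kwargs,
    ) -> "PropagationResults":
        """Run the Monte Carlo error propagation over an inventory sample."""
        cfg = SimulationConfig(n_replicates=n_replicates, seed=seed, **config_kwargs)
        sim = run_simulation(inventory, self.system, cfg)
        return PropagationResults(sim)

    # -- plots -----------------------------------------------------------
    def plot_ensemble(self, component: str, px: str = "a", py: str = "b", ax=None):
        """Scatter of two bootstrap coefficients (joint parameter spread)."""
        import matplotlib.pyplot as plt

        ens = self.ensembles[component]
        names = list(self.fits[component].param_names)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(ens.draws[:, names.index(px)], ens.draws[:, names.index(py)],
                   s=4, alpha=0.4)
        ax.set_xlabel(px)
        ax.set_ylabel(py)
        ax.set_title(f"{component}: bootstrap parameter ensemble (B={ens.n_draws})")
        return ax

    # -- persistence -----------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "n_boot": self.n_boot,
            "seed": self.seed,
            "merch_spec": {
                "stump_height": self.merch_spec.stump_height,
                "top_dob": self.merch_spec.top_dob,
                "min_dbh": self.merch_spec.min_dbh,
            },
            "wdsg": {"mean": self.wdsg.mean, "se": self.wdsg.se, "n": self.wdsg.n},
            "cf": {"mean": self.cf.mean, "se": self.cf.se, "n": self.cf.n},
            "components": {},
        }
        for name, fit in self.fits.items():
            vfn = self.variance_fns[name]
            obj["components"][name] = {
                "form": fit.form,
                "param_names": list(fit.param_names),
                "theta": fit.theta.tolist(),
                "n_obs": fit.n_obs,
                "sse": fit.sse,
                "r_squared": fit.r_squared,
                "residuals": fit.residuals.tolist(),
                "ensemble": self.ensembles[name].draws.tolist(),
                "variance_fn": {
                    "form": vfn.form, "phi1": vfn.phi1, "phi2": vfn.phi2,
                    "phi3": vfn.phi3,
                },
                "variance_stats": self.variance_stats.get(name, {}),
            }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path) -> "SystemFit":
        obj = json.loads(Path(path).read_text())
        fits, ensembles, variance_fns, variance_stats = {}, {}, {}, {}
        for name, c in obj["components"].items():
            fits[name] = FitResult(
                form=c["form"],
                theta=np.asarray(c["theta"], float),
                param_names=tuple(c["param_names"]),
                n_obs=int(c["n_obs"]),
                sse=float(c["sse"]),
                r_squared=float(c["r_squared"]),
                residuals=np.asarray(c["residuals"], float),
            )
            ensembles[name] = ParameterEnsemble(
                component=name,
                form=c["form"],
                point=np.asarray(c["theta"], float),
                draws=np.asarray(c["ensemble"], float),
            )
            v = c["variance_fn"]
            variance_fns[name] = VarianceFnParams(v["form"], v["phi1"], v["phi2"], v["phi3"])
            variance_stats[name] = c.get("variance_stats", {})
        ms = obj["merch_spec"]
        return cls(
            fits=fits,
            ensembles=ensembles,
            variance_fns=variance_fns,
            variance_stats=variance_stats,
            wdsg=ScalarMeanEstimate(**obj["wdsg"]),
            cf=ScalarMeanEstimate(**obj["cf"]),
            merch_spec=MerchSpec(ms["stump_height"], ms["top_dob"], ms["min_dbh"]),
            n_boot=int(obj["n_boot"]),
            seed=obj["seed"],
        )


class PropagationResults:
    """Monte Carlo propagation output with the variance decomposition."""

    def __init__(self, sim: SimulationResult):
        self.sim = sim
        self._table: Optional[pd.DataFrame] = None

    @property
    def table(self) -> pd.DataFrame:
        """Per-component decomposition: y, v_y, v_m, v_t, se_y, se_t, m%, s%."""
        if self._table is None:
            self._table = self.sim.decomposition_table()
        return self._table

    @property
    def counters(self) -> dict[str, int]:
        return self.sim.counters

    def replicates(self) -> pd.DataFrame:
        return self.sim.to_frame()

    def m_pct(self, component: str) -> float:
        return float(self.table.set_index("component").loc[component, "m_pct"])

    def s_pct(self, component: str) -> float:
        return float(self.table.set_index("component").loc[component, "s_pct"])

    def summary(self) -> str:
        t = self.table.copy()
        for col in ("y", "v_y", "v_m", "v_t", "se_y", "se_t"):
            t[col] = t[col].map(lambda v: f"{v:.3E}")
        for col in ("m_pct", "s_pct"):
            t[col] = t[col].map(lambda v: f"{v:.2f}%")
        lines = [
            "Model-error propagation over the inventory sample",
            "=" * 60,
            f"replicates: {self.sim.n_replicates}   trees: {self.sim.n_trees}   "
            f"plots: {self.sim.n_plots}",
            f"counters: {self.sim.counters}",
            "",
            t[["component", "y", "v_y", "v_m", "m_pct", "s_pct"]].to_string(index=False),
        ]
        return "\n".join(lines)

    def to_report_csv(self, path) -> None:
        """Write the decomposition table (3-significant-digit scientific
        notation for the level/variance columns, percents at 2 decimals)."""
        t = self.table.copy()
        for col in ("y", "v_y", "v_m", "v_t", "se_y", "se_t"):
            t[col] = t[col].map(lambda v: f"{v:.3E}")
        for col in ("m_pct", "s_pct"):
            t[col] = t[col].map(lambda v: f"{v:.2f}")
        t.to_csv(path, index=False)

    def to_replicates_csv(self, path) -> None:
        self.replicates().to_csv(path, index=False)

    def plot_running_mean(self, component: str, ax=None):
        """Replicate-count stability diagnostic: running mean of y_(r)."""
        import matplotlib.pyplot as plt

        y = self.sim.y_r[component]
        running = np.cumsum(y) / np.arange(1, y.size + 1)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, y.size + 1), running)
        ax.set_xlabel("replicate")
        ax.set_ylabel(f"running mean of {component} total")
        return ax
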