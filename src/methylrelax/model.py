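"""Model/Results objects wrapping the fitting machinery.

The surface follows the convention of statistical-modelling packages: a
model object is built from data plus fixed experimental conditions, its
``fit()`` returns a results object carrying estimates, uncertainties,
diagnostics and a ``summary()`` table, and simulation/plotting hang off
those objects.

Two models are provided:

* :class:`RecoveryModel` — one saturation-recovery curve (or a temperature
  series) fitted against the three-population relaxation model, by
  four-parameter grid search or by single-parameter tau_1 estimation;
* :class:`ArrheniusModel` — ln(tau_1) versus 1/T regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .arrhenius import ArrheniusParams
from .dataset import RecoveryDataset
from .exceptions import InvalidParameterError
from .fitting import (
    GridSearchResult,
    MultiExpFit,
    Tau1Estimate,
    arrhenius_regression,
    fit_multiexponential,
    fit_tau1_fixed_bath,
    fit_tau1_series,
    grid_search,
    predict_alpha_curve,
)
from .geometry import FieldConditions, MethylGeometry, MotionState
from .solomon import recovery_solution

__all__ = ["RecoveryModel", "RecoveryResults", "ArrheniusModel", "ArrheniusResults"]


def _format_summary(title: str, rows: list[tuple[str, str, str]]) -> str:
    width = max(len(r[0]) for r in rows) + 2
    lines = [title, "=" * 60]
    lines += [f"{name:<{width}}{value:>18}{stderr:>18}" for name, value, stderr in rows]
    lines.append("=" * 60)
    return "\n".join(lines)


class RecoveryModel:
    """Saturation-recovery data confronted with the relaxation forward model.

    Parameters
    ----------
    data : RecoveryDataset or sequence of RecoveryDataset
        One curve, or one per temperature for a joint series fit.
    geometry, field : MethylGeometry, FieldConditions
        Fixed experimental conditions of the forward model.

    Examples
    --------
    >>> geom = MethylGeometry(s2=0.93)
    >>> field = FieldConditions.from_proton_mhz(800.0, 19.2)
    >>> model = RecoveryModel(dataset, geom, field)
    >>> res = model.fit(method="tau1", n_b=1.6, sigma=0.9)
    >>> print(res.summary())
    """

    def __init__(self, data: RecoveryDataset | Sequence[RecoveryDataset],
                 geometry: MethylGeometry | None = None,
                 field: FieldConditions | None = None) -> None:
        self.datasets = [data] if isinstance(data, RecoveryDataset) else list(data)
        if not self.datasets:
            raise InvalidParameterError("no datasets supplied")
        self.geometry = geometry if geometry is not None else MethylGeometry()
        self.field = field if field is not None else FieldConditions.from_proton_mhz()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, geometry=None, field=None) -> "RecoveryModel":
        """Build from a long table with columns site, temperature_K, time_s,
        intensity (the same layout the io module reads and writes)."""
        from .io import datasets_from_frame
        return cls(datasets_from_frame(frame), geometry, field)

    def fit(self, method: str = "tau1", **kwargs) -> "RecoveryResults":
        """Fit the model.

        ``method`` is one of

        * ``"tau1"`` — tau_1 per dataset with the bath parameters fixed
          (kwargs: ``n_b``, ``sigma``, plus scan options); branch ambiguity
          is resolved jointly across a series;
        * ``"grid"`` — four-parameter (n_B, sigma, S^2, tau_1) grid search
          per dataset (kwargs: ``grids``, ``n_refine``, ``tolerances``);
        * ``"multiexp"`` — empirical multi-exponential fit per dataset
          (kwarg: ``n_components``).
        """
        if method == "tau1":
            ests = fit_tau1_series(self.datasets, self.geometry, self.field, **kwargs)
            return RecoveryResults(self, method, tau1_estimates=ests,
                                   fixed={"n_b": kwargs.get("n_b", 1.6),
                                          "sigma": kwargs.get("sigma", 0.9),
                                          "s2": self.geometry.s2})
        if method == "grid":
            res = [grid_search(ds, self.geometry, self.field, **kwargs)
                   for ds in self.datasets]
            return RecoveryResults(self, method, grid_results=res)
        if method == "multiexp":
            fits = [fit_multiexponential(ds, kwargs.get("n_components", 2))
                    for ds in self.datasets]
            return RecoveryResults(self, method, multiexp_fits=fits)
        raise InvalidParameterError(f"unknown method {method!r}")


@dataclass
class RecoveryResults:
    """Estimates, uncertainties and diagnostics from a RecoveryModel fit."""

    model: RecoveryModel
    method: str
    tau1_estimates: list[Tau1Estimate] | None = None
    grid_results: list[GridSearchResult] | None = None
    multiexp_fits: list[MultiExpFit] | None = None
    fixed: dict = dc_field(default_factory=dict)

    @property
    def params(self) -> pd.DataFrame:
        """One row of fitted parameters per dataset."""
        rows = []
        for ds, item in zip(self.model.datasets, self._items()):
            row = {"site": ds.site, "temperature_K": ds.temperature}
            if self.method == "tau1":
                row.update({"tau1_s": item.tau1, "side": item.side,
                            "rss": item.objective, **self.fixed})
            elif self.method == "grid":
                row.update({"n_b": item.n_b, "sigma": item.sigma, "s2": item.s2,
                            "tau1_s": item.tau1, "rss": item.objective,
                            "boundary": item.boundary})
            else:
                row.update({"m0": item.m0, "alpha": item.alpha,
                            "lambda_fast": float(item.rates[0]),
                            "lambda_slow": float(item.rates[-1]),
                            "rss": item.rss, "degenerate": item.degenerate})
            rows.append(row)
        return pd.DataFrame(rows)

    def _items(self):
        return self.tau1_estimates or self.grid_results or self.multiexp_fits

    def fittedvalues(self, index: int = 0) -> np.ndarray:
        """Model curve evaluated at the data delays of dataset ``index``."""
        ds = self.model.datasets[index]
        item = self._items()[index]
        if self.method == "multiexp":
            return item.curve(ds.times)
        if self.method == "tau1":
            tau1, n_b, sigma, s2 = item.tau1, self.fixed["n_b"], self.fixed["sigma"], self.fixed["s2"]
        else:
            tau1, n_b, sigma, s2 = item.tau1, item.n_b, item.sigma, item.s2
        sol = recovery_solution(self.model.geometry.with_s2(s2), self.model.field,
                                MotionState(tau1), n_b=n_b, sigma=sigma)
        f = sol.curve(ds.times)
        m0 = float(f @ ds.intensities) / float(f @ f)
        return m0 * f

    def resid(self, index: int = 0) -> np.ndarray:
        return self.model.datasets[index].intensities - self.fittedvalues(index)

    def arrhenius(self) -> "ArrheniusResults":
        """Arrhenius regression over the fitted tau_1(T) series."""
        p = self.params
        if "tau1_s" not in p:
            raise InvalidParameterError("no tau_1 estimates to regress")
        return ArrheniusModel(p["temperature_K"].to_numpy(), p["tau1_s"].to_numpy()).fit()

    def summary(self) -> str:
        p = self.params
        rows: list[tuple[str, str, str]] = [("parameter", "value", "")]
        for _, r in p.iterrows():
            label = f"{r['site']}@{r['temperature_K']:g}K"
            if self.method == "tau1":
                rows.append((f"tau1[{label}]", f"{r['tau1_s']:.4g} s", r["side"]))
            elif self.method == "grid":
                rows.append((f"(nB,sigma,S2,tau1)[{label}]",
                             f"({r['n_b']:.3g},{r['sigma']:.3g},{r['s2']:.3g},{r['tau1_s']:.3g})", ""))
            else:
                rows.append((f"(alpha,l1,l2)[{label}]",
                             f"({r['alpha']:.3g},{r['lambda_fast']:.3g},{r['lambda_slow']:.3g})", ""))
        title = f"RecoveryModel fit ({self.method}), {len(p)} dataset(s)"
        return _format_summary(title, rows)

    def plot(self, index: int = 0, ax=None):
        """Data and fitted curve for dataset ``index`` on a log time axis."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ds = self.model.datasets[index]
        ax.semilogx(ds.times, ds.intensities, "o", label="data")
        tt = np.geomspace(ds.times[ds.times > 0].min(), ds.times.max(), 200)
        item = self._items()[index]
        if self.method == "multiexp":
            ax.semilogx(tt, item.curve(tt), "-", label="fit")
        else:
            ax.semilogx(ds.times, self.fittedvalues(index), "-", label="fit")
        ax.set_xlabel("recovery delay (s)")
        ax.set_ylabel("intensity")
        ax.legend()
        return ax


class ArrheniusModel:
    """ln(tau_1) ~ 1/T ordinary least squares."""

    def __init__(self, temperatures: Sequence[float], tau1: Sequence[float]) -> None:
        self.temperatures = np.asarray(temperatures, dtype=float)
        self.tau1 = np.asarray(tau1, dtype=float)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       temperature_col: str = "temperature_K",
                       tau_col: str = "tau1_s") -> "ArrheniusModel":
        return cls(frame[temperature_col].to_numpy(), frame[tau_col].to_numpy())

    def fit(self) -> "ArrheniusResults":
        return ArrheniusResults(self, arrhenius_regression(self.temperatures, self.tau1))


@dataclass
class ArrheniusResults:
    """Activation energy and prefactor with OLS standard errors."""

    model: ArrheniusModel
    params: ArrheniusParams

    @property
    def ea(self) -> float:
        return self.params.ea

    @property
    def tau0(self) -> float:
        return self.params.tau0

    def fittedvalues(self) -> np.ndarray:
        return self.params.tau(self.model.temperatures)

    def resid(self) -> np.ndarray:
        """Residuals on the ln(tau) scale used by the regression."""
        return np.log(self.model.tau1) - np.log(self.fittedvalues())

    def predict_alpha(self, geometry: MethylGeometry | None = None,
                      field: FieldConditions | None = None,
                      n_b: float = 1.6, sigma: float = 0.9,
                      temperatures: Sequence[float] | None = None) -> pd.DataFrame:
        """Back-calculated (lambda_fast, lambda_slow, alpha) vs temperature."""
        geometry = geometry if geometry is not None else MethylGeometry(s2=0.93)
        field = field if field is not None else FieldConditions.from_proton_mhz()
        temps = temperatures if temperatures is not None else self.model.temperatures
        return predict_alpha_curve(geometry, field, self.params, n_b=n_b, sigma=sigma,
                                   temperatures=temps)

    def summary(self) -> str:
        p = self.params
        rows = [("parameter", "value", "stderr"),
                ("E_a (kcal/mol)", f"{p.ea:.4g}",
                 f"{p.ea_stderr:.2g}" if p.ea_stderr is not None else "-"),
                ("tau_0 (s)", f"{p.tau0:.4g}",
                 f"{p.tau0_stderr:.2g}" if p.tau0_stderr is not None else "-"),
                ("n points", str(len(self.model.temperatures)), "")]
        return _format_summary("Arrhenius regression of ln(tau1) on 1/T", rows)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        x = 1000.0 / self.model.temperatures
        ax.plot(x, np.log(self.model.tau1), "o", label="tau1 estimates")
        xx = np.linspace(x.min(), x.max(), 50)
        ax.plot(xx, np.log(self.params.tau(1000.0 / xx)), "-", label="Arrhenius fit")
        ax.set_xlabel("1000 / T (K$^{-1}$)")
        ax.set_ylabel(r"ln $\tau_1$")
        ax.legend()
        return ax
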