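"""Fitting machinery: multi-exponential recovery fits, the four-parameter
grid search, single-parameter tau_1 estimation, and Arrhenius regression.

The estimation strategy mirrors variable-temperature relaxation practice:

1. per-temperature grid search over (n_B, sigma, S^2, tau_1) against the
   full three-population recovery model, with iterative bisection
   refinement of the grid around the incumbent optimum;
2. with the bath parameters and order parameter frozen at representative
   values, a one-dimensional fit of tau_1 at each temperature;
3. ordinary least squares of ln(tau_1) on 1/T to extract the activation
   energy and Arrhenius prefactor of the methyl rotation.

All objectives are unweighted sums of squared intensity residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .arrhenius import ArrheniusParams
from .constants import R_GAS_KCAL
from .dataset import RecoveryDataset
from .exceptions import BracketError, FitFailureError, InvalidParameterError
from .geometry import FieldConditions, MethylGeometry, MotionState
from .solomon import recovery_solution
from . import rates as _rates

__all__ = [
    "MultiExpFit",
    "fit_multiexponential",
    "GridSearchResult",
    "grid_search",
    "Tau1Estimate",
    "fit_tau1_fixed_bath",
    "fit_tau1_series",
    "arrhenius_regression",
    "predict_alpha_curve",
]


# ---------------------------------------------------------------------------
# multi-exponential saturation-recovery fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiExpFit:
    """Result of a 1-, 2- or 3-component saturating-exponential fit.

    Amplitudes sum to 1 and rates are sorted descending, so for the
    two-component form the pair is (alpha, 1 - alpha) with alpha attached to
    the faster rate.  ``stderr`` maps parameter names to 1-sigma
    uncertainties from the fit covariance (None where unavailable).
    ``degenerate`` flags fits whose components are not separately
    identifiable (nearly equal rates or a vanishing amplitude).
    """

    m0: float
    amplitudes: np.ndarray
    rates: np.ndarray
    stderr: dict[str, float | None]
    rss: float
    n_points: int
    degenerate: bool = False

    @property
    def alpha(self) -> float:
        """Amplitude of the fastest component."""
        return float(self.amplitudes[0])

    def curve(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.m0 * (1.0 - np.exp(-np.outer(t, self.rates)) @ self.amplitudes)


def _recovery_model(n_components: int) -> lmfit.Model:
    if n_components == 1:
        def f(t, m0, lam1):
            return m0 * (1.0 - np.exp(-lam1 * t))
    elif n_components == 2:
        def f(t, m0, alpha, lam1, lam2):
            return m0 * (1.0 - alpha * np.exp(-lam1 * t) - (1.0 - alpha) * np.exp(-lam2 * t))
    else:
        def f(t, m0, a1, a2, lam1, lam2, lam3):
            a3 = 1.0 - a1 - a2
            return m0 * (1.0 - a1 * np.exp(-lam1 * t) - a2 * np.exp(-lam2 * t)
                         - a3 * np.exp(-lam3 * t))
    return lmfit.Model(f, independent_vars=["t"])


def _initial_rate_guess(ds: RecoveryDataset) -> float:
    """Crude single-rate guess: delay at which the curve reaches ~63% of max."""
    m0 = max(np.max(ds.intensities), 1e-30)
    above = np.nonzero(ds.intensities >= 0.63 * m0)[0]
    t63 = ds.times[above[0]] if len(above) else ds.times[-1]
    return 1.0 / max(t63, 1e-30)


def fit_multiexponential(ds: RecoveryDataset, n_components: int = 2) -> MultiExpFit:
    """Nonlinear least-squares fit of the saturating multi-exponential form.

    ``n_components`` selects M(t) = M0 (1 - sum_k alpha_k exp(-lambda_k t))
    with 1, 2 or 3 components constrained to sum_k alpha_k = 1.  Requires at
    least twice as many points as free parameters.  Raises
    :class:`FitFailureError` on non-convergence; near-degenerate two- or
    three-component solutions are returned with ``degenerate=True``.
    """
    if n_components not in (1, 2, 3):
        raise InvalidParameterError("n_components must be 1, 2 or 3")
    nfree = {1: 2, 2: 4, 3: 6}[n_components]
    if len(ds) < 2 * nfree:
        raise InvalidParameterError(
            f"need >= {2 * nfree} points for a {n_components}-component fit, got {len(ds)}")
    model = _recovery_model(n_components)
    m0_guess = max(np.max(ds.intensities), 1e-30)
    lam = _initial_rate_guess(ds)
    params = model.make_params()
    params["m0"].set(value=m0_guess, min=0.0)
    if n_components == 1:
        params["lam1"].set(value=lam, min=0.0)
    elif n_components == 2:
        params["alpha"].set(value=0.6, min=0.0, max=1.0)
        params["lam1"].set(value=4.0 * lam, min=0.0)
        params["lam2"].set(value=lam / 4.0, min=0.0)
    else:
        params["a1"].set(value=0.5, min=-0.5, max=1.5)
        params["a2"].set(value=0.4, min=-0.5, max=1.5)
        params["lam1"].set(value=8.0 * lam, min=0.0)
        params["lam2"].set(value=lam, min=0.0)
        params["lam3"].set(value=lam / 8.0, min=0.0)
    result = model.fit(ds.intensities, params, t=ds.times)
    if not result.success:
        raise FitFailureError(f"multi-exponential fit did not converge: {result.message}")
    p = result.params
    if n_components == 1:
        amps = np.array([1.0])
        lams = np.array([p["lam1"].value])
    elif n_components == 2:
        amps = np.array([p["alpha"].value, 1.0 - p["alpha"].value])
        lams = np.array([p["lam1"].value, p["lam2"].value])
    else:
        a1, a2 = p["a1"].value, p["a2"].value
        amps = np.array([a1, a2, 1.0 - a1 - a2])
        lams = np.array([p["lam1"].value, p["lam2"].value, p["lam3"].value])
    order = np.argsort(-lams)
    lams, amps = lams[order], amps[order]
    degenerate = False
    if n_components >= 2:
        lam_sep = np.min(np.abs(np.diff(lams))) / max(lams[0], 1e-30)
        if lam_sep < 0.05 or np.min(np.abs(amps)) < 0.01:
            degenerate = True
    stderr = {name: (p[name].stderr if p[name].stderr is not None else None)
              for name in p}
    return MultiExpFit(m0=p["m0"].value, amplitudes=amps, rates=lams, stderr=stderr,
                       rss=float(np.sum(result.residual**2)), n_points=len(ds),
                       degenerate=degenerate)


# ---------------------------------------------------------------------------
# forward-model objective
# ---------------------------------------------------------------------------

def _model_ssr(ds: RecoveryDataset, geom: MethylGeometry, field: FieldConditions,
               tau1: float, n_b: float, sigma: float, s2: float) -> float:
    """SSR between data and the forward recovery curve.

    The overall scale M0 is profiled out analytically (linear least squares
    given the curve shape), leaving the four physical parameters.
    """
    sol = recovery_solution(geom.with_s2(s2), field, MotionState(tau1),
                            n_b=n_b, sigma=sigma)
    f = sol.curve(ds.times)
    denom = float(f @ f)
    m0 = float(f @ ds.intensities) / denom if denom > 0 else 0.0
    r = ds.intensities - m0 * f
    return float(r @ r)


# ---------------------------------------------------------------------------
# four-parameter grid search with bisection refinement
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    """Best-fitting (n_B, sigma, S^2, tau_1) and the evaluation audit trail.

    ``ledger`` holds every evaluated grid point with its objective, one block
    per refinement iteration, so the bisection path can be audited.
    """

    n_b: float
    sigma: float
    s2: float
    tau1: float
    objective: float
    ledger: pd.DataFrame
    n_iterations: int
    boundary: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"n_b": self.n_b, "sigma": self.sigma, "s2": self.s2, "tau1": self.tau1}


def _default_grids() -> dict[str, np.ndarray]:
    return {
        "n_b": np.linspace(0.1, 10.0, 8),
        "sigma": np.linspace(0.0, 10.0, 8),
        "s2": np.linspace(0.7, 1.0, 4),
        "tau1": np.geomspace(1e-12, 1e-6, 13),
    }


def grid_search(ds: RecoveryDataset, geom: MethylGeometry, field: FieldConditions,
                grids: dict[str, np.ndarray] | None = None,
                n_refine: int = 20, n_starts: int = 3,
                tolerances: dict[str, float] | None = None,
                polish: bool = True, polish_maxfev: int = 20000) -> GridSearchResult:
    """Exhaustive grid search over (n_B, sigma, S^2, tau_1) with refinement.

    Every grid point is pushed through the full three-population forward
    model and scored by the unweighted SSR against ``ds``.  After the
    initial sweep the grid is iteratively re-centered on an incumbent with
    the spacing halved (binary refinement; tau_1 is refined in log space)
    until each spacing falls below its tolerance or ``n_refine`` iterations.
    Because the fast and slow branches of R1(tau_1) and the S^2/tau_1
    trade-off can alias on a coarse grid, refinement restarts from the
    ``n_starts`` best mutually-separated points of the initial sweep and the
    overall best refined optimum wins.  By default the incumbent is finally
    polished by a derivative-free simplex descent (``polish=True``), which
    follows the flat valley of the objective below grid resolution.

    A final optimum on the boundary of the *initial* grid triggers a
    ``UserWarning`` advising a wider grid, and is reported via ``boundary``.
    """
    grids = dict(_default_grids() if grids is None else grids)
    for key in ("n_b", "sigma", "s2", "tau1"):
        if key not in grids or len(np.atleast_1d(grids[key])) == 0:
            raise InvalidParameterError(f"grid for {key!r} is missing or empty")
        grids[key] = np.atleast_1d(np.asarray(grids[key], dtype=float))
    tol = {"n_b": 0.02, "sigma": 0.02, "s2": 0.005, "tau1_log10": 0.005}
    if tolerances:
        tol.update(tolerances)

    initial_bounds = {k: (v.min(), v.max()) for k, v in grids.items()}
    ledger_rows: list[dict] = []

    def sweep(g: dict[str, np.ndarray], iteration: int):
        evaluated = []
        for nb in g["n_b"]:
            for sg in g["sigma"]:
                for s2 in g["s2"]:
                    for t1 in g["tau1"]:
                        try:
                            ssr = _model_ssr(ds, geom, field, t1, nb, sg, s2)
                        except InvalidParameterError:
                            continue
                        ledger_rows.append({"iteration": iteration, "n_b": nb,
                                            "sigma": sg, "s2": s2, "tau1": t1,
                                            "objective": ssr})
                        evaluated.append((ssr, (nb, sg, s2, t1)))
        if not evaluated:
            raise FitFailureError("no valid grid point could be evaluated")
        evaluated.sort(key=lambda e: e[0])
        return evaluated

    initial_spacing = {
        "n_b": np.max(np.diff(grids["n_b"])) if len(grids["n_b"]) > 1 else 0.0,
        "sigma": np.max(np.diff(grids["sigma"])) if len(grids["sigma"]) > 1 else 0.0,
        "s2": np.max(np.diff(grids["s2"])) if len(grids["s2"]) > 1 else 0.0,
        "tau1_log10": (np.max(np.diff(np.log10(grids["tau1"])))
                       if len(grids["tau1"]) > 1 else 0.0),
    }

    evaluated = sweep(grids, 0)

    # pick up to n_starts seeds separated by >= 1.5 initial spacings in at
    # least one parameter, so distinct basins each get a refinement run
    def separated(p, q) -> bool:
        checks = []
        if initial_spacing["n_b"] > 0:
            checks.append(abs(p[0] - q[0]) >= 1.5 * initial_spacing["n_b"])
        if initial_spacing["sigma"] > 0:
            checks.append(abs(p[1] - q[1]) >= 1.5 * initial_spacing["sigma"])
        if initial_spacing["s2"] > 0:
            checks.append(abs(p[2] - q[2]) >= 1.5 * initial_spacing["s2"])
        if initial_spacing["tau1_log10"] > 0:
            checks.append(abs(math.log10(p[3]) - math.log10(q[3]))
                          >= 1.5 * initial_spacing["tau1_log10"])
        return any(checks)

    seeds: list[tuple[float, tuple]] = []
    for ssr, pt in evaluated:
        if all(separated(pt, s[1]) for s in seeds):
            seeds.append((ssr, pt))
        if len(seeds) >= max(1, n_starts):
            break

    def refine(seed_obj: float, seed_pt: tuple, start_iter: int):
        # pattern search: a 5-point local grid (+-2 spacings) per parameter;
        # the spacing is halved only when the incumbent stays at the center,
        # otherwise the grid re-centers at the same spacing so the search
        # can track diagonal valleys (e.g. the S^2/tau_1 trade-off)
        best_obj, best_pt = seed_obj, seed_pt
        spacing = {k: (v / 2.0 if v > 0 else 0.0) for k, v in initial_spacing.items()}
        it = start_iter
        for step in range(n_refine):
            if (spacing["n_b"] <= tol["n_b"] and spacing["sigma"] <= tol["sigma"]
                    and spacing["s2"] <= tol["s2"]
                    and spacing["tau1_log10"] <= tol["tau1_log10"]):
                break
            nb0, sg0, s20, t10 = best_pt
            local: dict[str, np.ndarray] = {}
            for key, center in (("n_b", nb0), ("sigma", sg0), ("s2", s20)):
                if spacing[key] > 0:
                    g = np.linspace(center - 2 * spacing[key],
                                    center + 2 * spacing[key], 5)
                    if key == "n_b":
                        g = g[g > 0]
                    elif key == "sigma":
                        # clamp to the sigma >= 0 boundary so it stays reachable
                        g = np.unique(np.clip(g, 0.0, None))
                    else:
                        g = np.unique(np.clip(g, None, 1.0))
                        g = g[g > 0]
                    local[key] = g if len(g) else np.array([center])
                else:
                    local[key] = np.array([center])
            if spacing["tau1_log10"] > 0:
                lt = math.log10(t10)
                local["tau1"] = 10.0 ** np.linspace(lt - 2 * spacing["tau1_log10"],
                                                    lt + 2 * spacing["tau1_log10"], 5)
            else:
                local["tau1"] = np.array([t10])
            it += 1
            obj, pt = sweep(local, it)[0]
            moved = obj < best_obj * (1.0 - 1e-12) and pt != best_pt
            if obj < best_obj:
                best_obj, best_pt = obj, pt
            if not moved:
                for key in spacing:
                    spacing[key] /= 2.0
        return best_obj, best_pt, it

    best_obj, best_pt = evaluated[0]
    it_total = 0
    for seed_obj, seed_pt in seeds:
        obj, pt, it_total = refine(seed_obj, seed_pt, it_total)
        if obj < best_obj:
            best_obj, best_pt = obj, pt

    if polish:
        # derivative-free simplex descent from the grid incumbent: the
        # objective has a very flat valley along the S^2/tau_1 trade-off
        # that grid bisection cannot traverse to the bottom
        def penalized(x):
            nb, sg, s2, lt = x
            if nb <= 0 or sg < 0 or not 0.0 < s2 <= 1.0:
                return np.inf
            try:
                return _model_ssr(ds, geom, field, 10.0 ** lt, nb, sg, s2)
            except InvalidParameterError:
                return np.inf

        x0 = [best_pt[0], best_pt[1], best_pt[2], math.log10(best_pt[3])]
        res = scipy.optimize.minimize(
            penalized, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 0.0,
                     "maxfev": polish_maxfev, "maxiter": polish_maxfev})
        if np.isfinite(res.fun) and res.fun <= best_obj:
            best_obj = float(res.fun)
            best_pt = (float(res.x[0]), float(res.x[1]), float(res.x[2]),
                       float(10.0 ** res.x[3]))

    boundary = any(
        math.isclose(best_pt[i], initial_bounds[k][0], rel_tol=1e-9, abs_tol=1e-15)
        or math.isclose(best_pt[i], initial_bounds[k][1], rel_tol=1e-9, abs_tol=1e-15)
        or best_pt[i] < initial_bounds[k][0] or best_pt[i] > initial_bounds[k][1]
        for i, k in enumerate(("n_b", "sigma", "s2", "tau1"))
        if len(np.atleast_1d(grids[k])) > 1 or initial_bounds[k][0] != initial_bounds[k][1]
    )
    if boundary:
        warnings.warn("grid-search optimum lies on (or beyond) the initial grid "
                      "boundary; widen the grid", UserWarning, stacklevel=2)

    return GridSearchResult(n_b=best_pt[0], sigma=best_pt[1], s2=best_pt[2],
                            tau1=best_pt[3], objective=best_obj,
                            ledger=pd.DataFrame(ledger_rows), n_iterations=it_total,
                            boundary=boundary)


# ---------------------------------------------------------------------------
# one-dimensional tau_1 estimation with fixed bath parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tau1Estimate:
    """A tau_1 estimate with its branch of the double-valued rate curve.

    ``side`` is ``"fast"`` when tau_1 lies below the correlation time of the
    R1 maximum (fast-motion branch) and ``"slow"`` above it.  ``candidates``
    lists every local optimum found as (tau1, side, objective).
    """

    tau1: float
    side: str
    objective: float
    temperature: float
    candidates: tuple[tuple[float, str, float], ...]


def _tau_at_rate_maximum(geom: MethylGeometry, field: FieldConditions) -> float:
    """Correlation time maximizing the powder-averaged single-pair R1."""
    res = scipy.optimize.minimize_scalar(
        lambda lt: -_rates.r1_single_ch(geom, field, MotionState(10.0 ** lt)),
        bounds=(-12.0, -6.0), method="bounded",
        options={"xatol": 1e-6})
    return 10.0 ** res.x


def fit_tau1_fixed_bath(ds: RecoveryDataset, geom: MethylGeometry, field: FieldConditions,
                        n_b: float = 1.6, sigma: float = 0.9,
                        side: str = "auto",
                        tau_bounds: tuple[float, float] = (1e-12, 1e-6),
                        n_scan: int = 121) -> Tau1Estimate:
    """Estimate tau_1 with all other model parameters frozen.

    The SSR objective is scanned on a log-spaced tau_1 bracket and each local
    minimum refined by bounded golden-section search.  Because R1(tau_1) is
    double-valued around the T1 minimum the objective generically has one
    minimum per branch; ``side`` selects ``"fast"``/``"slow"``, or ``"auto"``
    for the globally best.  Raises :class:`BracketError` when the optimum
    sits at the edge of the scanned range.
    """
    if side not in ("auto", "fast", "slow"):
        raise InvalidParameterError("side must be 'auto', 'fast' or 'slow'")
    lts = np.linspace(math.log10(tau_bounds[0]), math.log10(tau_bounds[1]), n_scan)

    def obj(lt: float) -> float:
        return _model_ssr(ds, geom, field, 10.0 ** lt, n_b, sigma, geom.s2)

    vals = np.array([obj(lt) for lt in lts])
    i_glob = int(np.argmin(vals))
    if i_glob in (0, n_scan - 1):
        raise BracketError("objective minimized at the edge of the tau_1 range; "
                           "widen tau_bounds")
    minima = [i for i in range(1, n_scan - 1)
              if vals[i] <= vals[i - 1] and vals[i] <= vals[i + 1]]
    tau_star = _tau_at_rate_maximum(geom, field)
    candidates = []
    for i in minima:
        res = scipy.optimize.minimize_scalar(obj, bounds=(lts[i - 1], lts[i + 1]),
                                             method="bounded", options={"xatol": 1e-7})
        t1 = 10.0 ** res.x
        candidates.append((t1, "fast" if t1 < tau_star else "slow", float(res.fun)))
    candidates.sort(key=lambda c: c[2])
    pool = candidates if side == "auto" else [c for c in candidates if c[1] == side]
    if not pool:
        raise BracketError(f"no local optimum found on the {side!r} branch")
    t1, br, val = pool[0]
    return Tau1Estimate(tau1=t1, side=br, objective=val, temperature=ds.temperature,
                        candidates=tuple(candidates))


def fit_tau1_series(datasets: Sequence[RecoveryDataset], geom: MethylGeometry,
                    field: FieldConditions, n_b: float = 1.6, sigma: float = 0.9,
                    arrhenius_consistency: bool = True,
                    **kwargs) -> list[Tau1Estimate]:
    """tau_1 at each temperature with branch ambiguity resolved jointly.

    A single recovery curve cannot always distinguish the fast- and
    slow-motion branches of R1(tau_1); across a temperature series the
    physical solution must have tau_1 monotonically increasing as the sample
    cools.  The per-dataset candidate optima are combined by dynamic
    programming to find the monotone assignment of lowest total SSR.

    With ``arrhenius_consistency`` (default) the assignment is then iterated
    to self-consistency against an Arrhenius regression of the series: each
    temperature's candidate is re-chosen as the one nearest the fitted line
    in ln(tau_1).  Near the T1 minimum the two branches fit a noisy curve
    almost equally well, and the thermal-activation constraint is what
    identifies the physical branch.
    """
    order = np.argsort([-ds.temperature for ds in datasets])
    fits = [fit_tau1_fixed_bath(datasets[i], geom, field, n_b=n_b, sigma=sigma,
                                side="auto", **kwargs) for i in order]
    # DP over candidates; state = candidate index at previous temperature
    paths: list[tuple[float, list[int]]] = [(c[2], [j]) for j, c in enumerate(fits[0].candidates)]
    for k in range(1, len(fits)):
        new_paths = []
        for j, c in enumerate(fits[k].candidates):
            best = None
            for cost, path in paths:
                prev = fits[k - 1].candidates[path[-1]]
                if c[0] >= prev[0]:  # tau must not decrease as T drops
                    if best is None or cost < best[0]:
                        best = (cost, path)
            if best is not None:
                new_paths.append((best[0] + c[2], best[1] + [j]))
        if not new_paths:  # no monotone assignment; fall back to global minima
            new_paths = [(cost + fits[k].candidates[0][2], path + [0])
                         for cost, path in paths]
        paths = new_paths
    _, best_path = min(paths, key=lambda p: p[0])

    if arrhenius_consistency and len(fits) >= 3:
        temps = np.array([datasets[i].temperature for i in order])
        path = list(best_path)
        for _ in range(5):
            taus = np.array([fits[k].candidates[j][0] for k, j in enumerate(path)])
            try:
                pred = arrhenius_regression(temps, taus).tau(temps)
            except InvalidParameterError:
                break
            new_path = [int(np.argmin([abs(math.log(c[0] / pred[k]))
                                       for c in f.candidates]))
                        for k, f in enumerate(fits)]
            if new_path == path:
                break
            path = new_path
        best_path = path

    resolved = []
    for f, j in zip(fits, best_path):
        t1, br, val = f.candidates[j]
        resolved.append(replace(f, tau1=t1, side=br, objective=val))
    # restore caller's dataset order
    out: list[Tau1Estimate] = [None] * len(datasets)  # type: ignore[list-item]
    for pos, est in zip(order, resolved):
        out[pos] = est
    return out


# ---------------------------------------------------------------------------
# Arrhenius regression
# ---------------------------------------------------------------------------

def arrhenius_regression(temperatures: Sequence[float],
                         tau1: Sequence[float]) -> ArrheniusParams:
    """OLS of ln(tau_1) on 1/T: slope = E_a/R, intercept = ln(tau_0).

    Standard errors of the regression coefficients propagate directly to
    E_a (linear) and tau_0 (delta method on the exponential).
    Requires at least three distinct temperatures.
    """
    t = np.asarray(temperatures, dtype=float)
    tau = np.asarray(tau1, dtype=float)
    if len(t) < 3:
        raise InvalidParameterError("Arrhenius regression needs >= 3 points")
    if len(np.unique(t)) != len(t):
        raise InvalidParameterError("temperatures must be distinct")
    if np.any(t <= 0) or np.any(tau <= 0):
        raise InvalidParameterError("temperatures and correlation times must be positive")
    fit = scipy.stats.linregress(1.0 / t, np.log(tau))
    ea = fit.slope * R_GAS_KCAL
    tau0 = math.exp(fit.intercept)
    return ArrheniusParams(ea=ea, tau0=tau0,
                           ea_stderr=fit.stderr * R_GAS_KCAL,
                           tau0_stderr=tau0 * fit.intercept_stderr)


# ---------------------------------------------------------------------------
# forward prediction of the temperature dependence
# ---------------------------------------------------------------------------

def predict_alpha_curve(geom: MethylGeometry, field: FieldConditions,
                        arrhenius: ArrheniusParams,
                        n_b: float = 1.6, sigma: float = 0.9,
                        temperatures: Sequence[float] = (268.0, 233.0, 198.0, 178.0, 149.0),
                        ) -> pd.DataFrame:
    """Back-calculated fast/slow rates and fast amplitude versus temperature.

    For each temperature: tau_1 from the Arrhenius law -> MAS-averaged
    transition rates -> Solomon matrix -> bath-augmented system -> recovery
    solution, summarized as the two-component (lambda_fast, lambda_slow,
    alpha) a bi-exponential fit would report.  With ``sigma == 0`` the
    isolated 2-spin model is used instead.
    """
    rows = []
    for temp in temperatures:
        motion = MotionState.from_temperature(arrhenius, temp)
        sol = recovery_solution(geom, field, motion, n_b=n_b, sigma=sigma)
        lam_fast, lam_slow, alpha = sol.two_component()
        rows.append({"temperature_K": temp, "tau1_s": motion.tau1,
                     "lambda_fast": lam_fast, "lambda_slow": lam_slow,
                     "alpha": alpha})
    return pd.DataFrame(rows)
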