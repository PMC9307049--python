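"""Bounded least-squares estimation of growth kinetics and hyphal P uptake.

Two inverse problems:

* `fit_growth` — estimate the tip kinetics (k, v, b[, d]) from hyphal
  length-density observations by minimising the sum of squared residuals
  between the closed-form model and the data, with box bounds and a
  seeded multi-start (log-uniform within bounds) local search.
* `fit_uptake` — estimate the hyphal uptake coefficient lambda_h from a
  far-field-normalised P depletion profile at the final observation time,
  holding D_eff fixed and driving the transport solver with a supplied
  length-density field.  Only the product r_m * lambda_h is identified,
  so results always disclose the r_m used.

Replicate handling follows the two natural modes: pool all replicates into
one fit, or fit each replicate and aggregate (`aggregate_replicates`,
mean +/- sample SD).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .growth import (
    GrowthParams,
    ObservationSet,
    evaluate_at,
    predict_rho,
)
from .uptake import UptakeParams, solve_uptake

__all__ = [
    "FitResult",
    "AggregateFit",
    "DEFAULT_GROWTH_BOUNDS",
    "fit_growth",
    "fit_uptake",
    "r_squared",
    "aggregate_replicates",
]

#: Default box bounds; brackets the magnitudes typical of split-compartment
#: colonisation assays by >= 10x.
DEFAULT_GROWTH_BOUNDS: dict[str, tuple[float, float]] = {
    "k": (1e-6, 1e-2),       # cm^-2 s^-1
    "v": (1e-7, 1e-3),       # cm s^-1
    "b_branch": (0.0, 1e-4),  # s^-1
    "d": (0.0, 1e-4),        # s^-1
}

DEFAULT_LAMBDA_BOUNDS = (0.0, 1e-3)  # cm s^-1

#: Condition number of J^T J above which near-flat directions are flagged.
#: Separates dense three-parameter fits (~1e4) from fits with a near-flat
#: direction, e.g. the weakly-identified destruction rate d (~1e7).
IDENTIFIABILITY_COND = 1e6


class NonConvergenceError(RuntimeError):
    """Every optimisation start failed."""


class DegenerateDataError(ValueError):
    """Observations carry no signal (all zero / constant)."""


class UnidentifiableError(ValueError):
    """The requested parameter cannot be constrained by the supplied data."""


@dataclass
class FitResult:
    """Outcome of one bounded least-squares fit."""

    estimates: dict[str, float]
    objective: float
    r2: float
    n_starts: int
    converged: bool
    bounds: dict[str, tuple[float, float]]
    seed: int | None
    identifiability_warning: bool = False
    condition_number: float | None = None
    start_endpoints: list[dict] = field(default_factory=list, repr=False)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "objective": self.objective,
            "r2": self.r2,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "seed": self.seed,
            "identifiability_warning": self.identifiability_warning,
            "condition_number": self.condition_number,
            "extras": self.extras,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def growth_params(self) -> GrowthParams:
        e = self.estimates
        return GrowthParams(
            k=e["k"], v=e["v"], b_branch=e.get("b_branch", 0.0), d=e.get("d", 0.0)
        )


@dataclass
class AggregateFit:
    """Per-parameter mean and sample SD across replicate fits."""

    mean: dict[str, float]
    sd: dict[str, float]
    replicate_table: pd.DataFrame

    def format_entry(self, name: str, digits: int = 3) -> str:
        """Render one parameter in 'm x 10^e +/- s x 10^e' style."""
        return (
            f"{_sci(self.mean[name], digits)} ± {_sci(self.sd[name], digits + 1)}"
        )


def _sci(x: float, digits: int) -> str:
    if x == 0:
        return "0"
    exp = int(np.floor(np.log10(abs(x))))
    mant = x / 10.0**exp
    return f"{mant:.{digits - 1}f} × 10^{exp}"


def r_squared(model_values, obs_values) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    SS_tot is taken about the observation mean.  Raises if the observations
    have zero variance (R^2 undefined).
    """
    m = np.asarray(model_values, float)
    o = np.asarray(obs_values, float)
    if m.shape != o.shape or m.size < 2:
        raise ValueError("model and observations must share a length >= 2")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("observations have zero variance; R^2 undefined")
    ss_res = float(np.sum((m - o) ** 2))
    return 1.0 - ss_res / ss_tot


def _log_uniform_starts(rng, bounds: list[tuple[float, float]], n: int) -> np.ndarray:
    """Log-uniform samples within bounds; zero lower bounds are floored at
    1e-8 of the upper bound so the decade sweep stays meaningful."""
    starts = np.empty((n, len(bounds)))
    for j, (lo, hi) in enumerate(bounds):
        lo_eff = max(lo, hi * 1e-8)
        starts[:, j] = 10 ** rng.uniform(np.log10(lo_eff), np.log10(hi), size=n)
    return starts


def fit_growth(
    obs: ObservationSet,
    bounds: dict[str, tuple[float, float]] | None = None,
    fix_d: bool = True,
    d_value: float = 0.0,
    n_starts: int = 16,
    seed: int = 0,
) -> FitResult:
    """Fit (k, v, b[, d]) to length-density observations.

    Minimises ``sum (rho_model - rho_obs)^2`` with `scipy.optimize.least_squares`
    (trust-region reflective, box bounds) from ``n_starts`` log-uniform
    starting points.  Deterministic given ``(obs, bounds, seed, n_starts)``.
    The best optimum is returned together with every start's endpoint; a
    large condition number of the Gauss-Newton Hessian J^T J at the optimum
    raises the ``identifiability_warning`` flag (near-flat directions, e.g.
    on sparse designs with all four parameters free).
    """
    bounds_all = dict(DEFAULT_GROWTH_BOUNDS)
    if bounds:
        bounds_all.update(bounds)
    names = ["k", "v", "b_branch"] + ([] if fix_d else ["d"])
    blist = [bounds_all[n] for n in names]

    y = obs.values
    if np.all(y == 0):
        raise DegenerateDataError("all observations are zero; growth parameters undetermined")
    if len(obs) < len(names):
        raise ValueError(
            f"need at least {len(names)} informative records, got {len(obs)}"
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = dict(zip(names, theta))
        params = GrowthParams(
            k=p["k"], v=p["v"], b_branch=p["b_branch"], d=p.get("d", d_value)
        )
        return predict_rho(params, obs.positions, obs.times) - y

    rng = np.random.default_rng(seed)
    starts = _log_uniform_starts(rng, blist, n_starts)
    lo = np.array([b[0] for b in blist])
    hi = np.array([b[1] for b in blist])

    best = None
    endpoints: list[dict] = []
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                x_scale=np.maximum(x0, 1e-30),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - defensive
            endpoints.append({"x0": x0.tolist(), "error": str(exc)})
            continue
        endpoints.append(
            {"x0": x0.tolist(), "x": res.x.tolist(), "cost": float(res.cost)}
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise NonConvergenceError(
            f"all {n_starts} starts failed; endpoints: {endpoints}"
        )

    jac = best.jac
    jtj = jac.T @ jac
    try:
        cond = float(np.linalg.cond(jtj))
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    ident_warn = not np.isfinite(cond) or cond > IDENTIFIABILITY_COND
    if ident_warn:
        warnings.warn(
            "near-flat objective directions detected "
            f"(cond(J^T J) = {cond:.3g}); estimates may be unidentifiable"
        )

    estimates = dict(zip(names, (float(v) for v in best.x)))
    if fix_d:
        estimates["d"] = d_value
    model = residuals(best.x) + y
    costs = np.array([e["cost"] for e in endpoints if "cost" in e])
    return FitResult(
        estimates=estimates,
        objective=float(np.sum(best.fun**2)),
        r2=r_squared(model, y),
        n_starts=n_starts,
        converged=bool(best.success),
        bounds={n: bounds_all[n] for n in names},
        seed=seed,
        identifiability_warning=ident_warn,
        condition_number=cond,
        start_endpoints=endpoints,
        extras={
            "start_cost_dispersion": float(costs.std()) if costs.size else np.nan,
            "fixed": {} if not fix_d else {"d": d_value},
        },
    )


def fit_uptake(
    p_obs: pd.DataFrame,
    rho_field,
    uparams: UptakeParams,
    t_final: float,
    bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
    nx: int = 201,
    nt: int = 81,
    domain_length: float | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Estimate lambda_h from a normalised P profile at the final time.

    Parameters
    ----------
    p_obs : DataFrame
        Columns ``x_cm`` and ``c_rel`` (c_TOT / c_inf at t_final).
    rho_field : GrowthSolution, array, callable or scalar
        Length-density field driving the sink term.
    uparams : UptakeParams
        All transport parameters; ``lambda_h`` is ignored (it is the free
        parameter).
    t_final : float
        Time of the observed profile, s.

    A log-spaced coarse scan within bounds selects the multi-start points;
    each is refined with bounded least squares.  ``lambda_h >= 0`` always.
    """
    x_obs = np.asarray(p_obs["x_cm"], float)
    c_obs = np.asarray(p_obs["c_rel"], float)
    if x_obs.size < 2:
        raise ValueError("profile needs at least two points")
    L = domain_length if domain_length is not None else max(1.5 * x_obs.max(), x_obs.max() + 0.5)
    x_grid = np.linspace(0.0, L, nx)
    t_grid = np.linspace(0.0, t_final, nt)

    from .uptake import _rho_on_grid

    rho = _rho_on_grid(rho_field, x_grid, t_grid)
    if np.all(rho == 0):
        raise UnidentifiableError("rho is identically zero; lambda_h unidentifiable")
    if np.all(c_obs > 1.0 + 1e-6):
        warnings.warn("profile exceeds the far field everywhere: no depletion signal")

    def model_profile(lam: float) -> np.ndarray:
        up = uparams.replace(lambda_h=float(lam))
        with warnings.catch_warnings():
            # the coarse-grid advisory is expected at extreme scan values
            warnings.simplefilter("ignore", UserWarning)
            sol = solve_uptake(up, rho, x_grid, t_grid)
        return np.interp(x_obs, x_grid, sol.c_tot[-1]) / uparams.c_inf

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model_profile(theta[0]) - c_obs

    lo, hi = bounds
    lo_eff = max(lo, hi * 1e-10)
    scan = np.concatenate([[lo], 10 ** np.linspace(np.log10(lo_eff), np.log10(hi), 25)])
    scan_cost = np.array([np.sum(residuals(np.array([s])) ** 2) for s in scan])
    order = np.argsort(scan_cost)
    x0s = scan[order[:n_starts]]

    best = None
    endpoints = []
    for x0 in x0s:
        res = optimize.least_squares(
            residuals,
            np.array([max(x0, lo_eff * 1e-2) if x0 > 0 else lo_eff * 1e-2]),
            bounds=([lo], [hi]),
            method="trf",
            x_scale=[max(x0, lo_eff)],
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=200,
        )
        endpoints.append({"x0": float(x0), "x": float(res.x[0]), "cost": float(res.cost)})
        if best is None or res.cost < best.cost:
            best = res

    lam_hat = float(best.x[0])
    # snap to the lower bound when zero uptake already fits as well
    cost_lo = float(np.sum(residuals(np.array([lo])) ** 2))
    cost_hat = float(np.sum(residuals(best.x) ** 2))
    if cost_lo <= cost_hat + 1e-30:
        lam_hat = lo
    model = model_profile(lam_hat)
    try:
        r2 = r_squared(model, c_obs)
    except DegenerateDataError:
        r2 = np.nan
    return FitResult(
        estimates={"lambda_h": lam_hat},
        objective=float(np.sum((model - c_obs) ** 2)),
        r2=r2,
        n_starts=len(x0s),
        converged=bool(best.success),
        bounds={"lambda_h": bounds},
        seed=seed,
        start_endpoints=endpoints,
        extras={"r_m": uparams.r_m, "d_eff": uparams.d_eff, "t_final": t_final},
    )


def fit_growth_per_replicate(
    obs: ObservationSet, **kwargs
) -> tuple[list[FitResult], AggregateFit]:
    """Fit each replicate separately and aggregate (Table-style mean +/- SD)."""
    reps = pd.unique(obs.replicates)
    fits = [fit_growth(obs.subset_replicate(r), **kwargs) for r in reps]
    return fits, aggregate_replicates(fits)


def aggregate_replicates(fits: list[FitResult]) -> AggregateFit:
    """Per-parameter mean and sample SD (n-1 denominator) across fits."""
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for i, f in enumerate(fits):
        row = {"fit": i, **f.estimates, "r2": f.r2, "objective": f.objective}
        rows.append(row)
    table = pd.DataFrame(rows)
    names = [c for c in table.columns if c != "fit"]
    mean = {n: float(table[n].mean()) for n in names}
    sd = {
        n: float(table[n].std(ddof=1)) if len(fits) > 1 else 0.0 for n in names
    }
    return AggregateFit(mean=mean, sd=sd, replicate_table=table)
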