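"""Parameter estimation from mono-culture and cell-free data.

The fitting strategy mirrors the study design of the co-culture experiments:

1. ``fit_cellfree_ros`` estimates the abiotic ROS constants (d, e, m, l)
   from cell-free ROS-proxy time series at two or more LA concentrations.
2. ``fit_monoculture`` fixes those constants and estimates one species'
   growth/toxicity/detox parameters jointly across its mono-culture growth
   curves (and, for model 2, its ROS series).
3. ``predict_coculture`` integrates the co-culture system from the
   mono-culture estimates with **no refitting**; ``goodness_scores``
   quantifies fit (mono data) and prediction (held-out co data) as sums of
   squared log10 errors.

Least squares is bounded (box [0, 1e10]) via the trust-region reflective
algorithm; the objective is the vector of log10 residuals, so a point one
decade off contributes 1.0 to the squared objective.  Optimisation starts
from a fixed-seed ensemble of log-uniform draws (multi-start) because the
objective is multi-modal in the kinetic parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_core import (
    AbioticRosParams,
    CultureState,
    ModelSpec,
    SpeciesParams,
    PARAM_BOUND,
)
from .simulate import IntegrationError, Trajectory, integrate_batch

__all__ = [
    "CFU_FLOOR",
    "ROS_FLOOR",
    "FitProblem",
    "FitResult",
    "log10_residuals",
    "fit_cellfree_ros",
    "fit_monoculture",
    "predict_coculture",
    "goodness_scores",
    "squared_log10_error",
]

#: Residual floor for CFU counts (CFU/ml): log10 of zero counts is undefined,
#: and densities below one cell per ml are observationally equivalent to zero.
CFU_FLOOR = 1.0
#: Residual floor for the ROS proxy (au).
ROS_FLOOR = 1e-3

_DEFAULT_SEED = 1789
#: Log-uniform multi-start draws span this many decades below each
#: parameter's upper bound when its lower bound is 0.
_LOG_SPAN_DECADES = 12.0


def log10_residuals(observed, predicted, floor: float = CFU_FLOOR) -> np.ndarray:
    """log10(observed) - log10(predicted), with both series floored.

    Values below ``floor`` (including zeros from censoring or extinction)
    are clamped to it, so two sub-floor values agree exactly.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: observed {obs.shape} vs predicted {pred.shape}")
    return np.log10(np.maximum(obs, floor)) - np.log10(np.maximum(pred, floor))


@dataclass
class FitProblem:
    """Specification of one bounded least-squares estimation.

    ``free`` lists the parameter names to estimate; ``bounds`` maps each to
    a (lo, hi) box inside [0, 1e10]; ``scale`` is ``"log"`` (default;
    optimise log10 of the parameter) or ``"linear"``.  ``fixed`` holds
    parameters that are held at given values.  Exactly one model family's
    parameter object is populated from ``free`` + ``fixed``.
    """

    spec: ModelSpec
    free: Sequence[str]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    scale: str = "log"
    n_starts: int = 20
    n_polish: int = 8  # starts kept (by probe objective) for full optimisation
    seed: int = _DEFAULT_SEED
    #: optional informed start(s): a name->value dict or a list of them,
    #: prepended to the random ensemble
    x0: dict[str, float] | list[dict[str, float]] | None = None

    def __post_init__(self):
        if self.scale not in ("log", "linear"):
            raise ValueError("scale must be 'log' or 'linear'")
        for name, (lo, hi) in self.bounds.items():
            if not (0 <= lo <= hi <= PARAM_BOUND):
                raise ValueError(f"bounds for {name} must satisfy 0 <= lo <= hi <= {PARAM_BOUND:g}")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")

    def bound_for(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, (0.0, PARAM_BOUND))


@dataclass
class FitResult:
    """Outcome of a multi-start bounded least-squares fit."""

    params: dict[str, float]
    objective: float
    residuals: np.ndarray
    success: bool
    start_index: int
    start_objectives: np.ndarray
    pinned: list[str]
    free: list[str]

    def species_params(self, base: SpeciesParams | None = None) -> SpeciesParams:
        base = base or SpeciesParams(r=0.0, K=1.0, Y=1.0)
        known = {k: v for k, v in self.params.items()
                 if k in SpeciesParams.__dataclass_fields__}
        return replace(base, **known)

    def abiotic_params(self) -> AbioticRosParams:
        return AbioticRosParams(**{k: self.params[k] for k in ("d", "e", "m", "l")})


def _transform(values, los, his, scale):
    if scale == "linear":
        return values, los, his
    # log10 search; a 0 lower bound becomes a tiny positive floor
    tiny = np.maximum(los, his * 10 ** (-_LOG_SPAN_DECADES))
    return np.log10(np.maximum(values, tiny)), np.log10(tiny), np.log10(his)


def _untransform(x, scale):
    return 10 ** x if scale == "log" else x


def _multistart_least_squares(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    problem: FitProblem,
) -> FitResult:
    """Run bounded least squares from a fixed-seed start ensemble."""
    names = list(problem.free)
    # a degenerate box [v, v] pins the parameter exactly at v
    forced = {n: problem.bound_for(n)[0] for n in names
              if problem.bound_for(n)[0] == problem.bound_for(n)[1]}
    names = [n for n in names if n not in forced]
    if not names:
        resid = residual_fn(dict(forced))
        return FitResult(params={**problem.fixed, **forced},
                         objective=float(np.sum(np.asarray(resid) ** 2)),
                         residuals=np.asarray(resid), success=True, start_index=0,
                         start_objectives=np.array([float(np.sum(np.asarray(resid) ** 2))]),
                         pinned=sorted(forced), free=list(problem.free))
    los = np.array([problem.bound_for(n)[0] for n in names])
    his = np.array([problem.bound_for(n)[1] for n in names])
    rng = np.random.default_rng(problem.seed)

    # log-uniform draws within the (floored) box, regardless of search scale
    _, tlo, thi = _transform(his, los, his, "log")
    starts = [10 ** rng.uniform(tlo, thi) for _ in range(problem.n_starts)]
    if problem.x0 is not None:
        informed = problem.x0 if isinstance(problem.x0, list) else [problem.x0]
        for d in reversed(informed):
            starts.insert(0, np.array([d[n] for n in names], dtype=float))

    def wrapped(x):
        p = np.clip(_untransform(x, problem.scale), los, his)
        try:
            return residual_fn({**forced, **dict(zip(names, p))})
        except (IntegrationError, FloatingPointError):
            return np.full(wrapped.n_resid, 1e3)

    # residual length probe (needed for failure sentinel vectors)
    wrapped.n_resid = len(residual_fn({**forced,
                                       **dict(zip(names, np.clip(starts[0], los, his)))}))

    # probe every start with one residual evaluation, then fully optimise
    # only the most promising ones — the rest converge to the same basins
    probes = []
    for idx, s0 in enumerate(starts):
        x0, _, _ = _transform(np.clip(s0, los, his), los, his, problem.scale)
        probes.append(float(np.sum(wrapped(x0) ** 2)))
    order = np.argsort(probes)[: max(1, problem.n_polish)]

    best = None
    objectives = np.full(len(starts), np.inf)
    for idx in order:
        x0, xlo, xhi = _transform(np.clip(starts[idx], los, his), los, his, problem.scale)
        try:
            sol = least_squares(wrapped, x0, bounds=(xlo, xhi), method="trf",
                                x_scale="jac", max_nfev=400)
        except Exception:
            continue
        obj = float(np.sum(sol.fun ** 2))
        objectives[idx] = obj
        if best is None or obj < best[0]:
            best = (obj, int(idx), sol)
    if best is None:
        raise RuntimeError("all optimisation starts failed")

    obj, idx, sol = best
    values = np.clip(_untransform(sol.x, problem.scale), los, his)
    params = {**forced, **dict(zip(names, values))}
    pinned = sorted(set(forced) | {
        n for n, v, lo, hi in zip(names, values, los, his)
        if v <= lo + 1e-8 * (hi - lo) or v >= hi - 1e-8 * (hi - lo)})
    if pinned:
        warnings.warn(f"fitted parameters pinned at bounds: {pinned}", stacklevel=2)
    return FitResult(params={**problem.fixed, **params}, objective=obj,
                     residuals=sol.fun, success=bool(sol.success or obj < np.inf),
                     start_index=idx, start_objectives=np.array(objectives),
                     pinned=pinned, free=names)


# ---------------------------------------------------------------------------
# cell-free ROS pre-fit


def fit_cellfree_ros(
    ros_df: pd.DataFrame,
    problem: FitProblem | None = None,
    value_col: str = "ros_au",
    rtol: float = 1e-7,
) -> FitResult:
    """Estimate (d, e, m, l) from cell-free ROS series at several LA levels.

    ``ros_df`` is tidy with columns ``concentration_au`` (the initial LA,
    C0), ``time_h`` and ``value_col``; replicates may be present (each row
    contributes one residual).  The cell-free model-2 system (B = 0) is
    integrated per concentration and compared on the log10 scale with floor
    :data:`ROS_FLOOR`.
    """
    if problem is None:
        problem = FitProblem(
            spec=ModelSpec(family="model2"),
            free=["d", "e", "m", "l"],
            bounds={"d": (0.0, 10.0), "e": (0.0, 10.0),
                    "m": (1e-3, 1e3), "l": (0.0, 10.0)},
        )
    groups = []
    for c0, g in ros_df.groupby("concentration_au"):
        g = g.sort_values("time_h")
        times = np.unique(g["time_h"].to_numpy(dtype=float))
        groups.append((float(c0), times, g))
    dummy = SpeciesParams(r=0.0, K=1.0, Y=1.0)

    def residual_fn(values: dict[str, float]) -> np.ndarray:
        ab = AbioticRosParams(**{**{"d": 0.0, "e": 0.0, "m": 1.0, "l": 0.0},
                                 **problem.fixed, **values})
        res = []
        for c0, times, g in groups:
            t_grid = times if times[0] == 0 else np.concatenate([[0.0], times])
            traj = integrate_batch(CultureState(C=c0), dummy, dummy, problem.spec,
                                   t_grid, ab=ab, rtol=rtol)
            pred = np.interp(g["time_h"].to_numpy(dtype=float), traj.t, traj.column("R"))
            res.append(log10_residuals(g[value_col].to_numpy(dtype=float), pred,
                                       floor=ROS_FLOOR))
        return np.concatenate(res)

    return _multistart_least_squares(residual_fn, problem)


# ---------------------------------------------------------------------------
# mono-culture fit


def _integrate_mono_stacked(
    sp: SpeciesParams,
    spec: ModelSpec,
    ab: AbioticRosParams | None,
    c0s: np.ndarray,
    inoc: np.ndarray,
    N0: float,
    t_grid: np.ndarray,
    rtol: float,
) -> np.ndarray:
    """Integrate one species' mono-cultures at several LA levels in one solve.

    The conditions are independent, so stacking them into a single block
    state ``[B..., C..., R..., N...]`` gives identical dynamics while
    sharing solver overhead — worth a several-fold speedup inside the
    fitting loop.  Returns an array of shape (len(t_grid), n_cond, 4) in
    the order (B, C, R, N).
    """
    from scipy.integrate import solve_ivp

    n = len(c0s)
    ab_eff = spec.effective_abiotic(ab)
    use_n = spec.include_mm_nutrient and sp.r_N > 0
    model1 = spec.family == "model1"
    gamma = 0.0 if (model1 and spec.no_toxicity_accumulation) else sp.gamma
    r, K, Y, beta, alpha = sp.r, sp.K, sp.Y, sp.beta, sp.alpha
    dy = np.zeros(4 * n)

    def rhs(t, y):
        y = np.maximum(y, 0.0)
        B, C, R, N = y[:n], y[n:2*n], y[2*n:3*n], y[3*n:]
        growth = (r * B) * (C / (C + K)) if K > 0 else r * B * (C > 0)
        dC = -growth / Y
        if use_n:
            gN = (sp.r_N * B) * (N / (N + sp.K_N)) if sp.K_N > 0 else sp.r_N * B * (N > 0)
            growth = growth + gN
            dy[3*n:] = -gN / sp.Y_N
        if model1:
            dy[:n] = growth - (beta + gamma * t) * C * B
        else:
            dy[:n] = growth - beta * R * B
            gen = (ab_eff.d + ab_eff.e * R) * C
            dy[2*n:3*n] = gen - ab_eff.l * R - alpha * B * R
            if ab_eff.m > 0:
                dC = dC - gen / ab_eff.m
        dy[n:2*n] = dC
        return dy

    y0 = np.concatenate([inoc, c0s, np.zeros(n), np.full(n, N0)])
    atol = np.concatenate([np.full(n, 1e-4), np.full(3 * n, 1e-9)])
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"stacked mono-culture integration failed: {sol.message}")
    out = np.clip(sol.y.T, 0.0, None)  # (ntimes, 4n)
    return out.reshape(len(t_grid), 4, n).transpose(0, 2, 1)


def _mono_residuals(
    values: dict[str, float],
    problem: FitProblem,
    groups,
    ros_groups,
    abiotic: AbioticRosParams | None,
    inoculum: dict[float, float],
    N0: float,
    rtol: float,
    cfu_floor: float = CFU_FLOOR,
):
    par = {**problem.fixed, **values}
    sp = SpeciesParams(**{k: v for k, v in par.items()
                          if k in SpeciesParams.__dataclass_fields__})
    c0s = np.array([c0 for c0, _, _ in groups])
    inoc = np.array([inoculum[c0] for c0, _, _ in groups])
    all_times = [times for _, times, _ in groups]
    if ros_groups:
        all_times += [g["time_h"].to_numpy(dtype=float) for g in ros_groups.values()]
    t_grid = np.unique(np.concatenate([[0.0]] + all_times))
    sol = _integrate_mono_stacked(sp, problem.spec, abiotic, c0s, inoc, N0,
                                  t_grid, rtol)  # (ntimes, ncond, 4)
    res = []
    for i, (c0, times, g) in enumerate(groups):
        pred = np.interp(g["time_h"].to_numpy(dtype=float), t_grid, sol[:, i, 0])
        res.append(log10_residuals(g["cfu_per_ml"].to_numpy(dtype=float), pred,
                                   floor=cfu_floor))
        if ros_groups is not None and c0 in ros_groups:
            rg = ros_groups[c0]
            pred_r = np.interp(rg["time_h"].to_numpy(dtype=float), t_grid, sol[:, i, 2])
            res.append(log10_residuals(rg["ros_au"].to_numpy(dtype=float), pred_r,
                                       floor=ROS_FLOOR))
    return np.concatenate(res)


def _heuristic_starts(groups, inoculum: dict[float, float]) -> list[dict[str, float]]:
    """Crude data-driven initial guesses for the growth-curve shape parameters.

    Replaces hand tuning of start values: the maximum log-slope between
    consecutive time points bounds the Monod growth rate from below (the
    coarser the sampling, the larger the underestimate, hence several
    inflation factors), the largest density reached per au of LA estimates
    the yield, and the toxicity terms start small so optimisation decides
    whether death is needed.  A few extra multi-start members; the
    log-uniform ensemble still explores globally.
    """
    r0 = 0.0
    Y0 = 0.0
    cmax = 0.0
    for c0, times, g in groups:
        b = g.groupby("time_h")["cfu_per_ml"].apply(
            lambda s: np.exp(np.mean(np.log(np.maximum(s, CFU_FLOOR))))
        )
        t = b.index.to_numpy(dtype=float)
        v = np.log(np.maximum(b.to_numpy(dtype=float), CFU_FLOOR))
        if len(t) > 1:
            r0 = max(r0, float(np.max(np.diff(v) / np.diff(t))))
        if c0 > 0:
            Y0 = max(Y0, (float(b.max()) - inoculum[c0]) / c0)
        cmax = max(cmax, c0)
    r0 = max(r0, 1e-3)
    cmax = max(cmax, 1e-3)
    out = []
    for r_mult in (1.2, 2.5):
        for k_frac in (0.05, 0.25):
            out.append({
                "r": r_mult * r0, "K": k_frac * cmax, "Y": max(Y0, 1.0),
                "beta": 0.05 * r0 / cmax, "gamma": 0.05 * r0 / cmax / 20.0,
                "alpha": 1e-12,
            })
    return out


def fit_monoculture(
    problem: FitProblem,
    growth_df: pd.DataFrame,
    ros_df: pd.DataFrame | None = None,
    abiotic: AbioticRosParams | None = None,
    inoculum: float | dict[float, float] | None = None,
    N0: float = 0.0,
    rtol: float = 1e-6,
    cfu_floor: float = CFU_FLOOR,
) -> FitResult:
    """Fit one species' parameters to its mono-culture growth curves.

    ``growth_df`` is tidy (columns ``concentration_au``, ``time_h``,
    ``cfu_per_ml``; replicates as rows) covering one or more initial LA
    concentrations, which are fitted jointly.  For model 2, pass the
    ``abiotic`` constants pre-estimated by :func:`fit_cellfree_ros` (they
    are held fixed) and optionally the species' own ROS series ``ros_df``,
    whose points enter the objective with equal per-point weight.

    The starting density per concentration defaults to the mean observation
    at the earliest time point.
    """
    if problem.spec.family == "model2" and abiotic is None:
        raise ValueError("model2 mono-culture fits require the pre-fitted abiotic constants")
    groups = []
    for c0, g in growth_df.groupby("concentration_au"):
        g = g.sort_values("time_h")
        groups.append((float(c0), np.unique(g["time_h"].to_numpy(dtype=float)), g))
    if not groups:
        raise ValueError("empty growth dataset")

    if inoculum is None:
        inoc = {}
        for c0, times, g in groups:
            first = g[g["time_h"] == times[0]]["cfu_per_ml"]
            inoc[c0] = float(np.exp(np.mean(np.log(np.maximum(first, CFU_FLOOR)))))
    elif isinstance(inoculum, dict):
        inoc = {float(k): float(v) for k, v in inoculum.items()}
    else:
        inoc = {c0: float(inoculum) for c0, _, _ in groups}

    ros_groups = None
    if ros_df is not None and len(ros_df):
        ros_groups = {float(c0): g.sort_values("time_h")
                      for c0, g in ros_df.groupby("concentration_au")}

    if problem.x0 is None:
        defaults = {n: np.sqrt(max(problem.bound_for(n)[0], 1e-12 * problem.bound_for(n)[1])
                               * problem.bound_for(n)[1]) for n in problem.free}
        informed = []
        for guess in _heuristic_starts(groups, inoc):
            x0 = dict(defaults)
            for name in problem.free:
                if name in guess:
                    lo, hi = problem.bound_for(name)
                    x0[name] = float(np.clip(guess[name], lo if lo > 0 else hi * 1e-12, hi))
            informed.append(x0)
        if informed:
            problem = replace(problem, x0=informed)

    def residual_fn(values):
        return _mono_residuals(values, problem, groups, ros_groups, abiotic,
                               inoc, N0, rtol, cfu_floor)

    return _multistart_least_squares(residual_fn, problem)


# ---------------------------------------------------------------------------
# co-culture prediction and scoring


def predict_coculture(
    p_At: SpeciesParams,
    p_Ct: SpeciesParams,
    spec: ModelSpec,
    state0: CultureState,
    t_grid,
    ab: AbioticRosParams | None = None,
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate the co-culture from mono-culture estimates (no refitting)."""
    return integrate_batch(state0, p_At, p_Ct, spec, t_grid, ab=ab, rtol=rtol)


def squared_log10_error(
    traj: Trajectory,
    df: pd.DataFrame,
    column: str,
    value_col: str = "cfu_per_ml",
    floor: float = CFU_FLOOR,
) -> float:
    """Sum of squared log10 errors of a trajectory column against tidy data."""
    if df.empty:
        raise ValueError("empty dataset")
    pred = np.interp(df["time_h"].to_numpy(dtype=float), traj.t, traj.column(column))
    r = log10_residuals(df[value_col].to_numpy(dtype=float), pred, floor=floor)
    return float(np.sum(r ** 2))


def goodness_scores(
    mono_pairs: Sequence[tuple[Trajectory, pd.DataFrame, str]],
    co_pairs: Sequence[tuple[Trajectory, pd.DataFrame, str]],
    value_col: str = "cfu_per_ml",
    floor: float = CFU_FLOOR,
) -> dict[str, float]:
    """Goodness-of-fit (mono data) and goodness-of-prediction (co data).

    Each pair is ``(trajectory, tidy observations, state column)``, e.g.
    ``(traj, df_at_075, "B_At")``; scores are summed over all pairs.
    """
    if not mono_pairs and not co_pairs:
        raise ValueError("no datasets to score")
    fit = sum(squared_log10_error(tr, df, col, value_col, floor)
              for tr, df, col in mono_pairs)
    pred = sum(squared_log10_error(tr, df, col, value_col, floor)
               for tr, df, col in co_pairs)
    return {"goodness_of_fit": float(fit), "goodness_of_prediction": float(pred)}
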