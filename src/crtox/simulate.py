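"""Batch integration, serial-transfer chaining, and coexistence phase sweeps.

A *serial transfer* experiment grows a batch culture for a fixed interval
(72 h by default), dilutes it into fresh medium (100-fold by default) and
repeats.  Coexistence is read off the per-transfer end-of-cycle abundances:
a species whose density falls below the extinction threshold is removed.

The batch clock restarts at every transfer: in model 1 the accumulating
toxicity term ``gamma * t`` counts time since the current batch of medium
was prepared (fresh medium has not yet oxidised), and in model 2 fresh
medium contributes no ROS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    AbioticRosParams,
    CultureState,
    ModelSpec,
    SpeciesParams,
    STATE_VARS,
    rhs_vector,
)

__all__ = [
    "SURVIVED",
    "Trajectory",
    "TransferProtocol",
    "PhaseDiagram",
    "IntegrationError",
    "integrate_batch",
    "apply_transfer",
    "run_serial_transfers",
    "extinction_transfer",
    "sweep_phase",
    "extinction_vs_concentration",
]

#: Sentinel extinction-transfer index meaning "survived the full horizon".
SURVIVED = -1

SPECIES = ("At", "Ct")
_SPECIES_COL = {"At": "B_At", "Ct": "B_Ct"}


class IntegrationError(RuntimeError):
    """ODE integration failed; the message names the offending parameter set."""


@dataclass
class Trajectory:
    """Solution of one batch culture on a time grid.

    ``t`` is the grid in hours (strictly increasing); ``y`` has one row per
    grid point in the state order ``(B_At, B_Ct, C, R, N)``, clipped at 0.
    """

    t: np.ndarray
    y: np.ndarray
    spec: ModelSpec
    p_At: SpeciesParams
    p_Ct: SpeciesParams
    ab: AbioticRosParams | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("Trajectory time grid must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        return self.y[:, STATE_VARS.index(name)]

    def at(self, times) -> np.ndarray:
        """Linear interpolation of every state column at the given times."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        return np.column_stack([np.interp(times, self.t, self.y[:, j]) for j in range(5)])

    @property
    def final_state(self) -> CultureState:
        return CultureState.from_vector(self.y[-1], t=self.t[-1])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_VARS))
        df.insert(0, "time_h", self.t)
        return df


@dataclass(frozen=True)
class TransferProtocol:
    """Dilution schedule for a serial-transfer experiment.

    ``carryover='dilute_all'`` transfers an aliquot of the whole culture:
    residual LA, ROS and nutrient are diluted into the fresh medium.
    ``'biomass_only'`` transfers cells only (fresh medium otherwise).
    """

    D: float = 100.0
    interval: float = 72.0
    n_transfers: int = 5
    fresh_C0: float = 0.75
    fresh_N0: float = 0.0
    extinction_threshold: float = 1.0
    carryover: str = "dilute_all"

    def __post_init__(self):
        if self.D <= 1:
            raise ValueError("dilution factor D must be > 1")
        if self.interval <= 0:
            raise ValueError("transfer interval must be > 0")
        if self.extinction_threshold <= 0:
            raise ValueError("extinction threshold must be > 0")
        if self.carryover not in ("dilute_all", "biomass_only"):
            raise ValueError(f"unknown carryover policy {self.carryover!r}")

    def with_(self, **kw) -> "TransferProtocol":
        return replace(self, **kw)


def integrate_batch(
    state0: CultureState,
    p_At: SpeciesParams,
    p_Ct: SpeciesParams,
    spec: ModelSpec,
    t_grid,
    ab: AbioticRosParams | None = None,
    rtol: float = 1e-8,
    atol=None,
) -> Trajectory:
    """Integrate one batch culture of the chosen model on ``t_grid``.

    ``t_grid`` must start at ``state0.t``.  Uses LSODA (the death terms make
    the system moderately stiff late in a batch); states are clipped at 0
    after solving, since strictly positive trajectories can undershoot
    numerically.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must contain at least two time points")
    if abs(t_grid[0] - state0.t) > 1e-9:
        raise ValueError(f"t_grid starts at {t_grid[0]} but state0.t = {state0.t}")
    if atol is None:
        # abundances are O(1e5-1e10), chemicals O(1); scale atol per channel
        atol = np.array([1e-4, 1e-4, 1e-12, 1e-12, 1e-12])

    y0 = state0.to_vector()
    if spec.family == "model2" and spec.ros_free:
        y0[3] = 0.0  # antioxidant mimic: start without ROS

    sol = solve_ivp(
        rhs_vector,
        (t_grid[0], t_grid[-1]),
        y0,
        t_eval=t_grid,
        args=(p_At, p_Ct, spec, ab),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed ({sol.message}) for spec={spec}, p_At={p_At}, "
            f"p_Ct={p_Ct}, ab={ab}"
        )
    return Trajectory(t=sol.t, y=np.clip(sol.y.T, 0.0, None), spec=spec,
                      p_At=p_At, p_Ct=p_Ct, ab=ab)


def apply_transfer(state: CultureState, protocol: TransferProtocol) -> CultureState:
    """Dilute an end-of-cycle culture into fresh medium.

    ``dilute_all``: every component is carried over at 1/D and fresh LA /
    nutrient are added.  ``biomass_only``: only cells are carried over.
    The batch clock restarts at 0.
    """
    D = protocol.D
    if protocol.carryover == "dilute_all":
        return CultureState(
            B_At=state.B_At / D,
            B_Ct=state.B_Ct / D,
            C=protocol.fresh_C0 + state.C / D,
            R=state.R / D,
            N=protocol.fresh_N0 + state.N / D,
            t=0.0,
        )
    return CultureState(
        B_At=state.B_At / D,
        B_Ct=state.B_Ct / D,
        C=protocol.fresh_C0,
        R=0.0,
        N=protocol.fresh_N0,
        t=0.0,
    )


def run_serial_transfers(
    state0: CultureState,
    p_At: SpeciesParams,
    p_Ct: SpeciesParams,
    spec: ModelSpec,
    protocol: TransferProtocol,
    ab: AbioticRosParams | None = None,
    points_per_cycle: int = 25,
    keep_trajectories: bool = True,
    rtol: float = 1e-8,
):
    """Chain batch cycles with dilution into a serial-transfer experiment.

    Each cycle integrates ``protocol.interval`` hours from the (re-zeroed)
    batch clock; at the end-of-cycle check point any species below
    ``extinction_threshold`` is set to 0, the end state is recorded, and the
    culture is diluted for the next cycle.

    Returns ``(trajectories, table)`` where ``table`` has one row per
    transfer with end-of-cycle ``B_At``, ``B_Ct``, ``C``, ``R``, ``N``.
    With ``keep_trajectories=False`` the first element is an empty list
    (used by large phase sweeps).
    """
    t_grid = np.linspace(0.0, protocol.interval, points_per_cycle)
    trajectories = []
    rows = []
    state = state0
    for k in range(1, protocol.n_transfers + 1):
        state = CultureState(B_At=state.B_At, B_Ct=state.B_Ct, C=state.C,
                             R=state.R, N=state.N, t=0.0)
        traj = integrate_batch(state, p_At, p_Ct, spec, t_grid, ab=ab, rtol=rtol)
        if keep_trajectories:
            trajectories.append(traj)
        end = traj.final_state
        B_At = end.B_At if end.B_At >= protocol.extinction_threshold else 0.0
        B_Ct = end.B_Ct if end.B_Ct >= protocol.extinction_threshold else 0.0
        rows.append({"transfer": k, "B_At": B_At, "B_Ct": B_Ct,
                     "C": end.C, "R": end.R, "N": end.N})
        end = CultureState(B_At=B_At, B_Ct=B_Ct, C=end.C, R=end.R, N=end.N, t=end.t)
        state = apply_transfer(end, protocol)
    return trajectories, pd.DataFrame(rows)


def extinction_transfer(table: pd.DataFrame, species: str, threshold: float = 1.0) -> int:
    """First transfer at which a species' end-of-cycle density is below threshold.

    Returns :data:`SURVIVED` (= -1) if the species stays above threshold for
    the whole table.
    """
    if species not in _SPECIES_COL:
        raise KeyError(f"unknown species {species!r}; expected one of {SPECIES}")
    col = _SPECIES_COL[species]
    below = table[col].to_numpy() < threshold
    if not below.any():
        return SURVIVED
    return int(table["transfer"].to_numpy()[int(np.argmax(below))])


def _ext_sort_key(idx: int) -> float:
    """Order extinction indices with the survived sentinel ranked last."""
    return np.inf if idx == SURVIVED else float(idx)


@dataclass
class PhaseDiagram:
    """Outcome of a (initial LA) x (dilution factor) serial-transfer sweep.

    ``outcome[i, j]`` classifies the co-culture at C0_grid[i], D_grid[j] as
    ``coexistence`` / ``Ct_only`` / ``At_only`` / ``both_extinct`` at the
    horizon; ``at_ext`` / ``ct_ext`` hold per-species extinction transfer
    indices (:data:`SURVIVED` if the species persisted).
    """

    C0_grid: np.ndarray
    D_grid: np.ndarray
    outcome: np.ndarray
    at_ext: np.ndarray
    ct_ext: np.ndarray
    horizon: int

    def count(self, outcome: str) -> int:
        return int(np.sum(self.outcome == outcome))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, c0 in enumerate(self.C0_grid):
            for j, d in enumerate(self.D_grid):
                rows.append({
                    "C0_au": c0,
                    "dilution": d,
                    "outcome": self.outcome[i, j],
                    "at_extinction_transfer": int(self.at_ext[i, j]),
                    "ct_extinction_transfer": int(self.ct_ext[i, j]),
                })
        return pd.DataFrame(rows)


def _classify(at_ext: int, ct_ext: int) -> str:
    at_alive = at_ext == SURVIVED
    ct_alive = ct_ext == SURVIVED
    if at_alive and ct_alive:
        return "coexistence"
    if ct_alive:
        return "Ct_only"
    if at_alive:
        return "At_only"
    return "both_extinct"


def sweep_phase(
    C0_grid,
    D_grid,
    p_At: SpeciesParams,
    p_Ct: SpeciesParams,
    spec: ModelSpec,
    protocol_template: TransferProtocol,
    horizon: int | None = None,
    ab: AbioticRosParams | None = None,
    inoculum: float = 5e5,
    rtol: float = 1e-7,
) -> PhaseDiagram:
    """Run one co-culture serial-transfer simulation per grid cell and classify it.

    Deterministic: two sweeps with identical inputs give identical diagrams.
    """
    C0_grid = np.asarray(C0_grid, dtype=float)
    D_grid = np.asarray(D_grid, dtype=float)
    if C0_grid.size == 0 or D_grid.size == 0:
        raise ValueError("phase-sweep grids must be non-empty")
    horizon = horizon if horizon is not None else protocol_template.n_transfers

    outcome = np.empty((C0_grid.size, D_grid.size), dtype=object)
    at_ext = np.empty(outcome.shape, dtype=int)
    ct_ext = np.empty(outcome.shape, dtype=int)
    for i, c0 in enumerate(C0_grid):
        for j, d in enumerate(D_grid):
            protocol = protocol_template.with_(D=float(d), fresh_C0=float(c0),
                                               n_transfers=horizon)
            state0 = CultureState(B_At=inoculum, B_Ct=inoculum, C=float(c0),
                                  N=protocol.fresh_N0)
            _, table = run_serial_transfers(
                state0, p_At, p_Ct, spec, protocol, ab=ab,
                keep_trajectories=False, rtol=rtol,
            )
            a = extinction_transfer(table, "At", protocol.extinction_threshold)
            c = extinction_transfer(table, "Ct", protocol.extinction_threshold)
            at_ext[i, j] = a
            ct_ext[i, j] = c
            outcome[i, j] = _classify(a, c)
    return PhaseDiagram(C0_grid=C0_grid, D_grid=D_grid, outcome=outcome,
                        at_ext=at_ext, ct_ext=ct_ext, horizon=horizon)


def extinction_vs_concentration(
    C0_grid,
    p_At: SpeciesParams,
    p_Ct: SpeciesParams,
    spec: ModelSpec,
    protocol_template: TransferProtocol,
    horizon: int = 300,
    ab: AbioticRosParams | None = None,
    inoculum: float = 5e5,
    rtol: float = 1e-7,
) -> pd.DataFrame:
    """At extinction transfer in mono- vs co-culture along an initial-LA gradient.

    The long-horizon analogue of the phase sweep at one dilution factor,
    used to ask where the partner shortens (competitive exclusion) or
    extends (facilitation) At's survival.  Returns a tidy frame with
    columns C0_au, at_ext_mono, at_ext_co (:data:`SURVIVED` = persisted).
    """
    rows = []
    for c0 in np.asarray(C0_grid, dtype=float):
        protocol = protocol_template.with_(fresh_C0=float(c0), n_transfers=horizon)
        ext = {}
        for label, b_ct in (("mono", 0.0), ("co", inoculum)):
            state0 = CultureState(B_At=inoculum, B_Ct=b_ct, C=float(c0),
                                  N=protocol.fresh_N0)
            _, table = run_serial_transfers(
                state0, p_At, p_Ct, spec, protocol, ab=ab,
                keep_trajectories=False, rtol=rtol,
            )
            ext[label] = extinction_transfer(table, "At", protocol.extinction_threshold)
        rows.append({"C0_au": c0, "at_ext_mono": ext["mono"], "at_ext_co": ext["co"]})
    return pd.DataFrame(rows)
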