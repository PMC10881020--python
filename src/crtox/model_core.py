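"""Consumer-resource-toxin ODE models for a two-species co-culture on linoleic acid.

Two model families describe the growth of *Agrobacterium tumefaciens* (``At``)
and *Comamonas testosteroni* (``Ct``) on linoleic acid (LA) as the sole added
carbon source:

* **Model 1** (implicit toxicity): LA is both the nutrient and the toxin.
  Each species grows with Monod kinetics on the LA concentration ``C`` and
  dies at a per-capita rate ``(beta + gamma*t) * C`` — toxicity is
  proportional to LA and, through ``gamma``, accumulates linearly with the
  time the batch has been oxidising.

* **Model 2** (explicit ROS toxicity): LA is a nutrient only.  Reactive
  oxygen species (ROS, tracked as the proxy variable ``R``) are generated
  spontaneously from LA at rate ``(d + e*R) * C`` — the ``e`` term is the
  ROS-catalysed (autocatalytic) channel of lipid peroxidation — decay at
  rate ``l``, and are removed by bacteria at a per-capita rate ``alpha``.
  Death is per-capita ``beta * R``.

Both families optionally include a second Monod growth channel on an
unspecified minimal-medium nutrient ``N`` (initially 0.01 au), which accounts
for the residual growth observed with no added carbon source.

Units: time in hours, abundances in CFU/ml, chemical concentrations in
arbitrary units (au) with the convention 1 au of LA = 1 % v/v.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "PARAM_BOUND",
    "SpeciesParams",
    "AbioticRosParams",
    "CultureState",
    "ModelSpec",
    "DomainError",
    "monod",
    "rhs_model1",
    "rhs_model2",
    "rhs_vector",
]

#: Upper box bound on every rate/yield parameter (shared with the fitting
#: routine, which searches the box [0, PARAM_BOUND]).
PARAM_BOUND = 1e10


class DomainError(ValueError):
    """Raised when a state or parameter set is outside the model's domain."""


def _check_bounds(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not np.isfinite(v) or v < 0:
            raise DomainError(f"{type(obj).__name__}.{name} = {v!r}: must be finite and >= 0")
        if v > PARAM_BOUND:
            raise DomainError(
                f"{type(obj).__name__}.{name} = {v!r} exceeds the upper bound {PARAM_BOUND:g}"
            )


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species rates for either model family.

    Parameters
    ----------
    r : float
        Maximum specific growth rate on LA (1/h).
    K : float
        Monod half-saturation constant for LA (au).
    Y : float
        Yield: CFU/ml produced per au of LA consumed.
    beta : float
        Toxin sensitivity.  Model 1: death rate per au of LA (1/(au*h)).
        Model 2: death rate per au of ROS (1/(au*h)).
    gamma : float
        Toxicity-accumulation rate, model 1 only (1/(au*h^2)): the
        per-capita death rate is ``(beta + gamma*t) * C`` with ``t`` the
        time since the batch was prepared.
    alpha : float
        Per-capita ROS removal rate, model 2 only (ml/(CFU*h)).
    r_N, K_N, Y_N : float
        Optional Monod growth channel on the minimal-medium nutrient ``N``
        (same units as ``r``, ``K``, ``Y``).  Inert when ``r_N == 0``.
    """

    r: float
    K: float
    Y: float
    beta: float = 0.0
    gamma: float = 0.0
    alpha: float = 0.0
    r_N: float = 0.0
    K_N: float = 0.01
    Y_N: float = 1.0

    def __post_init__(self):
        _check_bounds(self, [f.name for f in fields(self)])
        if self.Y <= 0:
            raise DomainError("SpeciesParams.Y must be > 0 (division by yield)")
        if self.r_N > 0 and self.Y_N <= 0:
            raise DomainError("SpeciesParams.Y_N must be > 0 when r_N > 0")

    def with_(self, **kw) -> "SpeciesParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class AbioticRosParams:
    """Cell-free ROS generation/decay constants (model 2).

    ``d``: spontaneous generation rate per au LA (1/h); ``e``: ROS-catalysed
    generation rate (1/(au*h)); ``m``: au of LA consumed per au of ROS
    produced (dimensionless conversion); ``l``: first-order ROS decay (1/h).

    The cell-free system has the fixed point ``R* = d*C / (l - e*C)`` when
    ``l > e*C``: ROS first rises, then stabilises.
    """

    d: float
    e: float
    m: float
    l: float

    def __post_init__(self):
        _check_bounds(self, ("d", "e", "m", "l"))
        if self.d + self.e > 0 and self.m <= 0:
            raise DomainError("AbioticRosParams.m must be > 0 when d + e > 0 (division by m)")

    def with_(self, **kw) -> "AbioticRosParams":
        return replace(self, **kw)


#: Order of the state vector used by the integrators.
STATE_VARS = ("B_At", "B_Ct", "C", "R", "N")


@dataclass
class CultureState:
    """Abundances and concentrations of one culture at one time point.

    ``B_At``, ``B_Ct`` in CFU/ml; ``C`` (LA), ``R`` (ROS proxy) and ``N``
    (minimal-medium nutrient) in au; ``t`` in hours.  In model 1, ``R`` is
    unused and stays 0.
    """

    B_At: float = 0.0
    B_Ct: float = 0.0
    C: float = 0.0
    R: float = 0.0
    N: float = 0.0
    t: float = 0.0

    def __post_init__(self):
        for name in STATE_VARS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"CultureState.{name} = {v!r}: must be finite and >= 0")

    def to_vector(self) -> np.ndarray:
        return np.array([self.B_At, self.B_Ct, self.C, self.R, self.N], dtype=float)

    @classmethod
    def from_vector(cls, y, t: float = 0.0) -> "CultureState":
        y = np.clip(np.asarray(y, dtype=float), 0.0, None)
        return cls(B_At=y[0], B_Ct=y[1], C=y[2], R=y[3], N=y[4], t=t)


@dataclass(frozen=True)
class ModelSpec:
    """Which model family and which simplification variant to run.

    Variant flags:

    * ``no_toxicity_accumulation`` (model 1): force ``gamma = 0``.
    * ``linear_ros`` (model 2): force ``e = 0`` (no ROS-catalysed oxidation).
    * ``ros_free`` (model 2): force ``d = e = l = 0`` and start with
      ``R = 0`` — mimics continuous antioxidant (TBHQ) addition.
    * ``include_mm_nutrient``: activate the ``N`` growth channel.
    """

    family: str = "model2"
    no_toxicity_accumulation: bool = False
    linear_ros: bool = False
    ros_free: bool = False
    include_mm_nutrient: bool = False

    def __post_init__(self):
        if self.family not in ("model1", "model2"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "model1" and (self.linear_ros or self.ros_free):
            raise ValueError("ROS variant flags are only valid for model2")
        if self.family == "model2" and self.no_toxicity_accumulation:
            raise ValueError("no_toxicity_accumulation is only valid for model1")

    def effective_abiotic(self, ab: AbioticRosParams | None) -> AbioticRosParams:
        """Apply the variant flags to the abiotic ROS constants."""
        if self.family == "model1":
            return AbioticRosParams(0.0, 0.0, 1.0, 0.0)
        if ab is None:
            raise ValueError("model2 requires AbioticRosParams")
        if self.ros_free:
            return ab.with_(d=0.0, e=0.0, l=0.0)
        if self.linear_ros:
            return ab.with_(e=0.0)
        return ab


def monod(C: float, K: float) -> float:
    """Saturating uptake term C/(C+K), defined as 0 at C<=0 and 1 if K=0<C."""
    if C <= 0.0:
        return 0.0
    return C / (C + K)


def _growth_and_uptake(B, C, N, p: SpeciesParams, use_n: bool):
    """Monod growth of one species and its LA / N consumption rates."""
    gC = p.r * monod(C, p.K)
    growth = gC * B
    dC = -growth / p.Y
    dN = 0.0
    if use_n and p.r_N > 0:
        gN = p.r_N * monod(N, p.K_N)
        growth += gN * B
        dN = -gN * B / p.Y_N
    return growth, dC, dN


def rhs_vector(
    t: float,
    y: np.ndarray,
    p_At: SpeciesParams,
    p_Ct: SpeciesParams,
    spec: ModelSpec,
    ab: AbioticRosParams | None = None,
) -> np.ndarray:
    """Time derivative of the state vector ``[B_At, B_Ct, C, R, N]``.

    Negative inputs (adaptive solvers probe slightly outside the domain) are
    clipped to 0 before evaluating, keeping the vector field consistent with
    the non-negative model domain.
    """
    B1, B2, C, R, N = np.clip(y, 0.0, None)
    ab_eff = spec.effective_abiotic(ab)
    use_n = spec.include_mm_nutrient

    dB = np.empty(2)
    dC = 0.0
    dN = 0.0
    dR = 0.0
    for i, (B, p) in enumerate(((B1, p_At), (B2, p_Ct))):
        growth, dC_i, dN_i = _growth_and_uptake(B, C, N, p, use_n)
        if spec.family == "model1":
            gamma = 0.0 if spec.no_toxicity_accumulation else p.gamma
            death = (p.beta + gamma * t) * C * B
        else:
            death = p.beta * R * B
            dR -= p.alpha * B * R
        dB[i] = growth - death
        dC += dC_i
        dN += dN_i

    if spec.family == "model2":
        gen = (ab_eff.d + ab_eff.e * R) * C
        dR += gen - ab_eff.l * R
        if gen > 0.0:
            if ab_eff.m <= 0:
                raise DomainError("m = 0 with d + e > 0: ROS-coupled LA consumption undefined")
            dC -= gen / ab_eff.m

    return np.array([dB[0], dB[1], dC, dR, dN])


def _rhs_state(state, p_At, p_Ct, spec, ab, t=None):
    # derivatives may legitimately be negative, so return a plain dict
    # rather than a CultureState (which enforces non-negativity)
    tt = state.t if t is None else t
    dy = rhs_vector(tt, state.to_vector(), p_At, p_Ct, spec, ab)
    return dict(zip(STATE_VARS, dy))


def rhs_model1(
    state: CultureState,
    p_At: SpeciesParams,
    p_Ct: SpeciesParams,
    t: float | None = None,
    spec: ModelSpec | None = None,
) -> dict:
    """Model-1 time derivative of each state variable, as a dict.

    Mono-cultures are obtained by setting the absent species' abundance to 0.
    ``dR/dt`` is identically 0 in this family.
    """
    spec = spec or ModelSpec(family="model1")
    if spec.family != "model1":
        raise ValueError("rhs_model1 requires a model1 spec")
    return _rhs_state(state, p_At, p_Ct, spec, None, t)


def rhs_model2(
    state: CultureState,
    p_At: SpeciesParams,
    p_Ct: SpeciesParams,
    ab: AbioticRosParams,
    spec: ModelSpec | None = None,
) -> dict:
    """Model-2 time derivative of each state variable, as a dict.

    Setting both abundances to 0 gives the cell-free LA/ROS system used to
    pre-fit the abiotic constants.
    """
    spec = spec or ModelSpec(family="model2")
    if spec.family != "model2":
        raise ValueError("rhs_model2 requires a model2 spec")
    return _rhs_state(state, p_At, p_Ct, spec, ab)
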