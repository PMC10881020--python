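"""Synthetic datasets with the statistical structure of the co-culture study.

Every generator integrates the chosen ODE model (the "truth"), samples it on
the experimental design grid, and applies a measurement-noise model:

* CFU plate counts get multiplicative lognormal noise (dilution-series
  pipetting dominates counting error at 1e5-1e10 CFU/ml), left-censored at
  the detection limit;
* the MDA-TBA2 absorbance proxy for ROS gets additive Gaussian noise;
* calibration standards are a linear mean response plus Gaussian noise.

Identical seeds give identical datasets.  The tidy output schemas match
what the fitting and assay modules read (see :mod:`crtox.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model_core import CultureState, ModelSpec, SpeciesParams
from .simulate import integrate_batch
from .reference import INOCULUM, LA_CONCENTRATIONS, MM_NUTRIENT_N0, mm_nutrient_channel

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "CompoundProfile",
    "generate_growth_curves",
    "generate_ros_curves",
    "generate_calibration_standards",
    "generate_compound_screen",
    "MDA_STANDARDS_UM",
]

#: MDA-TBA2 standard concentrations (μM) used for the TBARS calibration curve.
MDA_STANDARDS_UM = (0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied to the noiseless model trajectories."""

    cfu_cv: float = 0.3            # lognormal coefficient of variation on counts
    detection_limit: float = 1e2   # CFU/ml; lower values are censored to this
    ros_sd: float = 0.01           # additive Gaussian sd on the MDA proxy (au)
    seed: int = 0

    def __post_init__(self):
        if self.cfu_cv < 0:
            raise ValueError("cfu_cv must be >= 0")
        if self.detection_limit <= 0:
            raise ValueError("detection_limit must be > 0")
        if self.ros_sd < 0:
            raise ValueError("ros_sd must be >= 0")

    @property
    def log_sigma(self) -> float:
        """Lognormal shape parameter giving the requested CV with mean 1."""
        return float(np.sqrt(np.log1p(self.cfu_cv ** 2)))

    def with_(self, **kw) -> "NoiseModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of the growth-curve experiments."""

    concentrations: tuple = LA_CONCENTRATIONS
    times: tuple = tuple(np.arange(0.0, 193.0, 24.0))  # daily, 8 days
    replicates: int = 3
    inoculum: float = INOCULUM
    culture_types: tuple = ("mono_At", "mono_Ct", "co", "cell_free")

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if list(self.times) != sorted(self.times):
            raise ValueError("sampling times must be sorted")

    def with_(self, **kw) -> "ExperimentDesign":
        return replace(self, **kw)


def _initial_state(culture: str, c0: float, inoculum: float, N0: float) -> CultureState:
    b_at = inoculum if culture in ("mono_At", "co") else 0.0
    b_ct = inoculum if culture in ("mono_Ct", "co") else 0.0
    return CultureState(B_At=b_at, B_Ct=b_ct, C=c0, N=N0)


def _truth_trajectories(params, spec, design, N0=0.0, rtol=1e-8):
    """Noiseless trajectory per (culture_type, concentration)."""
    t_grid = np.asarray(design.times, dtype=float)
    if t_grid[0] != 0.0:
        t_grid = np.concatenate([[0.0], t_grid])
    out = {}
    for culture in design.culture_types:
        for c0 in design.concentrations:
            state0 = _initial_state(culture, float(c0), design.inoculum, N0)
            out[(culture, float(c0))] = integrate_batch(
                state0, params["At"], params["Ct"], spec, t_grid,
                ab=params.get("abiotic"), rtol=rtol,
            )
    return out


def _lognoise(rng, values, noise: NoiseModel):
    if noise.cfu_cv == 0:
        return np.asarray(values, dtype=float)
    s = noise.log_sigma
    return values * rng.lognormal(-s ** 2 / 2.0, s, size=np.shape(values))


def generate_growth_curves(
    params: dict,
    spec: ModelSpec,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
    compound: str = "LA",
    N0: float = 0.0,
) -> pd.DataFrame:
    """Replicate CFU growth curves for every culture type and LA level.

    ``params`` maps ``"At"``/``"Ct"`` to :class:`SpeciesParams` (plus
    ``"abiotic"`` for model 2).  Counts below the detection limit are
    reported at the limit (left-censoring, as on a plate with too few
    colonies).  Cell-free conditions contribute no CFU rows.
    """
    design = design or ExperimentDesign()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    times = np.asarray(design.times, dtype=float)
    rows = []
    for (culture, c0), traj in _truth_trajectories(params, spec, design, N0).items():
        if culture == "cell_free":
            continue
        states = traj.at(times)
        for species, col in (("At", 0), ("Ct", 1)):
            if culture == f"mono_{'Ct' if species == 'At' else 'At'}":
                continue
            truth = states[:, col]
            ctype = "co" if culture == "co" else "mono"
            for rep in range(1, design.replicates + 1):
                obs = np.maximum(_lognoise(rng, truth, noise), noise.detection_limit)
                for t, v in zip(times, obs):
                    rows.append({
                        "species": species, "culture_type": ctype,
                        "compound": compound, "concentration_au": c0,
                        "replicate": rep, "time_h": t, "cfu_per_ml": v,
                    })
    return pd.DataFrame(rows)


def generate_ros_curves(
    params: dict,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
    compound: str = "LA",
) -> pd.DataFrame:
    """Replicate MDA-proxy (ROS) time series, including cell-free medium.

    Model 2 only.  The cell-free series rises towards the abiotic plateau
    ``R* = d*C/(l - e*C)``; cultures containing the detoxifier stay below
    it.  Additive Gaussian noise, clipped at 0.
    """
    design = design or ExperimentDesign()
    noise = noise or NoiseModel()
    spec = ModelSpec(family="model2")
    rng = np.random.default_rng(noise.seed + 1)  # decouple from CFU noise stream
    times = np.asarray(design.times, dtype=float)
    rows = []
    for (culture, c0), traj in _truth_trajectories(params, spec, design).items():
        truth = traj.at(times)[:, 3]
        for rep in range(1, design.replicates + 1):
            obs = truth + rng.normal(0.0, noise.ros_sd, size=truth.size) \
                if noise.ros_sd > 0 else truth.copy()
            obs = np.maximum(obs, 0.0)
            for t, v in zip(times, obs):
                rows.append({
                    "culture_type": culture, "compound": compound,
                    "concentration_au": c0, "replicate": rep,
                    "time_h": t, "ros_au": v,
                })
    return pd.DataFrame(rows)


def generate_calibration_standards(
    concentrations=MDA_STANDARDS_UM,
    slope: float = 0.01,
    intercept: float = 0.05,
    noise_sd: float = 0.005,
    seed: int = 0,
    replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate absorbances for the MDA-TBA2 standard series.

    Linear mean response ``A = intercept + slope*conc`` (532 nm absorbance
    per μM) with Gaussian noise; the 0 μM standard is the blank.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for conc in concentrations:
        for rep in range(1, replicates + 1):
            a = intercept + slope * conc
            if noise_sd > 0:
                a += rng.normal(0.0, noise_sd)
            rows.append({"concentration_um": float(conc), "replicate": rep,
                         "absorbance": max(a, 0.0)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CompoundProfile:
    """How one screened compound affects each species (model-1 terms).

    ``r``/``K``/``Y`` describe growth on the compound as a carbon source
    (0 = not consumable); ``beta``/``gamma`` its direct toxicity.  Residual
    growth on the minimal medium itself is always present, so a pure toxin
    still shows control-level growth at concentration 0.
    """

    name: str
    species: dict = field(default_factory=dict)  # species -> SpeciesParams

    @classmethod
    def null(cls, name: str = "inert") -> "CompoundProfile":
        p = SpeciesParams(r=0.0, K=1.0, Y=1.0)
        return cls(name, {"At": p, "Ct": p})

    @classmethod
    def toxin(cls, name: str = "toxin", beta: float = 0.3) -> "CompoundProfile":
        p = SpeciesParams(r=0.0, K=1.0, Y=1.0, beta=beta)
        return cls(name, {"At": p, "Ct": p})

    @classmethod
    def nutrient_toxin(cls, name: str = "LA_like") -> "CompoundProfile":
        """LA-like: consumable at low doses, increasingly toxic at high."""
        at = SpeciesParams(r=0.2, K=0.05, Y=4e9, beta=0.04, gamma=0.012)
        ct = SpeciesParams(r=0.14, K=0.01, Y=1e10)
        return cls(name, {"At": at, "Ct": ct})


def generate_compound_screen(
    profiles,
    concentrations=LA_CONCENTRATIONS,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Mono-culture growth curves for a compound screen, with MM controls.

    For each :class:`CompoundProfile`, both species are grown alone at a
    control (0) plus each tested concentration; every culture also carries
    the minimal-medium nutrient channel (N0 = 0.01 au), so controls grow to
    the MM plateau.  Output matches the growth-curve schema, with the
    control rows labelled ``compound="MM"``.
    """
    design = design or ExperimentDesign()
    noise = noise or NoiseModel()
    spec = ModelSpec(family="model1", include_mm_nutrient=True)
    frames = []
    # one shared carbon-free control per species (dynamics are profile-independent)
    inert = mm_nutrient_channel(SpeciesParams(r=0.0, K=1.0, Y=1.0))
    for j, species in enumerate(("At", "Ct")):
        sub = design.with_(concentrations=(0.0,), culture_types=(f"mono_{species}",))
        frames.append(generate_growth_curves(
            {"At": inert, "Ct": inert}, spec, sub,
            noise.with_(seed=noise.seed + 900_000 + j),
            compound="MM", N0=MM_NUTRIENT_N0))
    for k, profile in enumerate(profiles):
        pars = {sp: mm_nutrient_channel(p) for sp, p in profile.species.items()}
        for species in ("At", "Ct"):
            if species not in pars:
                continue
            params = {"At": pars.get("At", pars[species]), "Ct": pars.get("Ct", pars[species])}
            sub = design.with_(concentrations=tuple(concentrations),
                               culture_types=(f"mono_{species}",))
            frames.append(generate_growth_curves(
                params, spec, sub,
                noise.with_(seed=noise.seed + 1000 * (k + 1) + (species == "Ct")),
                compound=profile.name, N0=MM_NUTRIENT_N0))
    return pd.concat(frames, ignore_index=True)
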