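"""Tidy CSV schemas, parameter serialisation, and run configuration.

All concentrations are stored in arbitrary units (au) with the convention
1 au = 1 % v/v LA; each CSV carries that convention in a leading ``#``
comment line.  Schema violations raise :class:`SchemaError` naming the
offending column or key.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model_core import AbioticRosParams, ModelSpec, SpeciesParams
from .simulate import TransferProtocol

__all__ = [
    "SchemaError",
    "GROWTH_COLUMNS",
    "ROS_COLUMNS",
    "read_growth_csv",
    "write_growth_csv",
    "read_ros_csv",
    "write_ros_csv",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
    "RunConfig",
]

UNIT_COMMENT = "# concentrations in au; 1 au = 1 % v/v linoleic acid; time in hours"

GROWTH_COLUMNS = ("species", "culture_type", "compound", "concentration_au",
                  "replicate", "time_h", "cfu_per_ml")
ROS_COLUMNS = ("culture_type", "compound", "concentration_au",
               "replicate", "time_h", "ros_au")

_GROWTH_KEY = ("species", "culture_type", "compound", "concentration_au",
               "replicate", "time_h")
_ROS_KEY = ("culture_type", "compound", "concentration_au", "replicate", "time_h")
_CULTURE_TYPES = {"mono", "co", "cell_free", "mono_At", "mono_Ct"}


class SchemaError(ValueError):
    """A dataset file violates the tidy schema; the message names the issue."""


def _validate(df: pd.DataFrame, columns, key, value_col: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return df
    bad_ct = set(df["culture_type"].unique()) - _CULTURE_TYPES
    if bad_ct:
        raise SchemaError(f"unknown culture_type value(s): {sorted(bad_ct)}")
    for col in (value_col, "concentration_au", "time_h"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise SchemaError(f"non-numeric value(s) in column {col!r}")
        if (vals < 0).any():
            raise SchemaError(f"negative value(s) in column {col!r}")
    dup = df.duplicated(subset=list(key))
    if dup.any():
        first = df[dup].iloc[0]
        raise SchemaError(
            "duplicate (condition, replicate, time) key, first at "
            + ", ".join(f"{k}={first[k]!r}" for k in key)
        )
    return df


def _read_csv(path, columns, key, value_col):
    df = pd.read_csv(path, comment="#")
    if df.empty and not df.columns.size:
        raise SchemaError(f"{path}: empty file without header")
    return _validate(df, columns, key, value_col)


def _write_csv(df, path, columns, key, value_col):
    _validate(df, columns, key, value_col)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(UNIT_COMMENT + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_growth_csv(path) -> pd.DataFrame:
    """Read a tidy CFU growth-curve CSV, validating the schema."""
    return _read_csv(path, GROWTH_COLUMNS, _GROWTH_KEY, "cfu_per_ml")


def write_growth_csv(df: pd.DataFrame, path) -> None:
    """Write a tidy CFU growth-curve CSV (round-trips with the reader)."""
    _write_csv(df, path, GROWTH_COLUMNS, _GROWTH_KEY, "cfu_per_ml")


def read_ros_csv(path) -> pd.DataFrame:
    """Read a tidy ROS-proxy CSV, validating the schema."""
    return _read_csv(path, ROS_COLUMNS, _ROS_KEY, "ros_au")


def write_ros_csv(df: pd.DataFrame, path) -> None:
    """Write a tidy ROS-proxy CSV."""
    _write_csv(df, path, ROS_COLUMNS, _ROS_KEY, "ros_au")


# ---------------------------------------------------------------------------
# parameter serialisation: flat key-value maps grouped by species / section


def _plain(d: dict) -> dict:
    """Cast numpy scalars to plain Python types for clean YAML."""
    return {k: float(v) if isinstance(v, (int, float, np.floating)) else v
            for k, v in d.items()}


def params_to_dict(species: dict[str, SpeciesParams],
                   abiotic: AbioticRosParams | None = None,
                   spec: ModelSpec | None = None) -> dict:
    out: dict = {"species": {name: _plain(asdict(p)) for name, p in species.items()}}
    if abiotic is not None:
        out["abiotic"] = _plain(asdict(abiotic))
    if spec is not None:
        out["model"] = asdict(spec)
    return out


def params_from_dict(d: dict):
    """Inverse of :func:`params_to_dict`; returns (species, abiotic, spec)."""
    try:
        species = {name: SpeciesParams(**vals) for name, vals in d["species"].items()}
    except KeyError as e:
        raise SchemaError(f"parameter file missing key {e}") from None
    except TypeError as e:
        raise SchemaError(f"bad species parameter entry: {e}") from None
    abiotic = AbioticRosParams(**d["abiotic"]) if "abiotic" in d else None
    spec = ModelSpec(**d["model"]) if "model" in d else None
    return species, abiotic, spec


def save_params(path, species, abiotic=None, spec=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params_to_dict(species, abiotic, spec), fh, sort_keys=True)


def load_params(path):
    with open(path, encoding="utf-8") as fh:
        return params_from_dict(yaml.safe_load(fh))


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end pipeline run."""

    family: str = "model2"
    seed: int = 0
    outdir: str = "crtox_run"
    cfu_cv: float = 0.3
    ros_sd: float = 0.01
    n_starts: int = 20
    n_polish: int = 6
    fit_concentrations: tuple = (0.1, 0.75)
    sweep_C0: tuple = (0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1.0)
    sweep_D: tuple = (30.0, 100.0, 300.0, 1000.0)
    horizon: int = 5
    protocol: dict = field(default_factory=dict)  # TransferProtocol overrides
    log_level: str = "INFO"

    def transfer_protocol(self, **overrides) -> TransferProtocol:
        return TransferProtocol(**{**self.protocol, **overrides})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        for k in ("fit_concentrations", "sweep_C0", "sweep_D"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)
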