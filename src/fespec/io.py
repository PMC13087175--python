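"""Readers/writers, unit handling and run configuration.

Input tables are delimited text (comma-separated, UTF-8, "." decimal) with
one row per sample.  A ``ColumnMapping`` associates canonical field names
(see ``transect.CANONICAL_COLUMNS``) with input headers and unit strings;
per-kg concentrations are converted to per-litre with in-situ density
(surface-pressure EOS-80).  Below-detection entries (``<x`` strings) become
0 for siderophores — undetectable siderophores do not bind Fe — and missing
for every other field.  Everything is mol L-1 internally; nmol/pmol at the
I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .thermo import ConfigError
from .transect import CANONICAL_COLUMNS

__all__ = [
    "ColumnMapping",
    "RunConfig",
    "seawater_density",
    "read_samples",
    "write_samples",
    "load_run_config",
    "setup_logging",
]

log = logging.getLogger("fespec")

#: unit -> (scale to the canonical per-litre unit, needs density)
_UNIT_FACTORS = {
    "nmol/L": (1.0, False),
    "nmol/kg": (1.0, True),
    "pmol/L": (1.0, False),
    "pmol/kg": (1.0, True),
    "umol/L": (1.0, False),
    "umol/kg": (1.0, True),
    "nmol/m3": (1e-3, False),
}

_REQUIRED = ("station", "lon", "lat", "depth", "temp", "sal", "ph_total",
             "doc", "tpp", "dfe", "lpfe")


@dataclass
class ColumnMapping:
    """canonical field -> (input header, unit string or '' for canonical)."""

    columns: dict = field(default_factory=dict)

    @classmethod
    def identity(cls) -> "ColumnMapping":
        return cls({k: (k, "") for k in CANONICAL_COLUMNS})

    @classmethod
    def from_yaml(cls, path) -> "ColumnMapping":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cols = {}
        for canon, spec in raw.items():
            if canon not in CANONICAL_COLUMNS:
                raise ConfigError(f"mapping: unknown canonical field {canon!r}")
            if isinstance(spec, str):
                cols[canon] = (spec, "")
            else:
                cols[canon] = (str(spec["column"]), str(spec.get("unit", "")))
        return cls(cols)


def seawater_density(S, T) -> np.ndarray:
    """Seawater density at surface pressure (kg L-1), EOS-80 polynomial."""
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    rw = (999.842594 + 6.793952e-2 * T - 9.095290e-3 * T ** 2
          + 1.001685e-4 * T ** 3 - 1.120083e-6 * T ** 4 + 6.536332e-9 * T ** 5)
    A = (8.24493e-1 - 4.0899e-3 * T + 7.6438e-5 * T ** 2
         - 8.2467e-7 * T ** 3 + 5.3875e-9 * T ** 4)
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T ** 2
    C = 4.8314e-4
    return (rw + A * S + B * S ** 1.5 + C * S * S) / 1000.0


def _parse_value(raw, below_detection_zero: bool) -> float:
    if isinstance(raw, str):
        s = raw.strip()
        if not s or s.lower() in ("na", "nan", "nd"):
            return np.nan
        if s.startswith("<"):
            return 0.0 if below_detection_zero else np.nan
        return float(s)
    return float(raw) if raw is not None else np.nan


def read_samples(
    path,
    mapping: ColumnMapping | None = None,
    depth_min: float | None = 250.0,
) -> pd.DataFrame:
    """Read, unit-normalize and validate a per-sample observation table.

    ``depth_min`` applies the analysis depth filter at read time (the study
    domain is > 250 m); pass ``None`` to keep all depths.
    """
    mapping = mapping or ColumnMapping.identity()
    raw = pd.read_csv(path, dtype=str, comment="#")
    if raw.empty:
        raise ValueError(f"{path}: empty sample table")
    missing = [
        c for c in _REQUIRED
        if c in mapping.columns and mapping.columns[c][0] not in raw.columns
    ]
    if missing:
        canon = ", ".join(missing)
        raise ValueError(f"{path}: missing required columns for fields: {canon}")
    out = pd.DataFrame()
    for canon, (header, unit) in mapping.columns.items():
        if header not in raw.columns:
            continue
        if canon == "station":
            out[canon] = raw[header].astype(str)
            continue
        bd_zero = canon == "siderophore"
        vals = np.array([_parse_value(v, bd_zero) for v in raw[header]])
        out[canon] = vals
        if unit:
            out.attrs.setdefault("units", {})[canon] = unit
    # unit conversion (needs temp/sal for density)
    for canon, (header, unit) in mapping.columns.items():
        if not unit or canon not in out:
            continue
        if unit == CANONICAL_COLUMNS[canon][1].replace("umol kg-1", "umol/kg"):
            continue
        if unit not in _UNIT_FACTORS:
            raise ValueError(f"field {canon!r}: unsupported unit {unit!r}")
        scale, per_kg = _UNIT_FACTORS[unit]
        v = out[canon].values * scale
        if per_kg and canon != "oxygen":  # oxygen is canonically per kg
            v = v * seawater_density(out["sal"].values, out["temp"].values)
        out[canon] = v
    if "siderophore" in out:
        out["siderophore"] = out["siderophore"].fillna(0.0)
    if depth_min is not None:
        out = out[out["depth"] > depth_min].reset_index(drop=True)
    log.info("read %d samples from %s", len(out), path)
    return out


def write_samples(df: pd.DataFrame, path) -> None:
    """Write a tidy sample/result table as CSV (UTF-8, '.' decimal)."""
    df.to_csv(path, index=False)
    log.info("wrote %d rows to %s", len(df), path)


@dataclass
class RunConfig:
    """Paths, pathway selection, presets and the seed for one pipeline run."""

    input_table: str = ""
    thermo_config: str = ""
    phase_config: str = ""
    endmember_table: str = ""
    output_dir: str = "."
    pathways: tuple = ("p1", "p2", "p3", "p4")
    inlier_preset: str = "data"
    activity_model: str = "davies"
    seed: int = 0
    verbosity: str = "INFO"

    _KNOWN = (
        "input_table", "thermo_config", "phase_config", "endmember_table",
        "output_dir", "pathways", "inlier_preset", "activity_model",
        "seed", "verbosity",
    )


def load_run_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(RunConfig._KNOWN)
    if unknown:
        raise ConfigError(f"run config: unknown keys {sorted(unknown)}")
    cfg = RunConfig(**{k: raw[k] for k in raw})
    if isinstance(cfg.pathways, (list, tuple)):
        cfg.pathways = tuple(cfg.pathways)
    for key in ("input_table", "thermo_config", "phase_config", "endmember_table"):
        p = getattr(cfg, key)
        if p and not Path(p).exists():
            raise ConfigError(f"run config: {key} path {p!r} does not exist")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
    )
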