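"""Extended optimum multiparameter analysis (eOMPA).

Decomposes each sample's hydrographic/nutrient signature into non-negative
water-mass endmember fractions summing to one, plus a remineralisation
extent dP (umol kg-1 of phosphate equivalent) acting through a Redfield
stoichiometry vector.  The observation model per parameter row is::

    obs = E x + r dP,   x >= 0,  sum(x) = 1

with E the endmember matrix and r the Redfield vector
(0 T, 0 S, -170 O2, +1 PO4, +16 NO3+NO2, +40 SiO4 by default).

Each parameter row is standardized by the spread of the endmember matrix and
weighted; the mass-conservation row is weighted 100x the tracer rows.  The
constrained least-squares problem is solved with non-negative least squares,
splitting dP into positive and negative parts so its sign is free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "PARAMETERS",
    "REDFIELD",
    "WaterMassEndmember",
    "MixingSolution",
    "load_endmembers",
    "default_endmembers",
    "solve_mixing",
    "correlate_tracer_with_fractions",
]

PARAMETERS = ("T", "S", "O2", "PO4", "NO3NO2", "SiO4")
REDFIELD = np.array([0.0, 0.0, -170.0, 1.0, 16.0, 40.0])
MASS_ROW_WEIGHT = 100.0


@dataclass
class WaterMassEndmember:
    """Source-water properties of one water mass."""

    name: str
    values: dict  # parameter -> value, canonical units (degC, psu, umol kg-1)


@dataclass
class MixingSolution:
    """Solved mixing fractions and remineralisation extent for one sample."""

    fractions: dict  # water mass -> fraction
    delta_p: float  # umol kg-1 phosphate-equivalent remineralisation
    residual_norm: float  # weighted residual over tracer rows

    @property
    def fraction_vector(self) -> np.ndarray:
        return np.array(list(self.fractions.values()))


def load_endmembers(path) -> list[WaterMassEndmember]:
    """Read a water-mass x parameter table (CSV with a ``water_mass`` column)."""
    df = pd.read_csv(path)
    missing = [p for p in PARAMETERS if p not in df.columns]
    if missing:
        raise ValueError(f"endmember table missing parameter columns {missing}")
    return [
        WaterMassEndmember(
            name=str(row["water_mass"]),
            values={p: float(row[p]) for p in PARAMETERS},
        )
        for _, row in df.iterrows()
    ]


def default_endmembers() -> list[WaterMassEndmember]:
    """Bundled synthetic endmember table for the six subsurface water masses.

    Representative values for ESSW, SAMW, AAIW, UCDW, PDW and LCDW
    constructed for testing; a study endmember table in the same layout
    replaces it.
    """
    with resources.as_file(
        resources.files("fespec.data").joinpath("endmembers_synthetic.csv")
    ) as p:
        return load_endmembers(p)


def solve_mixing(
    sample: dict,
    endmembers: list[WaterMassEndmember],
    redfield: np.ndarray | None = None,
    weights: dict | None = None,
) -> MixingSolution:
    """Solve non-negative, mass-conserving mixing for one sample.

    ``sample`` maps parameter names to observed values.  ``weights`` are
    per-parameter (default 1); standardization by the endmember-matrix spread
    makes the weighting scale-free, so multiplying a weight while dividing
    the corresponding uncertainty leaves the solution unchanged.
    """
    if len(endmembers) < 2:
        raise ValueError("need at least 2 endmembers")
    r = REDFIELD if redfield is None else np.asarray(redfield, dtype=float)
    w = np.array([(weights or {}).get(p, 1.0) for p in PARAMETERS])
    E = np.array([[em.values[p] for em in endmembers] for p in PARAMETERS])
    b = np.array([float(sample[p]) for p in PARAMETERS])
    scale = E.std(axis=1)
    scale[scale == 0] = 1.0
    center = E.mean(axis=1)
    # standardized, weighted rows; sum(x)=1 lets the centering cancel
    Ez = (E - center[:, None]) / scale[:, None] * w[:, None]
    bz = (b - center) / scale * w
    rz = r / scale * w
    k = len(endmembers)
    # variables: k fractions, dP+ and dP-
    A = np.hstack([Ez, rz[:, None], -rz[:, None]])
    mass = np.concatenate([np.full(k, MASS_ROW_WEIGHT * w.mean()), [0.0, 0.0]])
    A_aug = np.vstack([A, mass])
    b_aug = np.concatenate([bz, [MASS_ROW_WEIGHT * w.mean()]])
    x, _ = nnls(A_aug, b_aug, maxiter=10 * A_aug.shape[1] * 50)
    fractions = x[:k]
    ssum = fractions.sum()
    if ssum <= 0:
        raise ValueError("degenerate mixing system: all fractions zero")
    delta_p = float(x[k] - x[k + 1])
    resid = A @ x - bz
    return MixingSolution(
        fractions={em.name: float(f) for em, f in zip(endmembers, fractions)},
        delta_p=delta_p,
        residual_norm=float(np.linalg.norm(resid)),
    )


def correlate_tracer_with_fractions(
    tracer, solutions: list[MixingSolution]
) -> pd.DataFrame:
    """Pearson r and two-sided p of a tracer against each water-mass fraction.

    Constant fraction vectors yield NaN with a flag.  Returns a table indexed
    by water mass with columns r, p, n, constant.
    """
    tracer = np.asarray(tracer, dtype=float)
    if len(tracer) != len(solutions):
        raise ValueError("tracer and solutions length mismatch")
    names = list(solutions[0].fractions)
    rows = []
    for name in names:
        f = np.array([s.fractions[name] for s in solutions])
        ok = np.isfinite(tracer) & np.isfinite(f)
        if ok.sum() < 3 or np.ptp(f[ok]) == 0 or np.ptp(tracer[ok]) == 0:
            rows.append((name, np.nan, np.nan, int(ok.sum()), True))
            continue
        r, p = stats.pearsonr(tracer[ok], f[ok])
        rows.append((name, float(r), float(p), int(ok.sum()), False))
    return pd.DataFrame(
        rows, columns=["water_mass", "r", "p", "n", "constant"]
    ).set_index("water_mass")
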