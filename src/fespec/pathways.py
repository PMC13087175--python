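"""Pathway combinations and the headline partitioning quantities.

Four thermodynamically defined pathways compete for inorganic Fe:

* ``p1`` — reversible binding to heterogeneous DOM (NICA-Donnan),
* ``p2`` — reversible binding to siderophores (ferrioxamine B proxy),
* ``p3`` — precipitation of authigenic ferric hydroxide (authFeOH),
* ``p4`` — reversible binding to particulate organic matter (NICA-Donnan).

With only ``p1``-``p3`` active, the total-Fe boundary condition is the
observed dissolved Fe (DFe_obs); including ``p4`` switches it to the total
labile pool TLFe_obs = DFe_obs + LPFe_obs and makes no prior assumption about
the dissolved/particulate split.  Predicted partitioning:
``DFe_pred = Fe' + FeDOM + FeSid`` and ``LPFe_pred = authFeOH + FePOM``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import nica, thermo
from .engine import SpeciationProblem, SpeciationResult, solve_equilibrium

__all__ = [
    "PathwayConfig",
    "PartitionPrediction",
    "run_pathways",
    "fe_to_c_ratio",
    "residence_time_ratio",
    "ALL_PATHWAYS",
]

ALL_PATHWAYS = frozenset({"p1", "p2", "p3", "p4"})
C_MOLAR_MASS = 12.011  # g mol-1


@dataclass(frozen=True)
class PathwayConfig:
    """Which pathways are active; fixes the total-Fe boundary condition."""

    include: frozenset = frozenset({"p1", "p2", "p3", "p4"})

    def __post_init__(self):
        unknown = set(self.include) - ALL_PATHWAYS
        if unknown:
            raise ValueError(f"unknown pathways {sorted(unknown)}")

    @property
    def total_fe_source(self) -> str:
        return "TLFe_obs" if "p4" in self.include else "DFe_obs"

    @property
    def fingerprint(self) -> str:
        return "+".join(sorted(self.include))


@dataclass
class PartitionPrediction:
    """Predicted dissolved/labile-particulate Fe split for one sample."""

    dfe_pred: float  # mol L-1: Fe' + FeDOM + FeSid
    lpfe_pred: float  # mol L-1: authFeOH + FePOM
    result: SpeciationResult
    total_fe: float
    config: PathwayConfig
    fec_dom: float = float("nan")  # umol Fe (mol C)-1
    fec_pom: float = float("nan")


@dataclass
class SampleConditions:
    """Per-sample inputs required by the active pathways (canonical units)."""

    dfe_obs: float  # mol L-1
    lpfe_obs: float = 0.0  # mol L-1
    pH_total: float = 7.9
    T: float = 4.0
    S: float = 34.6
    dom_mass: float = 0.0  # kg L-1
    pom_mass: float = 0.0  # kg L-1
    siderophore_total: float = 0.0  # mol L-1
    doc: float = float("nan")  # umol L-1, for Fe:C
    poc: float = float("nan")  # umol L-1, for Fe:C


def run_pathways(
    sample: SampleConditions,
    config: PathwayConfig,
    phases: dict | None = None,
    dataset: thermo.ThermoDataset | None = None,
    warm_start: tuple | None = None,
    compute_affinity: bool = False,
) -> PartitionPrediction:
    """Build and solve the speciation problem for one sample and pathway set.

    Siderophore concentrations below detection enter as zero, matching the
    interpolated-field construction upstream.  Missing required fields raise
    ``ValueError`` naming the pathway (callers turn this into a per-sample
    error record).
    """
    inc = config.include
    phases = phases if phases is not None else nica.default_phases()
    if "p1" in inc and not math.isfinite(sample.dom_mass):
        raise ValueError("pathway p1 requires a DOM mass (DOC observation)")
    if "p4" in inc and not math.isfinite(sample.pom_mass):
        raise ValueError("pathway p4 requires a POM mass (TPP observation)")
    if "p2" in inc and not math.isfinite(sample.siderophore_total):
        raise ValueError("pathway p2 requires a siderophore concentration")

    total = sample.dfe_obs + (sample.lpfe_obs if "p4" in inc else 0.0)
    dom = phases["dom"].with_mass(sample.dom_mass) if "p1" in inc else None
    pom = phases["pom"].with_mass(sample.pom_mass) if "p4" in inc else None
    sid = (
        phases["siderophore"].with_total(sample.siderophore_total)
        if "p2" in inc
        else None
    )
    problem = SpeciationProblem(
        total_fe=total,
        pH_total=sample.pH_total,
        T=sample.T,
        S=sample.S,
        dom=dom,
        pom=pom,
        siderophore=sid,
        allow_mineral="p3" in inc,
        dataset=dataset,
        compute_affinity=compute_affinity,
    )
    res = solve_equilibrium(problem, warm_start=warm_start)
    pred = PartitionPrediction(
        dfe_pred=res.fe_prime + res.fe_dom + res.fe_sid,
        lpfe_pred=res.auth_feoh + res.fe_pom,
        result=res,
        total_fe=total,
        config=config,
    )
    if math.isfinite(sample.doc) and sample.doc > 0:
        pred.fec_dom = fe_to_c_ratio(res.fe_dom, sample.doc * 1e-6)
    if math.isfinite(sample.poc) and sample.poc > 0:
        pred.fec_pom = fe_to_c_ratio(res.fe_pom, sample.poc * 1e-6)
    return pred


def fe_to_c_ratio(bound_fe: float, organic_c: float) -> float:
    """Fe:C ratio in umol Fe per mol C, from mol L-1 inputs."""
    if organic_c == 0.0:
        return float("nan")
    if organic_c < 0:
        raise ValueError("organic carbon concentration must be >= 0")
    return 1e6 * bound_fe / organic_c


def residence_time_ratio(c_dfe: float, c_lpfe: float) -> float:
    """Scavenging residence-time ratio tau_LPFe / tau_Part = 1 + DFe/LPFe.

    At equilibrium the residence time of labile particulate Fe exceeds that
    of the particles themselves by the dissolved:particulate partitioning
    factor; any consistent concentration unit works.
    """
    if c_lpfe == 0.0:
        return math.inf
    return 1.0 + c_dfe / c_lpfe
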