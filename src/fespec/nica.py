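"""Heterogeneous organic Fe binding: NICA-Donnan phases and discrete ligands.

Dissolved and particulate organic matter (DOM, POM) are each represented as a
NICA-Donnan phase: a bimodal distribution of binding-site affinities (two site
groups, each a quasi-Gaussian Sips distribution of width ``p``) with
ion-specific non-ideality exponents ``n_i``, coupled to a Donnan gel phase
whose electrostatic potential concentrates counter-ions.  Siderophores are a
discrete, dissolved high-affinity ligand proxied by ferrioxamine B.

The NICA isotherm for ion ``i`` on group ``g``::

    theta_i = (K_i c_i)^n_i / S  *  S^p / (1 + S^p),   S = sum_j (K_j c_j)^n_j
    bound_i = (n_i / n_H) Qmax theta_i

with ``c_j`` the *local* (Donnan-phase) free concentrations ``c_bulk chi^z``.

The module also builds the conditional affinity spectrum of occupied Fe sites.
NICA is exactly the integral of a local multicomponent isotherm over a Sips
density in a common heterogeneity coordinate; the occupation-weighted mean of
log10 K over that density is the reported effective affinity K'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .thermo import R_GAS, SeawaterComposition, ConfigError

__all__ = [
    "NicaSiteGroup",
    "NicaDonnanPhase",
    "DonnanState",
    "DiscreteLigand",
    "AffinityReport",
    "nica_bound_amount",
    "donnan_volume",
    "solve_donnan_potential",
    "siderophore_speciation",
    "weighted_mean_occupied_logK",
    "sips_density",
    "load_phases",
    "default_phases",
]

FARADAY = 96485.33212  # C mol-1
V_D_MIN = 5e-4  # L kg-1; numerical safety clip far outside the seawater regime

#: charges of the specifically-binding ions the default parameter sets use
ION_CHARGES = {"H": 1, "Mg": 2, "Ca": 2, "Fe3": 3}


@dataclass(frozen=True)
class NicaSiteGroup:
    """One site group: proton parameters plus per-ion median affinity and n."""

    Qmax: float  # mol sites kg-1
    logK_H: float
    n_H: float
    p: float  # generic heterogeneity (0, 1]
    ions: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    # ions: name -> (logK, n)

    def __post_init__(self):
        # zero-Qmax groups are legal as degenerate limits (e.g. a hypothetical
        # uncharged phase, or padding a single-group construction); the config
        # loader enforces strictly positive site densities for real phases
        if self.Qmax < 0:
            raise ConfigError("site group Qmax must be >= 0")
        if not 0 < self.p <= 1:
            raise ConfigError("site group p must lie in (0, 1]")
        if not 0 < self.n_H <= 1:
            raise ConfigError("site group n_H must lie in (0, 1]")
        for ion, (_, n) in self.ions.items():
            if not 0 < n <= 1:
                raise ConfigError(f"non-ideality n for ion {ion!r} must be in (0, 1]")


@dataclass(frozen=True)
class NicaDonnanPhase:
    """A heterogeneous organic binding phase (DOM or POM)."""

    name: str
    groups: tuple[NicaSiteGroup, NicaSiteGroup]
    donnan_b: float
    mass: float = 0.0  # kg L-1

    def __post_init__(self):
        if len(self.groups) != 2:
            raise ConfigError(f"phase {self.name!r} must have exactly two site groups")
        if self.mass < 0:
            raise ConfigError(f"phase {self.name!r} mass must be >= 0")

    def with_mass(self, mass: float) -> "NicaDonnanPhase":
        return NicaDonnanPhase(self.name, self.groups, self.donnan_b, mass)

    @property
    def Q_total(self) -> float:
        return sum(g.Qmax for g in self.groups)


@dataclass
class DonnanState:
    """Solved Donnan electrostatics: Boltzmann factor, potential, gel volume."""

    chi: float
    psi_D: float  # volts
    V_D: float  # L kg-1


@dataclass
class DiscreteLigand:
    """A dissolved discrete ligand (ferrioxamine-B-like siderophore proxy).

    ``logK_protonation`` are stepwise constants of the fully deprotonated
    ligand; Mg/Ca/Fe bind 1:1 to the deprotonated form.
    """

    name: str
    total: float  # mol L-1
    logK_protonation: Sequence[float]
    logK_Mg: float
    logK_Ca: float
    logK_Fe: float

    def __post_init__(self):
        if self.total < 0:
            raise ConfigError("ligand total must be >= 0")

    def with_total(self, total: float) -> "DiscreteLigand":
        return DiscreteLigand(
            self.name, total, self.logK_protonation,
            self.logK_Mg, self.logK_Ca, self.logK_Fe,
        )


@dataclass
class AffinityReport:
    """Occupation-weighted mean effective Fe affinity and its spectrum."""

    mean_logK: float  # nan when no Fe is bound
    support: np.ndarray  # sampled log10 K grid (both groups concatenated)
    occupied_density: np.ndarray  # d(bound Fe)/d(log10 K) on the support
    per_group_mean: tuple = ()
    per_group_bound: tuple = ()


# ----------------------------------------------------------------------------
# core isotherm


def nica_bound_amount(
    phase: NicaDonnanPhase, local_free: Mapping[str, float]
) -> dict[str, float]:
    """Bound amount (mol kg-1) per ion at the given local free concentrations.

    ``local_free`` must include ``"H"``; all concentrations are Donnan-phase
    values.  Returns the per-ion totals summed over both site groups.  When
    every concentration is zero the binding is zero.
    """
    for ion, c in local_free.items():
        if c < 0:
            raise ValueError(f"negative local concentration for {ion!r}")
    out = {ion: 0.0 for ion in local_free}
    for g in phase.groups:
        params = {"H": (g.logK_H, g.n_H), **g.ions}
        s = {}
        S = 0.0
        for ion, c in local_free.items():
            if ion not in params or c == 0.0:
                continue
            logK, n = params[ion]
            si = math.exp(n * ((logK * math.log(10.0)) + math.log(c)))
            s[ion] = si
            S += si
        if S == 0.0:
            continue
        Sp = S ** g.p
        occ = Sp / (1.0 + Sp)
        for ion, si in s.items():
            n = params[ion][1]
            out[ion] += (n / g.n_H) * g.Qmax * (si / S) * occ
    return out


def donnan_volume(b: float, I: float) -> float:
    """Empirical Donnan gel volume: log10 V_D = b (1 - log10 I) - 1, clipped."""
    if I <= 0:
        raise ValueError("ionic strength must be > 0 for the Donnan volume law")
    return max(10.0 ** (b * (1.0 - math.log10(I)) - 1.0), V_D_MIN)


def phase_charge(
    phase: NicaDonnanPhase, local_free: Mapping[str, float]
) -> float:
    """Net phase charge q (mol charge kg-1): -Q_total + sum_i z_i bound_i."""
    bound = nica_bound_amount(phase, local_free)
    q = -phase.Q_total
    for ion, amt in bound.items():
        q += ION_CHARGES.get(ion, 0) * amt
    return q


def donnan_residual(
    phase: NicaDonnanPhase,
    chi: float,
    bulk_ions: Sequence[tuple[float, int]],
    binding_free: Mapping[str, float],
    V_D: float,
) -> float:
    """Charge-balance residual at Boltzmann factor ``chi`` (mol charge kg-1).

    ``bulk_ions`` lists (bulk concentration, charge) for every ion carrying
    the Donnan excess; ``binding_free`` the bulk free concentrations of the
    specifically-binding ions.
    """
    local = {ion: c * chi ** ION_CHARGES[ion] for ion, c in binding_free.items()}
    q = phase_charge(phase, local)
    excess = 0.0
    for c, z in bulk_ions:
        excess += z * c * (chi ** z - 1.0)
    return q + V_D * excess


def solve_donnan_potential(
    phase: NicaDonnanPhase,
    bulk: SeawaterComposition,
    pH_free: float,
    fe3_free: float = 0.0,
) -> DonnanState:
    """Find chi neutralizing the phase charge with the Donnan ion excess.

    The residual is monotone in chi (cations enrich as chi grows), so the
    root is bracketed and solved with Brent's method.
    """
    V_D = donnan_volume(phase.donnan_b, bulk.ionic_strength)
    cH = 10.0 ** (-pH_free)
    binding = {
        "H": cH,
        "Mg": bulk.concentrations.get("Mg", 0.0),
        "Ca": bulk.concentrations.get("Ca", 0.0),
        "Fe3": fe3_free,
    }
    charges = {"Na": 1, "Mg": 2, "Ca": 2, "K": 1, "Cl": -1, "SO4": -2}
    ions = [(c, charges[k]) for k, c in bulk.concentrations.items() if k in charges]
    ions.append((cH, 1))
    if fe3_free > 0:
        ions.append((fe3_free, 3))

    def resid(logchi: float) -> float:
        return donnan_residual(phase, math.exp(logchi), ions, binding, V_D)

    if phase.Q_total == 0.0 or abs(resid(0.0)) == 0.0:
        chi = 1.0
    else:
        lo, hi = -2.0, 2.0
        for _ in range(12):
            if resid(lo) < 0 < resid(hi):
                break
            lo *= 2.0
            hi *= 2.0
        else:
            raise RuntimeError(
                f"Donnan bracket not found for phase {phase.name!r} "
                f"(I={bulk.ionic_strength:.3g}, pH_free={pH_free:.3g})"
            )
        chi = math.exp(brentq(resid, lo, hi, xtol=1e-14, rtol=8.9e-16))
    TK = bulk.temperature + 273.15
    psi = -R_GAS * TK / FARADAY * math.log(chi)
    return DonnanState(chi=chi, psi_D=psi, V_D=V_D)


# ----------------------------------------------------------------------------
# discrete siderophore ligand


def siderophore_speciation(
    ligand: DiscreteLigand,
    fe3_free: float,
    bulk: SeawaterComposition,
    pH_free: float,
    T: float | None = None,
) -> tuple[float, float]:
    """Fe bound to the siderophore and the ligand side-reaction coefficient.

    Closes the ligand mass balance over protonated, Mg, Ca and Fe species.
    Constants are treated as conditional at seawater ionic strength and
    applied to free concentrations.  Returns ``(FeSid, alpha_L)`` where
    ``alpha_L = L_total_nonFe / [L]``.
    """
    if ligand.total == 0.0 or fe3_free == 0.0:
        return 0.0, _sid_alpha(ligand, bulk, pH_free)
    alpha = _sid_alpha(ligand, bulk, pH_free)
    KFe = 10.0 ** ligand.logK_Fe
    fesid = ligand.total * KFe * fe3_free / (alpha + KFe * fe3_free)
    return fesid, alpha


def _sid_alpha(ligand: DiscreteLigand, bulk: SeawaterComposition, pH_free: float):
    h = 10.0 ** (-pH_free)
    # cumulative protonation: beta_k = 10**(sum of first k stepwise logK)
    alpha = 1.0
    cum = 0.0
    for k, logK in enumerate(ligand.logK_protonation, start=1):
        cum += logK
        alpha += 10.0 ** cum * h ** k
    alpha += 10.0 ** ligand.logK_Mg * bulk.concentrations.get("Mg", 0.0)
    alpha += 10.0 ** ligand.logK_Ca * bulk.concentrations.get("Ca", 0.0)
    return alpha


# ----------------------------------------------------------------------------
# conditional affinity spectrum


def sips_density(u: np.ndarray, p: float) -> np.ndarray:
    """Quasi-Gaussian Sips density in the heterogeneity coordinate u = ln t.

    f(u) = sin(pi p) / (2 pi (cosh(p u) + cos(pi p))), normalized to 1.
    Collapses to a delta at u = 0 as p -> 1 (homogeneous limit).
    """
    return math.sin(math.pi * p) / (
        2.0 * math.pi * (np.cosh(p * np.asarray(u)) + math.cos(math.pi * p))
    )


def weighted_mean_occupied_logK(
    phase: NicaDonnanPhase,
    chi: float,
    binding_free_bulk: Mapping[str, float],
    n_nodes: int = 2048,
    homogeneous_p: float = 0.999,
) -> AffinityReport:
    """Occupation-weighted mean log10 K' of Fe-occupied sites, by quadrature.

    NICA for group g is exactly the Sips-density integral of the local
    multicomponent isotherm ``theta_Fe,loc(u) = s_Fe e^u / (1 + S e^u)`` with
    ``s_i = (K_i c_i,local)^{n_i}`` and the site affinity for Fe at
    heterogeneity coordinate u being ``log10 k = logK_Fe + u/(n_Fe ln10)``.
    The reported affinity is conditional to the *bulk* free Fe3+ (the Donnan
    accumulation factor chi^3 is folded in), so it is directly comparable to
    solution-side conditional constants.

    Returns a report with mean = nan when no Fe is bound.
    """
    lg_chi3 = 3.0 * math.log10(chi)
    supports, densities, means, bounds = [], [], [], []
    for g in phase.groups:
        if "Fe3" not in g.ions:
            continue
        logK_fe, n_fe = g.ions["Fe3"]
        params = {"H": (g.logK_H, g.n_H), **g.ions}
        s = {}
        for ion, (logK, n) in params.items():
            c = binding_free_bulk.get(ion, 0.0) * chi ** ION_CHARGES[ion]
            if c > 0:
                s[ion] = math.exp(n * (logK * math.log(10.0) + math.log(c)))
        s_fe = s.get("Fe3", 0.0)
        S = sum(s.values())
        if s_fe == 0.0:
            continue
        if g.p >= homogeneous_p:
            # delta distribution: every occupied site has the median affinity
            logk = logK_fe + lg_chi3
            theta = (s_fe / S) * (S / (1.0 + S))
            amount = (n_fe / g.n_H) * g.Qmax * theta
            supports.append(np.array([logk]))
            densities.append(np.array([amount]))
            means.append(logk)
            bounds.append(amount)
            continue
        umax = 8.0 * math.log(10.0) / g.p
        u = np.linspace(-umax, umax, n_nodes)
        f = sips_density(u, g.p)
        t = np.exp(u)
        theta_loc = s_fe * t / (1.0 + S * t)
        w = f * theta_loc
        logk = logK_fe + u / (n_fe * math.log(10.0)) + lg_chi3
        denom = np.trapezoid(w, u)
        if denom <= 0.0:
            continue
        mean_g = float(np.trapezoid(w * logk, u) / denom)
        amount = (n_fe / g.n_H) * g.Qmax * denom
        # density over log10 K: dtheta/dlogk = f * theta_loc * du/dlogk
        supports.append(logk)
        densities.append(w * (n_fe * math.log(10.0)) * (n_fe / g.n_H) * g.Qmax)
        means.append(mean_g)
        bounds.append(amount)
    if not bounds or sum(bounds) <= 0.0:
        return AffinityReport(
            mean_logK=float("nan"),
            support=np.array([]),
            occupied_density=np.array([]),
        )
    total = sum(bounds)
    mean = sum(m * b for m, b in zip(means, bounds)) / total
    return AffinityReport(
        mean_logK=float(mean),
        support=np.concatenate(supports),
        occupied_density=np.concatenate(densities),
        per_group_mean=tuple(means),
        per_group_bound=tuple(bounds),
    )


# ----------------------------------------------------------------------------
# configuration


def _parse_group(raw: Mapping, phase_name: str) -> NicaSiteGroup:
    try:
        ions = {
            str(k): (float(v["logK"]), float(v["n"]))
            for k, v in raw.get("ions", {}).items()
        }
        if float(raw["Qmax"]) <= 0:
            raise ConfigError(f"phase {phase_name!r}: Qmax must be > 0")
        return NicaSiteGroup(
            Qmax=float(raw["Qmax"]),
            logK_H=float(raw["logK_H"]),
            n_H=float(raw["n_H"]),
            p=float(raw["p"]),
            ions=ions,
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"phase {phase_name!r} site-group block malformed: {exc}")


def _parse_phases(raw: Mapping) -> dict:
    out: dict = {}
    for name in ("dom", "pom"):
        if name not in raw:
            continue
        block = raw[name]
        groups = tuple(_parse_group(g, name) for g in block["groups"])
        out[name] = NicaDonnanPhase(
            name=name.upper(), groups=groups, donnan_b=float(block["donnan_b"])
        )
    if "siderophore" in raw:
        b = raw["siderophore"]
        out["siderophore"] = DiscreteLigand(
            name=str(b.get("name", "siderophore")),
            total=0.0,
            logK_protonation=[float(x) for x in b["logK_protonation"]],
            logK_Mg=float(b["logK_Mg"]),
            logK_Ca=float(b["logK_Ca"]),
            logK_Fe=float(b["logK_Fe"]),
        )
    return out


def load_phases(path) -> dict:
    """Load phase/ligand parameter blocks from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: not a mapping of phase blocks")
    return _parse_phases(raw)


def default_phases() -> dict:
    """Bundled (placeholder-parameter) DOM/POM/siderophore blocks."""
    text = resources.files("fespec.data").joinpath("phases_default.yaml").read_text()
    return _parse_phases(yaml.safe_load(text))
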