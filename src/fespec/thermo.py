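"""Thermodynamic database, medium corrections and inorganic Fe(III) chemistry.

This module carries everything "below" the organic chemistry: the component /
reaction / mineral dataset, van't Hoff temperature correction, a Davies
activity model, the major-ion composition of seawater scaled from salinity,
inorganic Fe hydrolysis speciation (Fe' = Fe3+ plus its hydroxo complexes),
the apparent Fe' solubility with respect to authigenic ferric hydroxide
(authFeOH), and pH scale conversions (total / free / NBS).

Conventions
-----------
* Concentrations are mol L-1 throughout; temperatures are degC at the API
  surface and K internally; all equilibrium constants are stored at the
  reference temperature 298.15 K and corrected at runtime.
* ``pH_free`` is -log10 of the free proton *concentration*; proton activity
  is gamma_H * 10**-pH_free under the Davies model, or 10**-pH_free in
  conditional mode (gamma = 1 for constants already conditioned to seawater).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "R_GAS",
    "T_REF",
    "Component",
    "Reaction",
    "MineralPhase",
    "ThermoDataset",
    "SeawaterComposition",
    "ConfigError",
    "adjust_logK_temperature",
    "activity_coefficient",
    "davies_A",
    "seawater_major_ions",
    "inorganic_fe_speciation",
    "fe_prime_ratio",
    "fe_prime_solubility",
    "fe3_saturation_concentration",
    "convert_ph_scale",
    "load_thermo_dataset",
    "default_thermo_dataset",
]

R_GAS = 8.314462618  # J mol-1 K-1
T_REF = 298.15  # K
LN10 = math.log(10.0)

#: Reference seawater major-ion composition at S = 35, mol L-1.  Chloride is
#: adjusted slightly upward so the listed ions balance exactly (the minor
#: anions Br-, F-, HCO3- are folded into Cl- for charge-book-keeping).
REFERENCE_SEAWATER_S35: dict[str, float] = {
    "Na": 0.46906,
    "Mg": 0.05282,
    "Ca": 0.01028,
    "K": 0.01021,
    "Cl": 0.54899,
    "SO4": 0.02824,
}


class ConfigError(ValueError):
    """Raised when a thermodynamic/phase configuration block is invalid."""


@dataclass(frozen=True)
class Component:
    """A basis species of the equilibrium tableau."""

    name: str
    charge: int


@dataclass(frozen=True)
class Reaction:
    """Formation of one product species from basis components.

    ``stoichiometry`` maps component names to signed integer counts, e.g.
    ``{"Fe3": 1, "H": -2}`` for ``Fe3+ + 2H2O = Fe(OH)2+ + 2H+``.  Water is
    implicit.  ``deltaH`` is the reaction enthalpy in J mol-1 (0 if unknown,
    in which case no temperature correction is applied).
    """

    product: str
    charge: int
    stoichiometry: Mapping[str, int]
    log10K_ref: float
    deltaH: float = 0.0


@dataclass(frozen=True)
class MineralPhase:
    """Solubility of a mineral: ``X(s) + nH+ = ... `` style dissolution.

    For authFeOH the reaction is ``Fe(OH)3(s) + 3H+ = Fe3+ + 3H2O`` with
    ``logKs_ref`` its log10 solubility constant at 298.15 K.
    """

    name: str
    logKs_ref: float
    deltaH: float = 0.0
    medium: str = ""


@dataclass(frozen=True)
class ThermoDataset:
    components: tuple[Component, ...]
    reactions: tuple[Reaction, ...]
    minerals: tuple[MineralPhase, ...]

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise ConfigError(f"unknown component {name!r}")

    def mineral(self, name: str = "authFeOH") -> MineralPhase:
        for m in self.minerals:
            if m.name == name:
                return m
        raise ConfigError(f"mineral phase {name!r} not defined in dataset")

    def validate(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ConfigError("components block: duplicate component names")
        charges = {c.name: c.charge for c in self.components}
        for rx in self.reactions:
            if not rx.stoichiometry:
                raise ConfigError(
                    f"reactions block: {rx.product!r} has empty stoichiometry"
                )
            z = 0
            for comp, nu in rx.stoichiometry.items():
                if comp not in charges:
                    raise ConfigError(
                        f"reactions block: {rx.product!r} references undefined "
                        f"component {comp!r}"
                    )
                z += nu * charges[comp]
            if z != rx.charge:
                raise ConfigError(
                    f"reactions block: {rx.product!r} charge {rx.charge} does "
                    f"not match stoichiometry-weighted sum {z}"
                )
        for m in self.minerals:
            if not math.isfinite(m.logKs_ref):
                raise ConfigError(f"minerals block: {m.name!r} logKs not finite")


@dataclass
class SeawaterComposition:
    """Major-ion composition (mol L-1) with salinity, temperature and I."""

    salinity: float
    temperature: float  # degC
    concentrations: dict[str, float] = field(default_factory=dict)
    ionic_strength: float = 0.0


# ----------------------------------------------------------------------------
# temperature and activity corrections


def adjust_logK_temperature(reaction, T: float) -> float:
    """van't Hoff correction of a reaction's log10 K to temperature ``T`` (K).

    log10 K(T) = log10 K_ref - (deltaH / (R ln 10)) * (1/T - 1/T_ref).
    Extrapolation outside 271-313 K is refused: the enthalpies are constant-
    deltaH parameterisations valid only near ambient conditions.
    """
    if not 271.0 <= T <= 313.0:
        raise ValueError(f"temperature {T} K outside supported range [271, 313]")
    dH = getattr(reaction, "deltaH", 0.0)
    logK = getattr(reaction, "log10K_ref", None)
    if logK is None:
        logK = reaction.logKs_ref  # MineralPhase
    if dH == 0.0:
        return logK
    return logK - dH / (R_GAS * LN10) * (1.0 / T - 1.0 / T_REF)


def davies_A(T: float) -> float:
    """Debye-Hueckel A coefficient (log10 basis) as a function of T in K."""
    t = T - 273.15
    return 0.4918 + 6.6098e-4 * t + 5.0231e-6 * t * t


def activity_coefficient(z: int, I: float, T: float = T_REF) -> float:
    """Davies-equation activity coefficient for charge ``z`` at ionic strength ``I``.

    log10 gamma = -A(T) z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I); gamma = 1 for
    uncharged species or at infinite dilution.
    """
    if I < 0:
        raise ValueError("ionic strength must be non-negative")
    if z == 0 or I == 0.0:
        return 1.0
    sI = math.sqrt(I)
    return 10.0 ** (-davies_A(T) * z * z * (sI / (1.0 + sI) - 0.3 * I))


def seawater_major_ions(S: float, T: float = 25.0) -> SeawaterComposition:
    """Major-ion composition scaled linearly with salinity from the S=35 table."""
    if not 0.0 <= S <= 42.0:
        raise ValueError(f"salinity {S} outside supported range [0, 42]")
    conc = {k: v * S / 35.0 for k, v in REFERENCE_SEAWATER_S35.items()}
    charges = {"Na": 1, "Mg": 2, "Ca": 2, "K": 1, "Cl": -1, "SO4": -2}
    I = 0.5 * sum(c * charges[k] ** 2 for k, c in conc.items())
    return SeawaterComposition(
        salinity=S, temperature=T, concentrations=conc, ionic_strength=I
    )


# ----------------------------------------------------------------------------
# inorganic Fe speciation


def _activity_mode_gammas(dataset: ThermoDataset, I: float, T: float, mode: str):
    if mode == "davies":
        return lambda z: activity_coefficient(z, I, T)
    if mode == "conditional":
        return lambda z: 1.0
    raise ValueError(f"unknown activity model {mode!r}")


def fe_prime_ratio(
    pH_free: float,
    T: float,
    S: float,
    dataset: ThermoDataset,
    activity_model: str = "davies",
) -> float:
    """Fe'/[Fe3+] side-reaction ratio of inorganic hydrolysis at fixed conditions.

    Fe' is linear in [Fe3+] at fixed pH/T/S, so the full speciation reduces to
    this single conditional ratio.
    """
    sw = seawater_major_ions(S, T)
    TK = T + 273.15
    gamma = _activity_mode_gammas(dataset, sw.ionic_strength, TK, activity_model)
    aH = gamma(1) * 10.0 ** (-pH_free)
    g3 = gamma(3)
    ratio = 1.0
    for rx in dataset.reactions:
        nu_fe = rx.stoichiometry.get("Fe3", 0)
        if nu_fe != 1:
            continue
        extra = [k for k in rx.stoichiometry if k not in ("Fe3", "H")]
        if extra:
            # hydrolysis-only ratio: skip mixed complexes (none in default set)
            continue
        nH = -rx.stoichiometry.get("H", 0)
        logK = adjust_logK_temperature(rx, TK)
        # a_prod = K * a_Fe3 * a_H**-nH ; [prod] = a_prod / gamma(z)
        ratio += 10.0 ** logK * g3 * aH ** (-nH) / gamma(rx.charge)
    return ratio


def inorganic_fe_speciation(
    fe3_free: float,
    pH_free: float,
    T: float,
    S: float,
    dataset: ThermoDataset,
    activity_model: str = "davies",
) -> dict[str, float]:
    """Concentrations of Fe3+ and each hydrolysis species, plus their sum Fe'.

    Each species follows mass action with temperature- and activity-corrected
    constants.  Returns a dict with one entry per species and ``"Fe_prime"``.
    """
    if fe3_free < 0:
        raise ValueError("fe3_free must be non-negative")
    sw = seawater_major_ions(S, T)
    TK = T + 273.15
    gamma = _activity_mode_gammas(dataset, sw.ionic_strength, TK, activity_model)
    aH = gamma(1) * 10.0 ** (-pH_free)
    aFe = gamma(3) * fe3_free
    out: dict[str, float] = {"Fe3": fe3_free}
    total = fe3_free
    for rx in dataset.reactions:
        if rx.stoichiometry.get("Fe3", 0) != 1:
            continue
        for comp in rx.stoichiometry:
            if comp not in ("Fe3", "H"):
                dataset.component(comp)  # raises ConfigError if undefined
        nH = -rx.stoichiometry.get("H", 0)
        logK = adjust_logK_temperature(rx, TK)
        conc = 10.0 ** logK * aFe * aH ** (-nH) / gamma(rx.charge)
        out[rx.product] = conc
        total += conc
    out["Fe_prime"] = total
    return out


def fe3_saturation_concentration(
    pH_free: float,
    T: float,
    S: float,
    dataset: ThermoDataset,
    activity_model: str = "davies",
) -> float:
    """[Fe3+] at authFeOH saturation: {Fe3+}_sat = *Ks(T) {H+}^3, as concentration."""
    mineral = dataset.mineral("authFeOH")
    sw = seawater_major_ions(S, T)
    TK = T + 273.15
    gamma = _activity_mode_gammas(dataset, sw.ionic_strength, TK, activity_model)
    aH = gamma(1) * 10.0 ** (-pH_free)
    logKs = adjust_logK_temperature(mineral, TK)
    return 10.0 ** logKs * aH ** 3 / gamma(3)


def fe_prime_solubility(
    pH_free: float,
    T: float,
    S: float,
    dataset: ThermoDataset,
    activity_model: str = "davies",
) -> float:
    """Apparent Fe' solubility (mol L-1): Fe' in equilibrium with authFeOH."""
    fe3_sat = fe3_saturation_concentration(pH_free, T, S, dataset, activity_model)
    return fe3_sat * fe_prime_ratio(pH_free, T, S, dataset, activity_model)


# ----------------------------------------------------------------------------
# pH scales


def _total_sulfate(S: float) -> float:
    # mol kg-soln-1, proportional to salinity
    return 0.02824 * S / 35.0


def _k_bisulfate(S: float, T: float) -> float:
    """HSO4- dissociation constant on the free scale (Dickson 1990 form)."""
    TK = T + 273.15
    I = 19.924 * S / (1000.0 - 1.005 * S)
    lnK = (
        -4276.1 / TK
        + 141.328
        - 23.093 * math.log(TK)
        + (-13856.0 / TK + 324.57 - 47.986 * math.log(TK)) * math.sqrt(I)
        + (35474.0 / TK - 771.54 + 114.723 * math.log(TK)) * I
        - 2698.0 / TK * I ** 1.5
        + 1776.0 / TK * I ** 2
        + math.log(1.0 - 0.001005 * S)
    )
    return math.exp(lnK)


def convert_ph_scale(
    pH: float, from_scale: str, to_scale: str, S: float, T: float
) -> float:
    """Convert pH between total, free and NBS scales at salinity S, T in degC.

    total <-> free uses bisulfate association; NBS applies the Davies proton
    activity coefficient on top of the free scale.
    """
    scales = {"total", "free", "NBS"}
    if from_scale not in scales or to_scale not in scales:
        raise ValueError(f"unknown pH scale in ({from_scale!r}, {to_scale!r})")
    if from_scale == to_scale:
        return pH
    shift_tf = math.log10(1.0 + _total_sulfate(S) / _k_bisulfate(S, T))
    sw = seawater_major_ions(S, T)
    gH = activity_coefficient(1, sw.ionic_strength, T + 273.15)
    # to free scale first
    if from_scale == "total":
        ph_free = pH + shift_tf
    elif from_scale == "NBS":
        ph_free = pH + math.log10(gH)
    else:
        ph_free = pH
    if to_scale == "free":
        return ph_free
    if to_scale == "total":
        return ph_free - shift_tf
    return ph_free - math.log10(gH)


# ----------------------------------------------------------------------------
# dataset loading


def _parse_thermo_mapping(raw: Mapping) -> ThermoDataset:
    try:
        comps = tuple(
            Component(name=str(c["name"]), charge=int(c["charge"]))
            for c in raw["components"]
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"components block malformed: {exc}") from exc
    try:
        rxns = tuple(
            Reaction(
                product=str(r["product"]),
                charge=int(r["charge"]),
                stoichiometry={str(k): int(v) for k, v in r["stoichiometry"].items()},
                log10K_ref=float(r["log10K_ref"]),
                deltaH=float(r.get("deltaH", 0.0)),
            )
            for r in raw.get("reactions", [])
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"reactions block malformed: {exc}") from exc
    try:
        minerals = tuple(
            MineralPhase(
                name=str(m["name"]),
                logKs_ref=float(m["logKs_ref"]),
                deltaH=float(m.get("deltaH", 0.0)),
                medium=str(m.get("medium", "")),
            )
            for m in raw.get("minerals", [])
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"minerals block malformed: {exc}") from exc
    ds = ThermoDataset(components=comps, reactions=rxns, minerals=minerals)
    ds.validate()
    return ds


def load_thermo_dataset(path) -> ThermoDataset:
    """Load and validate a thermodynamic dataset from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "components" not in raw:
        raise ConfigError(f"{path}: missing 'components' block")
    return _parse_thermo_mapping(raw)


def default_thermo_dataset() -> ThermoDataset:
    """The bundled (placeholder-constant) seawater dataset."""
    text = (
        resources.files("fespec.data").joinpath("thermo_seawater.yaml").read_text()
    )
    return _parse_thermo_mapping(yaml.safe_load(text))
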