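"""Synthetic zonal-transect generator with forward-model truth.

Emulates a subsurface (250-5000 m) zonal transect across the South Pacific
(~30 degS, from the South American margin westward across the dateline) with
smooth background fields for temperature, salinity, pH, oxygen, DOC and
particulate phosphorus, a mesopelagic siderophore patch, and elevated-Fe
plumes at three planted sources (a hydrothermal ridge, a volcano in the far
west and the continental shelf at the eastern edge).

"Observed" Fe concentrations are constructed by running the forward
equilibrium model (all four pathways) on the generated conditions and adding
multiplicative lognormal noise, so that with zero noise the analysis pipeline
closes exactly on the generated table.  Anomaly samples are perturbed away
from equilibrium by configured offsets: near-seafloor inert ferromanganese
particles (extra observed LPFe with a matching LPMn signature) and
labile/reduced Fe inputs in the saturated plume cores (extra observed DFe).
The per-sample truth (equilibrium pools and planted class) is emitted as a
parallel table keyed by sample id.

No claim of oceanographic realism is made beyond the observed ranges; fields
are low-order harmonics in longitude and exponentials/Gaussians in depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nica, thermo, transect as tr
from .ompa import PARAMETERS, REDFIELD, WaterMassEndmember
from .pathways import PathwayConfig, SampleConditions, run_pathways

__all__ = ["SyntheticConfig", "generate_transect", "generate_watermass_mixture"]

SIDEROPHORE_LOD = 5.0  # pmol L-1; below-detection values are emitted as 0


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the study-like conditions."""

    seed: int = 0
    n_stations: int = 40
    n_depths: int = 12
    lon_east: float = -72.0  # degE, eastern end (South American margin)
    lon_span: float = 109.0  # degrees travelled westward (ends at 179 degE)
    depth_min: float = 260.0
    depth_max: float = 5000.0
    # source descriptors: (lon center degE, depth center m, lon sigma deg,
    # depth sigma m, TLFe amplitude nmol L-1)
    ridge: tuple = (-117.0, 2500.0, 4.0, 600.0, 11.5)
    volcano: tuple = (177.0, 1200.0, 2.5, 350.0, 2.8)
    shelf: tuple = (-73.5, 3800.0, 2.5, 1400.0, 5.5)
    # mesopelagic siderophore patch (lon center, depth center, sigmas, peak pmol/L)
    sid_patch: tuple = (-117.0, 950.0, 8.0, 300.0, 425.0)
    noise_fe: float = 0.05  # lognormal sigma on observed Fe, ~analytical RSD
    noise_conditions: float = 0.01  # lognormal sigma on DOC/TPP
    n_anomaly_femn: int = 8
    n_anomaly_source: int = 12
    # planted offsets, nmol L-1: twice the enhanced-residual thresholds
    anomaly_lpfe_offset: float = 2 * abs(tr.ENHANCED_THRESHOLDS["lpfe_neg"])
    anomaly_dfe_offset: float = 2 * tr.ENHANCED_THRESHOLDS["dfe_pos"]


def _gauss(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def generate_transect(
    config: SyntheticConfig | None = None,
    phases: dict | None = None,
    dataset=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the sample table and its parallel truth table.

    Returns ``(samples, truth)``; ``samples`` has the canonical pipeline
    columns, ``truth`` the equilibrium pools (nmol L-1), the saturation flag
    and the planted class, keyed by ``sample_id``.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    phases = phases if phases is not None else nica.default_phases()
    dataset = dataset or thermo.default_thermo_dataset()

    lon_off = np.linspace(0.0, cfg.lon_span, cfg.n_stations)
    lons = ((cfg.lon_east - lon_off + 180.0) % 360.0) - 180.0
    depths = np.geomspace(cfg.depth_min, cfg.depth_max, cfg.n_depths)
    LON, Z = np.meshgrid(lons, depths, indexing="ij")
    OFF = np.repeat(lon_off[:, None], cfg.n_depths, axis=1)
    east = 1.0 - OFF / cfg.lon_span  # 1 at the margin, 0 in the far west
    n = LON.size
    lon = LON.ravel()
    z = Z.ravel()
    east = east.ravel()
    frac = (OFF / cfg.lon_span).ravel()

    # background hydrography (ranges mirror the observed subsurface window)
    T = 1.6 + 14.4 * np.exp(-(z - 250.0) / 700.0)
    S = 34.65 - 0.35 * _gauss(z, 900.0, 500.0) + 0.02 * np.cos(2 * np.pi * frac)
    ph = 7.76 + 0.19 * np.exp(-(z - 250.0) / 400.0) - 0.05 * east * _gauss(z, 800.0, 600.0)
    doc = (39.0 + 9.0 * np.exp(-(z - 250.0) / 600.0) + 1.5 * np.cos(2 * np.pi * frac))
    tpp = 0.3 + 3.2 * np.exp(-(z - 250.0) / 800.0) + 0.8 * east * np.exp(-(z - 250.0) / 500.0)
    doc = doc * rng.lognormal(0.0, cfg.noise_conditions, n)
    tpp = tpp * rng.lognormal(0.0, cfg.noise_conditions, n)
    aou = 20.0 + 150.0 * _gauss(z, 900.0, 700.0) * (0.4 + 0.6 * east)
    o2 = tr.oxygen_saturation(T, S) - aou

    # mesopelagic siderophore patch; undetectable outside it
    plon, pz, pslon, psz, ppeak = cfg.sid_patch
    sid = ppeak * _gauss(_dlon(lon, plon), 0.0, pslon) * _gauss(z, pz, psz)
    sid = np.where((z >= 400.0) & (z <= 1500.0), sid, 0.0)
    sid = np.where(sid < SIDEROPHORE_LOD, 0.0, sid)

    # total labile Fe: background plus the three source plumes
    tlfe = (0.55 + 0.45 * east) * (0.75 + 0.25 * z / 5000.0)
    for slon, sz, sslon, ssz, amp in (cfg.ridge, cfg.volcano, cfg.shelf):
        tlfe = tlfe + amp * _gauss(_dlon(lon, slon), 0.0, sslon) * _gauss(z, sz, ssz)

    stations = np.repeat(
        [f"S{i + 1:02d}" for i in range(cfg.n_stations)], cfg.n_depths
    )
    lat = np.full(n, -30.0)
    pom, _poc = tr.pom_from_tpp(tpp, stations, z)
    dom = tr.dom_from_doc(doc)

    # forward equilibrium model -> the "observations"
    cfgp = PathwayConfig(frozenset({"p1", "p2", "p3", "p4"}))
    dfe_eq = np.empty(n)
    lpfe_eq = np.empty(n)
    pools = np.empty((n, 5))
    capped = np.zeros(n, dtype=bool)
    warm = None
    for i in range(n):
        sample = SampleConditions(
            dfe_obs=tlfe[i] * 1e-9, lpfe_obs=0.0, pH_total=ph[i], T=T[i],
            S=S[i], dom_mass=dom[i], pom_mass=pom[i],
            siderophore_total=sid[i] * 1e-12,
        )
        pred = run_pathways(sample, cfgp, phases=phases, dataset=dataset,
                            warm_start=warm)
        r = pred.result
        if r.converged and r.fe3_free > 0:
            warm = (r.fe3_free, r.chi_dom, r.chi_pom)
        dfe_eq[i] = pred.dfe_pred * 1e9
        lpfe_eq[i] = pred.lpfe_pred * 1e9
        pools[i] = (r.fe_prime, r.fe_dom, r.fe_sid, r.fe_pom, r.auth_feoh)
        capped[i] = r.capped

    noise_d = rng.lognormal(0.0, cfg.noise_fe, n) if cfg.noise_fe > 0 else 1.0
    noise_l = rng.lognormal(0.0, cfg.noise_fe, n) if cfg.noise_fe > 0 else 1.0
    dfe_obs = dfe_eq * noise_d
    lpfe_obs = lpfe_eq * noise_l
    lpmn = np.full(n, 22.0) * rng.lognormal(0.0, 0.2, n)
    label = np.full(n, "equilibrium", dtype=object)

    # planted anomalies -------------------------------------------------
    # inert ferromanganese particles near the deep seafloor east of the ridge
    deep = np.flatnonzero((z > 3000.0) & (east > 0.45) & ~capped)
    pick = rng.choice(deep, size=min(cfg.n_anomaly_femn, deep.size), replace=False)
    lpfe_obs[pick] += cfg.anomaly_lpfe_offset
    lpmn[pick] = lpfe_obs[pick] * 1e3 / 1.1  # Fe:Mn of ferromanganese deposits
    label[pick] = "anomaly_femn"
    # labile/reduced Fe input in saturated plume cores: observed DFe excess
    sat = np.flatnonzero(capped & (label == "equilibrium"))
    pick = rng.choice(sat, size=min(cfg.n_anomaly_source, sat.size), replace=False)
    dfe_obs[pick] += cfg.anomaly_dfe_offset
    label[pick] = "anomaly_source"

    sample_id = np.arange(n)
    samples = pd.DataFrame(
        {
            "sample_id": sample_id,
            "station": stations,
            "lon": lon,
            "lat": lat,
            "depth": z,
            "temp": T,
            "sal": S,
            "oxygen": o2,
            "ph_total": ph,
            "doc": doc,
            "tpp": tpp,
            "dfe": dfe_obs,
            "lpfe": lpfe_obs,
            "tpfe": lpfe_obs * 3.0,  # refractory fraction rides along passively
            "lpmn": lpmn,
            "siderophore": sid,
        }
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_id,
            "fe_prime": pools[:, 0] * 1e9,
            "fe_dom": pools[:, 1] * 1e9,
            "fe_sid": pools[:, 2] * 1e9,
            "fe_pom": pools[:, 3] * 1e9,
            "auth_feoh": pools[:, 4] * 1e9,
            "dfe_eq": dfe_eq,
            "lpfe_eq": lpfe_eq,
            "capped": capped,
            "label": label,
        }
    )
    return samples, truth


def _dlon(lon, center):
    return (np.asarray(lon) - center + 180.0) % 360.0 - 180.0


def generate_watermass_mixture(
    endmembers: list[WaterMassEndmember],
    fractions,
    delta_p: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
) -> dict:
    """Forward-construct one eOMPA sample: obs = E x + r dP (+ noise)."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.min() < 0 or abs(fractions.sum() - 1.0) > 1e-12:
        raise ValueError("fractions must be non-negative and sum to 1")
    if len(fractions) != len(endmembers):
        raise ValueError("one fraction per endmember required")
    rng = np.random.default_rng(seed)
    E = np.array([[em.values[p] for em in endmembers] for p in PARAMETERS])
    obs = E @ fractions + REDFIELD * delta_p
    if noise > 0:
        obs = obs + rng.normal(0.0, noise, obs.shape) * np.where(
            np.abs(obs) > 0, np.abs(obs), 1.0
        ) * 0.01
    return dict(zip(PARAMETERS, obs))
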