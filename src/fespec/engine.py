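"""Multicomponent Fe equilibrium: mass balance, Donnan balances, mineral cap.

Solves, per sample, the simultaneous equilibrium of

* inorganic Fe hydrolysis (Fe' linear in free Fe3+ at fixed pH/T/S),
* Fe binding to the discrete siderophore ligand,
* Fe / H / Mg / Ca binding to the DOM and POM NICA-Donnan phases, each with
  its own Donnan charge balance, and
* precipitation of authigenic ferric hydroxide (authFeOH) when free Fe3+
  exceeds the ferrihydrite-like solubility cap,

subject to a fixed total-Fe boundary condition.  pH is an imposed condition
(total scale in, converted to free internally), never a solved unknown.

The production path is a damped Newton iteration on log-transformed unknowns
``{ln [Fe3+], ln chi_DOM, ln chi_POM}`` seeded by a short sequential warm-up;
precipitation is handled as a complementarity branch (solve, check the
saturation index, cap, re-solve).  ``brute_force_oracle`` re-solves the same
system by nested bracketed 1-D root finding and serves as the independent
cross-check; ``solve_equilibrium`` falls back to it automatically on
non-convergence and flags the path taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import nica, thermo
from .nica import AffinityReport, DiscreteLigand, NicaDonnanPhase
from .thermo import ThermoDataset

__all__ = [
    "SpeciationProblem",
    "SpeciationResult",
    "solve_equilibrium",
    "brute_force_oracle",
    "saturation_index",
    "solve_batch",
]

LN10 = math.log(10.0)
_CONV_TOL = 1e-10
_SI_TOL = 1e-6


@dataclass
class SpeciationProblem:
    """Totals plus fixed conditions for one equilibrium solve.

    ``total_fe`` is DFe_obs when only the dissolved-side pathways are active
    and TLFe_obs (= DFe_obs + LPFe_obs) when POM binding is included.
    """

    total_fe: float  # mol L-1
    pH_total: float
    T: float  # degC
    S: float  # psu
    dom: NicaDonnanPhase | None = None
    pom: NicaDonnanPhase | None = None
    siderophore: DiscreteLigand | None = None
    allow_mineral: bool = False
    dataset: ThermoDataset | None = None
    activity_model: str = "davies"
    compute_affinity: bool = True

    def __post_init__(self):
        if self.total_fe < 0:
            raise ValueError("total_fe must be >= 0")
        if self.dataset is None:
            self.dataset = thermo.default_thermo_dataset()


@dataclass
class SpeciationResult:
    """Equilibrium distribution of Fe over the defined pools (mol L-1)."""

    fe3_free: float
    fe_prime: float
    fe_dom: float
    fe_sid: float
    fe_pom: float
    auth_feoh: float
    chi_dom: float
    chi_pom: float
    saturation_index: float
    converged: bool
    iterations: int
    method: str = "newton"
    capped: bool = False
    pH_free: float = float("nan")
    affinity: dict[str, AffinityReport] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return (
            self.fe_prime + self.fe_dom + self.fe_sid + self.fe_pom + self.auth_feoh
        )


# ----------------------------------------------------------------------------
# fast problem context: everything precomputed to plain floats/tuples

_Z_SLOT = (1, 2, 2, 3)  # charges of (H, Mg, Ca, Fe3)
_SLOT = {"H": 0, "Mg": 1, "Ca": 2, "Fe3": 3}


class _Ctx:
    __slots__ = (
        "problem", "total", "cH", "cMg", "cCa", "ratio", "fe3_sat",
        "sid_alpha", "sid_KL", "phases", "pH_free", "sw",
    )

    def __init__(self, problem: SpeciationProblem):
        self.problem = problem
        p = problem
        self.total = p.total_fe
        self.sw = thermo.seawater_major_ions(p.S, p.T)
        self.pH_free = thermo.convert_ph_scale(p.pH_total, "total", "free", p.S, p.T)
        self.cH = 10.0 ** (-self.pH_free)
        self.cMg = self.sw.concentrations.get("Mg", 0.0)
        self.cCa = self.sw.concentrations.get("Ca", 0.0)
        self.ratio = thermo.fe_prime_ratio(
            self.pH_free, p.T, p.S, p.dataset, p.activity_model
        )
        self.fe3_sat = (
            thermo.fe3_saturation_concentration(
                self.pH_free, p.T, p.S, p.dataset, p.activity_model
            )
            if p.allow_mineral
            else math.inf
        )
        if p.siderophore is not None and p.siderophore.total > 0:
            self.sid_KL = 10.0 ** p.siderophore.logK_Fe
            self.sid_alpha = nica._sid_alpha(p.siderophore, self.sw, self.pH_free)
        else:
            self.sid_KL = 0.0
            self.sid_alpha = 1.0
        self.phases = []
        charges = {"Na": 1, "Mg": 2, "Ca": 2, "K": 1, "Cl": -1, "SO4": -2}
        bulk = [(c, charges[k]) for k, c in self.sw.concentrations.items()]
        bulk.append((self.cH, 1))
        for phase in (p.dom, p.pom):
            if phase is None:
                self.phases.append(None)
                continue
            VD = nica.donnan_volume(phase.donnan_b, self.sw.ionic_strength)
            groups = []
            for g in phase.groups:
                ions = [(g.n_H * g.logK_H * LN10, g.n_H, 0)]
                for ion, (logK, n) in g.ions.items():
                    ions.append((n * logK * LN10, n, _SLOT[ion]))
                groups.append((g.Qmax, g.n_H, g.p, tuple(ions)))
            self.phases.append(
                (phase, VD, tuple(groups), phase.Q_total, tuple(bulk))
            )

    # -- fast kernels -------------------------------------------------------

    def bound_fe_and_charge(self, iphase: int, chi: float, fe3: float):
        """(Fe bound mol kg-1, phase charge q mol kg-1) at chi, free Fe3+."""
        _, _, groups, Qtot, _ = self.phases[iphase]
        chi2 = chi * chi
        local = (self.cH * chi, self.cMg * chi2, self.cCa * chi2, fe3 * chi2 * chi)
        bound_fe = 0.0
        q = -Qtot
        for Qmax, nH, pg, ions in groups:
            S = 0.0
            terms = []
            for a, n, slot in ions:
                c = local[slot]
                if c > 0.0:
                    s = math.exp(a + n * math.log(c))
                    S += s
                    terms.append((s, n, slot))
            if S == 0.0:
                continue
            Sp = S ** pg
            occ = Sp / (1.0 + Sp)
            fac = Qmax * occ / (S * nH)
            for s, n, slot in terms:
                amt = fac * n * s
                q += _Z_SLOT[slot] * amt
                if slot == 3:
                    bound_fe += amt
        return bound_fe, q

    def donnan_resid(self, iphase: int, chi: float, fe3: float) -> float:
        """Charge-balance residual (mol charge kg-1), monotone increasing in chi."""
        _, VD, _, _, bulk = self.phases[iphase]
        _, q = self.bound_fe_and_charge(iphase, chi, fe3)
        inv = 1.0 / chi
        chi2 = chi * chi
        powz = {1: chi, 2: chi2, -1: inv, -2: inv * inv, 3: chi2 * chi}
        excess = 0.0
        for c, z in bulk:
            excess += z * c * (powz[z] - 1.0)
        if fe3 > 0.0:
            excess += 3.0 * fe3 * (powz[3] - 1.0)
        return q + VD * excess

    def dissolved_and_pom(self, fe3: float, chi_d: float, chi_p: float):
        """Pools (fe_prime, fe_sid, fe_dom, fe_pom) at given unknowns."""
        fe_prime = fe3 * self.ratio
        fe_sid = 0.0
        if self.sid_KL > 0.0:
            kf = self.sid_KL * fe3
            fe_sid = self.problem.siderophore.total * kf / (self.sid_alpha + kf)
        fe_dom = fe_pom = 0.0
        if self.phases[0] is not None and self.phases[0][0].mass > 0:
            b, _ = self.bound_fe_and_charge(0, chi_d, fe3)
            fe_dom = b * self.phases[0][0].mass
        if self.phases[1] is not None and self.phases[1][0].mass > 0:
            b, _ = self.bound_fe_and_charge(1, chi_p, fe3)
            fe_pom = b * self.phases[1][0].mass
        return fe_prime, fe_sid, fe_dom, fe_pom

    def mass_resid(self, fe3: float, chi_d: float, chi_p: float) -> float:
        """(sum of dissolved + POM pools - total)/total; monotone in fe3."""
        fp, fs, fd, fpom = self.dissolved_and_pom(fe3, chi_d, chi_p)
        return (fp + fs + fd + fpom) / self.total - 1.0


# ----------------------------------------------------------------------------
# 1-D bracketed solves (shared by warm-up, capped branch and oracle)


def _solve_chi(ctx: _Ctx, iphase: int, fe3: float, guess: float = 1.0) -> float:
    f = lambda lc: ctx.donnan_resid(iphase, math.exp(lc), fe3)
    g = math.log(max(guess, 1e-12))
    lo, hi = g - 1.0, g + 1.0
    flo, fhi = f(lo), f(hi)
    width = 1.0
    for _ in range(40):
        if flo < 0.0 < fhi:
            return math.exp(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))
        if flo == 0.0:
            return math.exp(lo)
        if fhi == 0.0:
            return math.exp(hi)
        width *= 2.0
        if flo > 0.0:
            lo -= width
            flo = f(lo)
        else:
            hi += width
            fhi = f(hi)
    raise RuntimeError("Donnan charge-balance bracket not found")


def _solve_fe3(ctx: _Ctx, chi_d: float, chi_p: float, guess: float | None = None):
    f = lambda lf: ctx.mass_resid(math.exp(lf), chi_d, chi_p)
    hi = math.log(ctx.total / ctx.ratio)  # inorganic-only upper bound
    if f(hi) < 0.0:  # numerical guard; cannot happen analytically
        return math.exp(hi)
    if guess is not None and guess > 0.0:
        lo = math.log(guess) - 2.0
        hi_g = min(math.log(guess) + 2.0, hi)
        if f(lo) < 0.0 < f(hi_g):
            return math.exp(brentq(f, lo, hi_g, xtol=1e-13, rtol=8.9e-16))
    lo = hi
    step = 4.0 * LN10
    for _ in range(30):
        lo -= step
        if f(lo) < 0.0:
            return math.exp(brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16))
    # everything bound even at vanishing fe3: free Fe is numerically zero
    return math.exp(lo)


# ----------------------------------------------------------------------------
# public solvers


def _zero_result(ctx: _Ctx) -> SpeciationResult:
    chi_d = _solve_chi(ctx, 0, 0.0) if ctx.phases[0] is not None else 1.0
    chi_p = _solve_chi(ctx, 1, 0.0) if ctx.phases[1] is not None else 1.0
    return SpeciationResult(
        fe3_free=0.0, fe_prime=0.0, fe_dom=0.0, fe_sid=0.0, fe_pom=0.0,
        auth_feoh=0.0, chi_dom=chi_d, chi_pom=chi_p,
        saturation_index=-math.inf, converged=True, iterations=0,
        pH_free=ctx.pH_free,
    )


def _newton(ctx: _Ctx, warm: tuple | None):
    """Damped Newton on log unknowns. Returns (fe3, chi_d, chi_p, iters) or None."""
    has_d = ctx.phases[0] is not None
    has_p = ctx.phases[1] is not None
    chi_d = warm[1] if warm else 1.0
    chi_p = warm[2] if warm else 1.0
    # sequential warm-up: chi is nearly decoupled from trace Fe
    if has_d:
        chi_d = _solve_chi(ctx, 0, 0.0, guess=chi_d)
    if has_p:
        chi_p = _solve_chi(ctx, 1, 0.0, guess=chi_p)
    fe3 = _solve_fe3(ctx, chi_d, chi_p, guess=warm[0] if warm else None)

    idx = [0] + ([1] if has_d else []) + ([2] if has_p else [])
    x = np.array([math.log(fe3), math.log(chi_d), math.log(chi_p)])[idx]

    def residuals(xv):
        full = [math.log(fe3), math.log(chi_d), math.log(chi_p)]
        for k, i in enumerate(idx):
            full[i] = xv[k]
        f3, cd, cp = math.exp(full[0]), math.exp(full[1]), math.exp(full[2])
        out = [ctx.mass_resid(f3, cd, cp)]
        if has_d:
            out.append(ctx.donnan_resid(0, cd, f3) / ctx.phases[0][3])
        if has_p:
            out.append(ctx.donnan_resid(1, cp, f3) / ctx.phases[1][3])
        return np.array(out)

    F = residuals(x)
    for it in range(1, 61):
        if np.max(np.abs(F)) < _CONV_TOL:
            full = [math.log(fe3), math.log(chi_d), math.log(chi_p)]
            for k, i in enumerate(idx):
                full[i] = x[k]
            return math.exp(full[0]), math.exp(full[1]), math.exp(full[2]), it
        n = len(x)
        J = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * max(abs(x[j]), 1.0)
            xp = x.copy()
            xp[j] += h
            J[:, j] = (residuals(xp) - F) / h
        try:
            dx = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            return None
        norm0 = float(np.max(np.abs(F)))
        lam = 1.0
        for _ in range(50):
            Fn = residuals(x + lam * dx)
            if float(np.max(np.abs(Fn))) < norm0:
                break
            lam *= 0.5
        else:
            return None
        x = x + lam * dx
        F = Fn
    return None


def _assemble(ctx: _Ctx, fe3, chi_d, chi_p, iters, method, capped) -> SpeciationResult:
    fp, fs, fd, fpom = ctx.dissolved_and_pom(fe3, chi_d, chi_p)
    if capped:
        auth = ctx.total - (fp + fs + fd + fpom)
        if auth < -1e-9 * ctx.total:
            raise RuntimeError(
                "negative authFeOH in capped branch: uncapped solve was correct"
            )
        auth = max(auth, 0.0)
        si = 0.0
    else:
        auth = 0.0
        si = math.log10(fe3 / ctx.fe3_sat) if math.isfinite(ctx.fe3_sat) else -math.inf
    res = SpeciationResult(
        fe3_free=fe3, fe_prime=fp, fe_dom=fd, fe_sid=fs, fe_pom=fpom,
        auth_feoh=auth, chi_dom=chi_d, chi_pom=chi_p, saturation_index=si,
        converged=True, iterations=iters, method=method, capped=capped,
        pH_free=ctx.pH_free,
    )
    if ctx.problem.compute_affinity:
        bulk_free = {"H": ctx.cH, "Mg": ctx.cMg, "Ca": ctx.cCa, "Fe3": fe3}
        for key, iph, chi in (("DOM", 0, chi_d), ("POM", 1, chi_p)):
            ph = ctx.phases[iph]
            if ph is not None and ph[0].mass > 0 and fe3 > 0:
                res.affinity[key] = nica.weighted_mean_occupied_logK(
                    ph[0], chi, bulk_free
                )
    return res


def solve_equilibrium(
    problem: SpeciationProblem, warm_start: tuple | None = None
) -> SpeciationResult:
    """Solve one speciation problem; see the module docstring for the method.

    ``warm_start`` optionally carries ``(fe3, chi_dom, chi_pom)`` from a
    neighbouring sample (transect runs).  On Newton failure the bracketed
    oracle is used automatically and ``result.method`` records it.
    """
    ctx = _Ctx(problem)
    if ctx.total == 0.0:
        return _zero_result(ctx)
    sol = _newton(ctx, warm_start)
    if sol is None:
        res = brute_force_oracle(problem)
        res.method = "oracle-fallback"
        return res
    fe3, chi_d, chi_p, iters = sol
    if problem.allow_mineral and fe3 > ctx.fe3_sat * (1.0 + 1e-12):
        fe3 = ctx.fe3_sat
        chi_d = _solve_chi(ctx, 0, fe3, chi_d) if ctx.phases[0] is not None else 1.0
        chi_p = _solve_chi(ctx, 1, fe3, chi_p) if ctx.phases[1] is not None else 1.0
        return _assemble(ctx, fe3, chi_d, chi_p, iters, "newton", True)
    return _assemble(ctx, fe3, chi_d, chi_p, iters, "newton", False)


def brute_force_oracle(problem: SpeciationProblem) -> SpeciationResult:
    """Independent solve by nested bracketed 1-D root finding.

    Outer level: chi_DOM; middle: chi_POM; inner: [Fe3+] closing the mass
    balance (each residual is monotone in its own unknown at fixed others).
    The same precipitation complementarity branch is applied afterwards.
    """
    ctx = _Ctx(problem)
    if ctx.total == 0.0:
        return _zero_result(ctx)
    has_d = ctx.phases[0] is not None
    has_p = ctx.phases[1] is not None
    state = {"fe3": None}

    def fe3_for(chi_d, chi_p):
        state["fe3"] = _solve_fe3(ctx, chi_d, chi_p, guess=state["fe3"])
        return state["fe3"]

    def pom_resid(chi_p, chi_d):
        return ctx.donnan_resid(1, chi_p, fe3_for(chi_d, chi_p))

    def solve_pom(chi_d):
        if not has_p:
            return 1.0
        f = lambda lc: pom_resid(math.exp(lc), chi_d)
        return math.exp(_widen_brentq(f))

    def dom_resid(chi_d):
        chi_p = solve_pom(chi_d)
        return ctx.donnan_resid(0, chi_d, fe3_for(chi_d, chi_p)), chi_p

    if has_d:
        f = lambda lc: dom_resid(math.exp(lc))[0]
        chi_d = math.exp(_widen_brentq(f))
    else:
        chi_d = 1.0
    chi_p = solve_pom(chi_d)
    fe3 = fe3_for(chi_d, chi_p)
    capped = problem.allow_mineral and fe3 > ctx.fe3_sat * (1.0 + 1e-12)
    if capped:
        fe3 = ctx.fe3_sat
        chi_d = _solve_chi(ctx, 0, fe3) if has_d else 1.0
        chi_p = _solve_chi(ctx, 1, fe3) if has_p else 1.0
    return _assemble(ctx, fe3, chi_d, chi_p, 0, "oracle", capped)


def _widen_brentq(f, lo: float = -2.0, hi: float = 2.0) -> float:
    flo, fhi = f(lo), f(hi)
    width = 2.0
    for _ in range(40):
        if flo < 0.0 < fhi:
            return brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
        if flo == 0.0:
            return lo
        if fhi == 0.0:
            return hi
        width *= 2.0
        if flo > 0.0:
            lo -= width
            flo = f(lo)
        else:
            hi += width
            fhi = f(hi)
    raise RuntimeError("bracket not found in nested bisection")


def saturation_index(result: SpeciationResult, problem: SpeciationProblem) -> float:
    """SI = log10({Fe3+}{H+}^-3 / *Ks(T)); 0 at the cap, < 0 undersaturated."""
    ctx = _Ctx(problem)
    if result.fe3_free == 0.0:
        return -math.inf
    if not math.isfinite(ctx.fe3_sat):
        raise ValueError("saturation index undefined without a mineral phase")
    return math.log10(result.fe3_free / ctx.fe3_sat)


def solve_batch(problems, warm: bool = True):
    """Solve a sequence of problems, warm-starting each from its predecessor."""
    out = []
    prev = None
    for p in problems:
        res = solve_equilibrium(p, warm_start=prev if warm else None)
        if res.converged and res.fe3_free > 0:
            prev = (res.fe3_free, res.chi_dom, res.chi_pom)
        out.append(res)
    return out
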