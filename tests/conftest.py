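import numpy as np
import pytest

from fespec import nica, thermo


@pytest.fixture(scope="session")
def dataset():
    return thermo.default_thermo_dataset()


@pytest.fixture(scope="session")
def phases():
    return nica.default_phases()


@pytest.fixture(scope="session")
def seawater():
    return thermo.seawater_major_ions(35.0, 10.0)


def single_group_phase(Qmax=1.0, logK_H=0.0, n_H=1.0, p=1.0, ions=None,
                       donnan_b=0.5, name="toy"):
    """A one-group NICA phase (second group degenerate)."""
    g = nica.NicaSiteGroup(Qmax=Qmax, logK_H=logK_H, n_H=n_H, p=p,
                           ions=ions or {})
    pad = nica.NicaSiteGroup(Qmax=0.0, logK_H=0.0, n_H=1.0, p=1.0, ions={})
    return nica.NicaDonnanPhase(name, (g, pad), donnan_b)


def random_problem(rng, phases, with_sid=False, allow_mineral=True,
                   compute_affinity=False):
    """One random speciation problem over the study's condition ranges."""
    from fespec.engine import SpeciationProblem

    sid = None
    if with_sid:
        sid = phases["siderophore"].with_total(rng.uniform(0.0, 425e-12))
    return SpeciationProblem(
        total_fe=10 ** rng.uniform(-12.0, -7.0),
        pH_total=rng.uniform(7.2, 8.2),
        T=rng.uniform(1.6, 16.0),
        S=rng.uniform(34.0, 35.5),
        dom=phases["dom"].with_mass(rng.uniform(0.0, 5e-6)),
        pom=phases["pom"].with_mass(rng.uniform(0.0, 5e-8)),
        siderophore=sid,
        allow_mineral=allow_mineral,
        compute_affinity=compute_affinity,
    )
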