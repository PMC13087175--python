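"""Occupied-site effective affinities shrink as the Fe load grows.

Binding sites are occupied in decreasing order of affinity, so the
occupation-weighted mean log10 K' of Fe-occupied DOM sites falls as total
Fe rises — the signature of organic-matter binding-site heterogeneity that
a one- or two-ligand model cannot produce.
"""

import numpy as np

from fespec import SpeciationProblem, default_phases, solve_equilibrium
from fespec.transect import dom_from_doc

phases = default_phases()
dom = phases["dom"].with_mass(float(dom_from_doc(42.0)))

print(f"{'total Fe (nmol/L)':>18}{'Fe-prime (pmol/L)':>20}{'log10 K_FeDOM':>15}")
for total in np.geomspace(0.05e-9, 10e-9, 7):
    res = solve_equilibrium(
        SpeciationProblem(total_fe=total, pH_total=7.85, T=4.0, S=34.6, dom=dom)
    )
    rep = res.affinity["DOM"]
    print(f"{total * 1e9:>18.3f}{res.fe_prime * 1e12:>20.5g}{rep.mean_logK:>15.2f}")

print("\nThe mean effective affinity is monotone non-increasing in the load,")
print("while Fe' rises over many decades for a ~200-fold change in total Fe:")
print("both are direct consequences of the bimodal Sips site distribution.")
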