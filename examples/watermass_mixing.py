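"""Water-mass decomposition (eOMPA) of a constructed deep-Pacific sample.

Builds a sample as a known mixture of AAIW, UCDW and PDW plus a planted
remineralisation extent, then inverts it: the solver recovers the fractions
and the phosphate-equivalent remineralisation dP through the Redfield vector
(0, 0, -170, 1, 16, 40).
"""

from fespec.ompa import default_endmembers, solve_mixing
from fespec.synthetic import generate_watermass_mixture

ems = default_endmembers()
true_fracs = [0.0, 0.0, 0.45, 0.35, 0.20, 0.0]  # AAIW/UCDW/PDW blend
sample = generate_watermass_mixture(ems, true_fracs, delta_p=0.25)

sol = solve_mixing(sample, ems)
print("water mass   true   recovered")
for em, t in zip(ems, true_fracs):
    print(f"{em.name:<10}{t:>7.2f}{sol.fractions[em.name]:>12.6f}")
print(f"remineralisation dP: planted 0.25, recovered {sol.delta_p:.6f} umol/kg")
print(f"weighted residual norm: {sol.residual_norm:.2e}")
print("\nNoiseless convex combinations are recovered to machine precision;")
print("on real samples the residual norm flags where the six endmembers")
print("cannot explain the hydrography.")
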