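"""Effect of switching the four pathways on and off for one Fe-rich sample.

Near a hydrothermal source (total labile Fe 11.5 nmol/L) the predicted
inorganic Fe' depends strongly on which sinks are allowed to compete:
DOM binding alone leaves Fe' high, siderophores trim it slightly, the
mineral cap removes the supersaturated excess into authFeOH, and POM
binding adds a small particulate-organic pool.
"""

from fespec import PathwayConfig, SampleConditions, run_pathways
from fespec.transect import dom_from_doc, pom_from_tpp

pom_mass, _ = pom_from_tpp(2.0)
sample = SampleConditions(
    dfe_obs=9.5e-9, lpfe_obs=2.0e-9, pH_total=7.78, T=2.2, S=34.68,
    dom_mass=float(dom_from_doc(40.0)), pom_mass=float(pom_mass),
    siderophore_total=20e-12,
)

print(f"{'pathways':<16}{'total Fe':>9}{'Fe-prime':>10}{'authFeOH':>10}"
      f"{'FePOM':>8}   (nmol/L)")
for combo in (("p1",), ("p1", "p2"), ("p1", "p2", "p3"), ("p1", "p2", "p3", "p4")):
    pred = run_pathways(sample, PathwayConfig(frozenset(combo)))
    r = pred.result
    print(f"{'+'.join(combo):<16}{pred.total_fe * 1e9:>9.2f}"
          f"{r.fe_prime * 1e9:>10.4f}{r.auth_feoh * 1e9:>10.3f}"
          f"{r.fe_pom * 1e9:>8.4f}")

print("\nAdding a pathway never raises Fe' (each is a competing sink).")
print("Without the mineral (rows 1-2) Fe' exceeds the authFeOH solubility;")
print("with p3 the excess precipitates and Fe' sits exactly at the cap.")
print("Pathway p4 uses DFe+LPFe as the total and partitions it freshly.")
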