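# Default thermodynamic dataset for inorganic Fe(III) chemistry in seawater.
#
# PLACEHOLDER CONSTANTS: the hydrolysis constants, reaction enthalpies and the
# ferrihydrite solubility product below are representative literature-magnitude
# values for a NaCl-like medium at 298.15 K / I = 0.  They are shipped so the
# package runs out of the box; a study-specific constant set can be supplied
# through the same schema and overrides this file.  Enthalpies are chosen so
# that the apparent Fe' solubility increases as both temperature and pH
# decrease over the subsurface-seawater window (pH_tot 7.2-8.2, 1.6-16 degC),
# the behaviour established for amorphous ferric hydroxides in saline media.
#
# Schema: components (name, charge), reactions (product, charge, stoichiometry
# over components with signed counts, log10K_ref at 298.15 K, deltaH in J/mol),
# minerals (name, logKs_ref for  Fe(OH)3(s) + 3H+ = Fe3+ + 3H2O , deltaH).

components:
  - {name: Fe3, charge: 3}
  - {name: H, charge: 1}
  - {name: Mg, charge: 2}
  - {name: Ca, charge: 2}
  - {name: Na, charge: 1}
  - {name: K, charge: 1}
  - {name: Cl, charge: -1}
  - {name: SO4, charge: -2}

reactions:
  # Fe3+ + n H2O = Fe(OH)n^(3-n) + n H+   (log10 *beta_n at 298.15 K)
  - product: FeOH
    charge: 2
    stoichiometry: {Fe3: 1, H: -1}
    log10K_ref: -2.19
    deltaH: 43000.0
  - product: FeOH2
    charge: 1
    stoichiometry: {Fe3: 1, H: -2}
    log10K_ref: -5.76
    deltaH: 71600.0
  - product: FeOH3
    charge: 0
    stoichiometry: {Fe3: 1, H: -3}
    log10K_ref: -13.60
    deltaH: 103800.0
  - product: FeOH4
    charge: -1
    stoichiometry: {Fe3: 1, H: -4}
    log10K_ref: -22.50
    deltaH: 133500.0

minerals:
  - name: authFeOH
    # Fe(OH)3(s) + 3 H+ = Fe3+ + 3 H2O ; amorphous / ferrihydrite-like phase
    logKs_ref: 3.2
    deltaH: -150000.0
    medium: "NaCl-compatible placeholder parameterisation"
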