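# Default NICA-Donnan binding phases and the discrete siderophore ligand.
#
# PLACEHOLDER PARAMETERS: the marine-DOM Fe parameter set used for the South
# Pacific is deposited externally and not bundled here; the DOM block below is
# a generic fulvic-acid-like set and the POM block a generic humic-acid-like
# set with the total site density reduced to 1 mol binding site / kg and a 3:1
# low-affinity : high-affinity split, the construction used for marine
# particulate organic matter.  Supply a study parameter file with the same
# schema to override.
#
# Per phase: donnan_b (empirical Donnan-volume coefficient) and exactly two
# site groups, each with Qmax (mol sites/kg), logK_H (median proton affinity),
# n_H, p (generic heterogeneity, 0-1], and per-ion {logK, n}.

dom:
  donnan_b: 0.57
  groups:
    - Qmax: 5.88          # low-affinity, carboxylic-type
      logK_H: 2.34
      n_H: 0.66
      p: 0.59
      ions:
        Mg:  {logK: -2.10, n: 0.85}
        Ca:  {logK: -2.13, n: 0.85}
        Fe3: {logK: 4.00,  n: 0.80}
    - Qmax: 1.86          # high-affinity, phenolic-type
      logK_H: 8.60
      n_H: 0.76
      p: 0.70
      ions:
        Mg:  {logK: -2.40, n: 0.80}
        Ca:  {logK: -3.00, n: 0.80}
        Fe3: {logK: 12.00, n: 0.40}

pom:
  donnan_b: 0.49
  groups:
    - Qmax: 0.75          # 3:1 split of 1 mol sites/kg, low-affinity group
      logK_H: 2.93
      n_H: 0.81
      p: 0.62
      ions:
        Mg:  {logK: -0.60, n: 0.77}
        Ca:  {logK: -1.37, n: 0.78}
        Fe3: {logK: 3.00,  n: 0.80}
    - Qmax: 0.25          # high-affinity group
      logK_H: 8.00
      n_H: 0.63
      p: 0.41
      ions:
        Mg:  {logK: 0.60,  n: 0.59}
        Ca:  {logK: -0.43, n: 0.75}
        Fe3: {logK: 16.00, n: 0.40}

siderophore:
  name: "ferrioxamine B proxy"
  # stepwise protonation constants of the fully deprotonated ligand
  logK_protonation: [10.84, 9.46, 9.00, 8.30]
  logK_Mg: 4.30
  logK_Ca: 2.64
  logK_Fe: 30.60
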