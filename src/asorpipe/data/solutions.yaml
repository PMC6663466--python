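# Standard whole-cell solutions for acid-activated chloride current work.
# Concentrations are free-ion totals in mM, summed over all salts in the
# recipe (chelators, buffers and sugars that contribute no permeant ion at
# these pH values are omitted).  measured_ljp_mv is the experimentally
# determined liquid junction potential of the bath against the NMDG-Cl
# reference pipette, used for ion-selectivity experiments.

standard_pipette_CsCl:
  # 150 CsCl, 10 EGTA, 10 HEPES, 5 MgCl2, pH 7.2 (CsOH)
  composition: {Cs: 150, Mg: 5, Cl: 160}
  ph: 7.2

bath_pH7.4:
  # 145 NaCl, 5 KCl, 1 MgCl2, 2 CaCl2, 10 glucose, 10 HEPES, pH 7.4 (NaOH)
  composition: {Na: 145, K: 5, Mg: 1, Ca: 2, Cl: 156}
  ph: 7.4

bath_pH4.8_citrate:
  # as bath_pH7.4 but buffered with 5 citrate instead of HEPES
  composition: {Na: 145, K: 5, Mg: 1, Ca: 2, Cl: 156, citrate: 5}
  ph: 4.8

NMDG-Cl_pipette:
  # 140 NMDG-Cl, 10 EGTA, 10 HEPES, 5 MgCl2, pH 7.2 (NMDG-OH)
  composition: {NMDG: 140, Mg: 5, Cl: 150}
  ph: 7.2

selectivity_bath_pH5.25:
  # 150 NaCl, 2 Ca(OH)2, 1 EGTA, 5 citric acid, pH 5.25 (NMDG-OH)
  composition: {Na: 150, Ca: 2, Cl: 150, citrate: 5}
  ph: 5.25
  measured_ljp_mv: 4.5

NaI_bath:
  # NaCl of the selectivity bath replaced equimolarly by NaI
  composition: {Na: 150, Ca: 2, I: 150, citrate: 5}
  ph: 5.25
  measured_ljp_mv: 4.3

Na2SO4_bath:
  # NaCl of the selectivity bath replaced by 100 Na2SO4
  composition: {Na: 200, Ca: 2, SO4: 100, citrate: 5}
  ph: 5.25
  measured_ljp_mv: 9.5
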