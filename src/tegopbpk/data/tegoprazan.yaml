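# Tegoprazan (parent compound) — final model parameter set.
# Clearances: recombinant-CYP intrinsic clearances split by product
# (µL/min/pmol enzyme); renal elimination as total plasma clearance.
# fm_targets_percent is the pathway apportionment (percent of an oral dose)
# that the enzyme-abundance calibration reproduces.
name: tegoprazan
molecular_weight_g_mol: 387.38
lipophilicity_logp: 1.75
fraction_unbound_plasma: 0.087
solubility_mg_L: 45.3
pka:
  - {value: 5.20, type: base}
  - {value: 12.0, type: acid}
specific_intestinal_permeability_cm_s: 1.16e-6
specific_organ_permeability_cm_s: 1.15e-4   # carried but inert: distribution is flow-limited
renal_plasma_clearance_mL_min_kg: 0.297
metabolism:
  intrinsic_clearance_uL_min_pmol:
    CYP3A4_to_M1: 9.29e-3
    CYP3A4_to_other: 0.236
    CYP2C19_to_M1: 0.0921
    CYP2C19_to_other: 0.242
  # In vitro recombinant-CYP values and ISEFs behind the initial estimates:
  # 0.855 (CYP3A4) and 0.614 (CYP2C19) µL/min/pmol, ISEF 0.21 and 0.25.
  in_vitro_clint_uL_min_pmol: {CYP3A4: 0.855, CYP2C19: 0.614}
  isef: {CYP3A4: 0.21, CYP2C19: 0.25}
  fm_targets_percent: {CYP3A4: 71.6, CYP2C19: 20.2, renal: 7.82}
dissolution:
  fasted: {t50_h: 0.942, shape: 0.990}
  fed: {t50_h: 4.23, shape: 0.502}
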