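# Rifampicin — CYP3A4 inducer (perpetrator).  Induction of de novo enzyme
# synthesis with an Emax model; Emax 9 and EC50 0.34 µmol/L (unbound) as
# used by open-source PBPK perpetrator libraries (OSP rifampicin model).
# Own kinetics: simplified one-compartment oral model matching reported
# rifampicin exposure (600 mg: Cmax ~10 µg/mL, t1/2 ~5 h).
name: rifampicin
mechanism: induction
target_enzyme: CYP3A4
emax: 9.0
ec50_umol_L: 0.34
own_kinetics:
  model: one_compartment_oral
  ka_per_h: 1.15
  volume_L: 55.0
  clearance_L_per_h: 7.0
  bioavailability: 0.93
  fu: 0.17
  molecular_weight_g_mol: 822.94
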