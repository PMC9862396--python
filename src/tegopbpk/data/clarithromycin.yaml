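# Clarithromycin — CYP3A4 mechanism-based inactivator (perpetrator).
# Inactivation constants from in vitro human liver microsome work
# (Ito et al., Drug Metab Dispos 2003: KI 5.49 µmol/L, kinact 0.042/min)
# as adopted by open-source PBPK perpetrator libraries.
# Own kinetics: simplified one-compartment oral model matching reported
# clarithromycin exposure (500 mg: Cmax ~2.3 µg/mL, t1/2 ~4 h); this is a
# deliberate reduction of the full whole-body perpetrator model.
name: clarithromycin
mechanism: mbi
target_enzyme: CYP3A4
ki_umol_L: 5.49
kinact_per_h: 2.52
own_kinetics:
  model: one_compartment_oral
  ka_per_h: 0.8
  volume_L: 120.0
  clearance_L_per_h: 22.0
  bioavailability: 0.55
  fu: 0.30
  molecular_weight_g_mol: 747.95
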