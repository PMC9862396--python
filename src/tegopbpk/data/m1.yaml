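# M1 (desmethyl tegoprazan), the major metabolite.  Formed from the parent
# by both CYP3A4 and CYP2C19; eliminated by a lumped total hepatic plasma
# clearance (its own CYP3A4-mediated elimination is deliberately not
# modelled).  Solubility is a nominal assumed value; M1 is never dosed.
name: M1
molecular_weight_g_mol: 373.40
lipophilicity_logp: 1.75          # constrained equal to the parent during fitting
fraction_unbound_plasma: 0.01
solubility_mg_L: 1.0e-3           # 1 ng/mL, assumed
pka:
  - {value: 5.35, type: base}
total_hepatic_plasma_clearance_mL_min_kg: 0.140
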