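# Gastrointestinal segment constants: luminal fluid volume, baseline pH,
# first-order transit rate, geometric surface area and the effective-area
# multiplier (villi/microvilli amplification) applied to permeability-driven
# uptake.  Stomach absorbs negligibly (area 0).  Minimal segmentation:
# stomach + 4 small-intestinal segments + colon.
segments:
  - {name: stomach,        volume_L: 0.05, pH: 1.5, transit_per_h: 2.77, area_cm2: 200.0,  area_multiplier: 0.0}
  - {name: duodenum,       volume_L: 0.10, pH: 6.0, transit_per_h: 6.00, area_cm2: 200.0,  area_multiplier: 500.0}
  - {name: jejunum_upper,  volume_L: 0.25, pH: 6.5, transit_per_h: 0.78, area_cm2: 600.0,  area_multiplier: 500.0}
  - {name: jejunum_lower,  volume_L: 0.25, pH: 7.0, transit_per_h: 0.78, area_cm2: 600.0,  area_multiplier: 500.0}
  - {name: ileum,          volume_L: 0.25, pH: 7.4, transit_per_h: 0.78, area_cm2: 600.0,  area_multiplier: 500.0}
  - {name: colon,          volume_L: 0.30, pH: 6.5, transit_per_h: 0.06, area_cm2: 1000.0, area_multiplier: 100.0}
meal:
  gastric_pH_peak: 5.5
  pH_decay_halflife_h: 0.75
  emptying_multiplier: 0.25
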