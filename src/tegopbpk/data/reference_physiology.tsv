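# Reference adult male physiology (73.5 kg, cardiac output 390 L/h).
# Organ volumes (L), regional blood flows (L/h) and tissue composition
# fractions (water / neutral lipid / phospholipid / protein) assembled from
# standard ICRP-type reference tables and tissue-composition compilations
# used by Poulin-Theil-family partition methods.  "bone" is the skeletal
# composite including marrow, hence its water/lipid content.
# liver flow is the hepatic ARTERY only; portal inflow (gut + spleen) is
# added by the circulation model. lung receives total cardiac output and is
# excluded from the flow-conservation sum.
organ	volume_L	flow_L_per_h	f_water	f_neutral_lipid	f_phospholipid	f_protein
adipose	14.00	19.50	0.180	0.7900	0.0020	0.020
bone	10.00	19.50	0.450	0.0800	0.0011	0.200
brain	1.45	46.80	0.770	0.0510	0.0565	0.080
gut	1.20	58.50	0.718	0.0487	0.0163	0.150
heart	0.33	15.60	0.758	0.0115	0.0166	0.160
kidney	0.31	74.10	0.783	0.0207	0.0162	0.160
liver	1.80	25.35	0.751	0.0348	0.0252	0.180
muscle	29.00	66.30	0.760	0.0238	0.0072	0.190
skin	3.30	19.50	0.718	0.0284	0.0111	0.250
spleen	0.19	7.80	0.788	0.0201	0.0198	0.180
rest	4.00	37.05	0.760	0.0400	0.0100	0.150
lung	0.50	390.00	0.811	0.0030	0.0090	0.150
venous_blood	3.70	0.00	0.830	0.0017	0.0021	0.170
arterial_blood	1.60	0.00	0.830	0.0017	0.0021	0.170
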