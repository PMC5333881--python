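# Three-element Windkessel (RCR) parameters per outlet. Resistances in
# 1e9 kg/(m^4 s), compliance in 1e-9 m^4 s^2/kg. R_prox and C are
# age-invariant; R_dist is tabulated per age (the only parameter that rises
# with aging, reproducing the age-related MAP increase).
# The four iliac outlets print a single distal resistance; it is taken as
# age-invariant (the source table's iliac rows carry fewer columns than the
# others, an ambiguity flagged here).
outlet,r_prox,r_dist_40,r_dist_60,r_dist_75,compliance
right_subclavian,0.20,1.60,1.66,1.75,1.68
left_subclavian,0.18,1.53,1.58,1.68,1.75
right_carotid,0.23,1.91,1.98,2.09,1.40
left_carotid,0.22,1.80,1.86,1.97,1.49
right_renal,0.24,1.12,1.16,1.24,2.43
left_renal,0.25,1.15,1.20,1.27,2.36
celiac,0.35,1.53,1.59,1.70,1.78
gastric,1.20,5.59,5.81,6.18,0.49
splenic,0.55,2.50,2.60,2.76,1.09
superior_mesenteric,0.23,0.60,0.63,0.67,4.65
inferior_mesenteric,1.40,3.82,3.99,4.28,0.73
right_ext_iliac,0.08,1.49,1.49,1.49,2.15
right_int_iliac,0.29,5.50,5.50,5.50,0.56
left_ext_iliac,0.08,1.49,1.49,1.49,2.15
left_int_iliac,0.30,5.45,5.45,5.45,0.56
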