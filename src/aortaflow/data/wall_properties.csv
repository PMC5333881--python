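# Regional aortic wall properties at three stations (ATA/DTA/IAA) for four age
# groups. Inner radius and wall thickness in mm, MAP and EP in mmHg, stretches
# dimensionless, biaxial material stiffness (circumferential K_tt, axial K_zz)
# in MPa, linearized at transmural pressure TP = MAP - EP.
# The 30 yo row carries geometry and MAP only (no linearized stiffness).
age,station,radius_mm,thickness_mm,map_mmhg,ep_mmhg,axial_stretch,circ_stretch,k_tt_mpa,k_zz_mpa
30,ATA,13.2,1.80,89,,,,,
30,DTA,9.60,1.76,89,,,,,
30,IAA,7.81,1.14,91,,,,,
40,ATA,14.07,2.00,93,7,1.15,1.34,0.40,0.28
40,DTA,11.63,1.70,93,2,1.17,1.24,0.50,0.46
40,IAA,8.24,1.05,95,0,1.23,1.24,1.46,1.30
60,ATA,16.13,2.45,95,17,1.08,1.22,0.75,0.27
60,DTA,12.08,1.90,95,12,1.09,1.21,0.71,0.64
60,IAA,8.27,1.50,97,0,1.09,1.12,1.66,1.51
75,ATA,16.25,2.90,102,15,1.03,1.14,0.91,0.41
75,DTA,12.71,2.15,102,10,1.03,1.22,1.02,0.58
75,IAA,8.98,1.92,105,0,1.04,1.01,2.14,1.97
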