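# Baseline murine umbilical-artery model parameters.
# Geometry: unloaded inner / interface / outer radius (um), loaded axial stretch.
A_um: 161.77
B_um: 206.86
C_um: 236.92
lambda_z: 1.28
# Layer neo-Hookean (GAG/matrix) shear moduli: inner (1), outer (2) tunica media.
mu1_kPa: 3.0
mu2_kPa: 0.1
# Outer-layer fiber families: 1 axial, 2 circumferential, 3/4 symmetric diagonal.
c1_1_kPa: 0.013
c2_1: 11.65
eta_1_deg: 0.0
c1_2_kPa: 2.66
c2_2: 1.20
eta_2_deg: 90.0
c1_3_kPa: 3.04
c2_3: 4.23
eta_3_deg: 41.92
c1_4_kPa: 3.04
c2_4: 4.23
eta_4_deg: -41.92
# Smooth-muscle tone: contractile stretch window; T_act set per simulation.
lambda_m: 2.5
lambda_0: 0.2
T_act_kPa: 0.0
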