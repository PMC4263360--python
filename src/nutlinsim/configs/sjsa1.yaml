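# SJSA-1-like cell line: strong Mdm2 gene amplification (50 copies) and a
# much lower p53 viability threshold, compensating the lower p53 levels
# imposed by the abundant Mdm2.  All other constants equal the RKO-like
# calibration (rko.yaml), which documents units and provenance.
G_p53: 2
G_mdm2: 50
G_pten: 2
q0_p53: 1.0e-4
q0_mdm2: 1.0e-4
q0_pten: 1.0e-4
q1_p53: 1.0e-4
q1_mdm2: 1.0e-9
q1_pten: 1.0e-9
activation_exponent: 2.0
activation_uses_total_phospho: false
s_mrna_p53: 0.03
s_mrna_mdm2: 0.02
s_mrna_pten: 0.03
d_mrna_p53: 3.0e-4
d_mrna_mdm2: 2.0e-4
d_mrna_pten: 3.0e-4
s_prot_p53: 0.03
s_prot_mdm2: 0.03
s_prot_pten: 0.03
k_phos_p53: 3.0e-4
k_dephos_p53: 6.0e-4
a1: 3.0e-5
a1p: 3.0e-7
d1: 1.0e-4
k_ub: 1.0e-2
k_deub: 1.0e-3
d_p53_basal: 3.0e-5
d_p53_biub: 1.0e-3
k_phos_m2: 3.0e-8
k_dephos_m2: 3.0e-3
i_m2: 1.0e-3
e_m2: 5.0e-4
d_m2: 1.0e-4
complex_degradation: true
k_pip: 1.0e-3
k_hyd: 3.0e-8
k_akt: 1.0e-8
k_deakt: 1.0e-3
d_pten: 3.0e-5
PIP_tot: 1.0e5
Akt_tot: 1.0e5
pten_enabled: true
b1: 1.0e-7
u1: 1.0e-3
i1: 600.0
e1: 5.0e-4
Ka_plasma: 0.2
Bmax_plasma: 400.0
k_a: 1.0
k_e: 5.0
alpha: 1.7
Ka_medium: 0.04
Bmax_medium: 100.0
P_th: 1400.0          # much lower threshold than the RKO-like fixture
tau: 1.0
t_assess: 48.0
recovery_mean_h: 0.0
viability_free_only: false
V: 2.0e-12
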