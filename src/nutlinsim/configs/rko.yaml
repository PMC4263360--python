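# RKO-like cell line: no Mdm2 amplification (2 gene copies per gene).
# Rates are per second unless noted.  Intracellular species in molecules
# per cell (p53 in dimer units); extracellular Nutlin in uM.
# Values are the package calibration: chosen to reproduce a low, noisy
# drug-free p53 baseline, a graded 48-h in-vitro dose-response over
# ~1-30 uM total Nutlin, and the post-bolus nuclear Mdm2 dip-and-recovery
# peaking ~10 h after an oral dose.  The viability threshold P_th is a
# calibration output, not a measured constant.

# gene copies and ON/OFF switching
G_p53: 2
G_mdm2: 2
G_pten: 2
q0_p53: 1.0e-4        # 1/s per active copy
q0_mdm2: 1.0e-4
q0_pten: 1.0e-4
q1_p53: 1.0e-4        # 1/s per inactive copy (constitutive)
q1_mdm2: 1.0e-9       # 1/s per inactive copy per (phospho-p53 dimer)^2
q1_pten: 1.0e-9
activation_exponent: 2.0
activation_uses_total_phospho: false

# transcription (molecules/s per active copy), mRNA decay, translation (1/s per mRNA)
s_mrna_p53: 0.03
s_mrna_mdm2: 0.02
s_mrna_pten: 0.03
d_mrna_p53: 3.0e-4
d_mrna_mdm2: 2.0e-4
d_mrna_pten: 3.0e-4
s_prot_p53: 0.03
s_prot_mdm2: 0.03
s_prot_pten: 0.03

# p53 nuclear module
k_phos_p53: 3.0e-4
k_dephos_p53: 6.0e-4
a1: 3.0e-5            # 1/s per molecule, Mdm2 + p53 association
a1p: 3.0e-7           # reduced association for phospho-p53 (protection)
d1: 1.0e-4
k_ub: 1.0e-2          # in-complex ubiquitin transfer
k_deub: 1.0e-3        # HAUSP (constant level folded in)
d_p53_basal: 3.0e-5
d_p53_biub: 1.0e-3    # proxy for fast poly-ubiquitin degradation

# Mdm2 module
k_phos_m2: 3.0e-8     # 1/s per phospho-Akt molecule
k_dephos_m2: 3.0e-3
i_m2: 1.0e-3          # nuclear import
e_m2: 5.0e-4          # nuclear export
d_m2: 1.0e-4
complex_degradation: true

# PTEN-PIP3-Akt module
k_pip: 1.0e-3
k_hyd: 3.0e-8         # 1/s per PTEN molecule
k_akt: 1.0e-8         # 1/s per PIP3 molecule
k_deakt: 1.0e-3
d_pten: 3.0e-5
PIP_tot: 1.0e5        # molecules, conserved
Akt_tot: 1.0e5        # molecules, conserved
pten_enabled: true

# Nutlin pharmacodynamics
b1: 1.0e-7            # 1/s per molecule (Kd = u1/b1 = 1e4 molecules ~ 8 nM)
u1: 1.0e-3
i1: 600.0             # molecules/s per uM extracellular free drug
e1: 5.0e-4            # efflux, 1/s

# pharmacokinetics (oral, mouse); k_a/k_e in 1/h, alpha in uM per mg/kg
Ka_plasma: 0.2        # 1/uM
Bmax_plasma: 400.0    # uM
k_a: 1.0
k_e: 5.0
alpha: 1.7
Ka_medium: 0.04       # culture medium binding (weaker than plasma)
Bmax_medium: 100.0

# viability rule and geometry
P_th: 4500.0          # nuclear phospho-p53 dimers
tau: 1.0              # h
t_assess: 48.0        # h (in-vitro default; in-vivo runs use 120 h)
recovery_mean_h: 0.0  # recovery from arrest disabled within the assessment window
viability_free_only: false
V: 2.0e-12            # L
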