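# Methods

## Model

`nutlinsim` simulates single tumour cells with wild-type p53 responding to
the Mdm2 inhibitor Nutlin.  The state combines

* **discrete gene activity** — each of the p53, Mdm2 and PTEN genes has a
  fixed copy number; every copy is an independent ON/OFF telegraph switch —
  with
* **continuous molecular amounts** — mRNAs, all p53 forms, Mdm2 pools, the
  PTEN–PIP3–Akt module and intracellular drug, evolved by mass-action ODEs.

Transcription factors act on the *probability* that a gene copy is ON, not
on the transcription rate: a copy deactivates at a constant rate `q0` and,
for the p53-target genes (Mdm2, PTEN), activates at `q1 · P_active²`, where
`P_active` is the number of free phosphorylated p53 dimers.  The square
reflects tetramer formation at the DNA-binding step (two dimers); p53 binds
DNA with high cooperativity, and a configuration switch
(`activation_exponent: 1.8`) exposes the measured Hill exponent instead.
The p53 gene activates constitutively.  Gene switching is the model's only
noise source; because every downstream reaction is driven by gene activity,
all species are nonetheless stochastic processes.

p53 is counted in dimer units and synthesised directly into the nucleus
(cytoplasmic p53 is neglected).  The negative feedback is mechanistic:
nuclear phospho-Mdm2 binds p53 (association `a1`, reduced to `a1p` for
phospho-p53 — phosphorylation protects p53 through weaker binding, not a
changed degradation rate), transfers a ubiquitin within the complex
(`k_ub`) and is released.  Only mono- and bi-ubiquitination are tracked;
the bi-ubiquitinated forms degrade fast (`d_p53_biub`) as a proxy for
poly-ubiquitin-mediated degradation, and HAUSP removes ubiquitins at
`k_deub` (HAUSP level constant, folded into the constant).  The positive
feedback runs p53 → PTEN → PIP3 ↓ → active Akt ↓ → less Mdm2
phosphorylation → less nuclear Mdm2.  PIP2+PIP3 and total Akt are conserved
by construction (the complementary pools are implicit).  PTEN is
cytoplasm-only.  PIP3–Akt coupling uses fast mass action; the constants put
it near equilibrium on the slow timescale, and a quasi-equilibrium variant
was considered and rejected as an extra code path with no observable
difference at the default rates.

Nutlin inactivates each of the three Mdm2 pools (cytoplasmic,
cytoplasmic-phospho, nuclear-phospho) by occupying the p53-binding pocket;
inactive pools still (de)phosphorylate, shuttle and degrade.  One drug
molecule rides on each inactive Mdm2; degradation of an inactive Mdm2
destroys its cargo (no recycling to the free pool).  Binding constants are
shared across the three pools — no pool-specific measurements exist to
justify more parameters.  Uptake is linear in the extracellular *free*
concentration (`i1`, which absorbs the µM→molecules conversion), efflux
linear in the intracellular free amount.

Extracellular drug: plasma and culture-medium proteins bind Nutlin
saturably and in quasi-steady state, so free concentration solves the
quadratic `N_tot = x + Bmax·Ka·x/(1+Ka·x)`.  Oral delivery in mice is
one-compartment with exponential gastro-enteric release (`k_a`) and linear
elimination of free drug only (`k_e`); `alpha` converts mg/kg to µM.
In-vitro exposures hold the total medium concentration constant and convert
it once to free drug.

**Viability rule.**  A cell is scored non-viable (arrest or apoptosis, in
the MTT sense) when nuclear phospho-p53 stays at or above a threshold
`P_th` for a contiguous interval of at least `tau` hours before the
assessment time (48 h in vitro, 120 h after the first in-vivo dose).  The
monitored signal includes phospho-p53 sequestered in Mdm2 complexes
(`viability_free_only` restricts it to free forms).  Two sub-`tau`
excursions separated by a gap do not trigger.  An optional recovery model
re-counts a triggered cell as viable when an exponential delay (mean
`recovery_mean_h`) elapses after the signal falls back below the threshold;
it is off by default — apoptosis dominates in the Mdm2-amplified line, and
arrest outlasts the 120 h window in the non-amplified one.

## Hybrid simulation algorithm

Between gene switches, all continuous species follow the combined ODE
(network + drug pharmacodynamics + exposure input), integrated with LSODA.
Switch times are sampled *exactly* for the inhomogeneous jump process: an
auxiliary state accumulates the total switching propensity
Λ(t) = ∫ λ(y(t)) dt along the solution, and the event fires when Λ reaches
an Exp(1) draw (located by the solver's root finder).  The channel — which
gene, which direction — is drawn proportionally to the per-channel
propensities at the event time; the gene count changes by ±1 and
integration restarts.  No thinning bound or tau-leap approximation is
involved; mRNA copy-number noise is deliberately absent (mRNA is an ODE
species), which is appropriate when burst noise from slow gene switching
dominates Poisson noise — the regime the default rates put the model in,
and the regime in which the test suite's SSA cross-check is run.

Reproducibility: each cell owns a PCG64 generator seeded `base_seed +
cell_index`; all draws (exponential targets, channel choices) come from it
in order, so a seed fixes the trajectory bit-for-bit.  The integrator also
restarts at fixed checkpoints (default 1 h) and at dose times; resuming
from the saved state and RNG state at a checkpoint therefore reproduces
the remainder of the run exactly, not merely to solver tolerance.

Numerics: default tolerances `rtol 1e-8`, `atol 1e-6` molecules for
single-cell work; population experiments default to `rtol 1e-6`,
`atol 1e-3`, which leaves population medians and viability calls unchanged
(checked against the strict setting) at roughly half the cost.  Output
grids are interpolated from dense solver output (default 0.1 h);
threshold crossings are located by linear interpolation on that grid.
States are clipped to zero at restart points to absorb solver-tolerance
undershoot.  Events landing in a zero-intensity region (a root located at
the boundary of vanishing propensity) are discarded and the clock re-drawn.

## Parameters and calibration

No published parameter table accompanies the mechanism description at this
level of detail, so the shipped fixtures are the package's own calibration,
documented per parameter in `configs/rko.yaml`.  Literature anchors fix
the orders of magnitude: gene dwell times of hours (`q0 = 1e-4 /s`),
mRNA half-lives of 0.6–1 h, protein half-lives of 2–9 h, a Nutlin–Mdm2
dissociation constant in the 10⁻⁸ M range (`u1/b1 = 1e4` molecules at the
2 pL cell volume), strong plasma protein binding (free fraction ~1% at low
total), and a mg/kg→µM conversion for a ~0.6 L/kg distribution volume.
Within those anchors the free constants were tuned once, using
deterministic mean-field runs plus small stochastic pilots, to reproduce
four qualitative behaviours and then frozen:

1. a low, fluctuating drug-free baseline of nuclear phospho-p53 whose
   1-h-sustained level stays well below the viability threshold;
2. a graded 48-h in-vitro dose-response with the viable/non-viable
   transition between ~3 and ~10 µM total Nutlin;
3. after an oral bolus, a sharp drop of active nuclear Mdm2 followed by an
   overshooting recovery peaking ~10 h post-dose, with a transient p53
   pulse preceding the Mdm2 peak;
4. a PTEN-dependent drug effect in the non-amplified (2-copy) fixture and
   a PTEN-insensitive one under 25-fold Mdm2 amplification.

The two fixtures differ only in the Mdm2 copy number (2 vs 50) and the
viability threshold (4500 vs 1400 dimers) — the amplified line needs a much
lower threshold to compensate for the p53 levels its abundant Mdm2
enforces.  The thresholds are calibration outputs, not measured constants.
`tau` defaults to 1 h; the viability calls are insensitive to halving it.

## What the simulations do and do not show

The populations are statistically identical cells: all variability is
intrinsic gene-switching noise.  Real dose-response variability also
contains extrinsic noise (cell size, cell-cycle phase, threshold
heterogeneity), transporter-mediated efflux, MDMX and Wip1 feedbacks, and
transcription-independent apoptosis — all deliberately out of scope.
Passing tests therefore validate the hybrid algorithm and the stated
mechanism, not quantitative agreement with any particular cell line;
viability percentages are calibration-conditional.

## Known limitations

* The p53 threshold is sharp; a noisy threshold would smooth the
  dose-response tails.
* Complex handling under degradation is a modelling choice: the p53 moiety
  degrades basally releasing Mdm2, while `complex_degradation: true` adds
  decay of the whole complex at the Mdm2 rate releasing nothing.
* The recovery model re-counts a cell at most once (first triggering
  excursion); re-arrest after recovery is not modelled.
* PK is single-compartment with the same binding parameters in plasma and
  tissue; distribution delays are not represented.
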