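"""State space, parameters and validation for the p53/Mdm2/PTEN–Nutlin model.

The model tracks a single tumour cell with three compartments (nucleus,
cytoplasm, extracellular space).  Gene copies switch ON/OFF stochastically
(telegraph process, see :mod:`nutlinsim.gene_switch`) while every other
reaction — transcription, translation, the p53–Mdm2 negative feedback with
explicit mono-/bi-ubiquitination, the PTEN–PIP3–Akt positive feedback, and
Nutlin binding — is deterministic mass action (:mod:`nutlinsim.network_odes`,
:mod:`nutlinsim.nutlin_pd`).

Unit conventions
----------------
* time: seconds internally; pharmacokinetic constants ``k_a``/``k_e`` are
  stated per hour and viability times (``tau``, ``t_assess``) in hours, as is
  customary for those quantities; conversions live in :mod:`nutlinsim.pk` and
  :mod:`nutlinsim.hybrid_engine`.
* intracellular species: molecules per cell.  p53 is counted in dimer units
  (one unit = one dimer): p53 is predominantly dimeric in the cell and binds
  DNA cooperatively as a tetramer (a pair of dimers).
* extracellular Nutlin: µM; the cell volume ``V`` converts between counts
  and concentrations where needed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SPECIES",
    "GENES",
    "ParameterSet",
    "CellState",
    "Event",
    "ResumeState",
    "Trajectory",
    "ParameterError",
    "ValidationError",
    "validate_parameters",
    "steady_state",
    "initial_state",
]


#: Continuous (ODE) species, in state-vector order.
SPECIES: tuple[str, ...] = (
    "R_p53", "R_mdm2", "R_pten",          # mRNAs
    "P", "P_u", "P_uu",                   # nuclear p53 dimers, unphosphorylated
    "P_p", "P_pu", "P_puu",               # nuclear p53 dimers, phosphorylated
    "C_P", "C_Pu", "C_Pp", "C_Ppu",       # p53·Mdm2 nuclear complexes
    "M2", "M2_p", "M2_pn",                # active Mdm2 (cyt, cyt-phos, nuc-phos)
    "M2_i", "M2_pi", "M2_pni",            # Nutlin-inactivated Mdm2
    "PTEN", "PIP3", "Akt_p",              # positive-feedback module
    "N_free",                             # intracellular free Nutlin
)

SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

GENES: tuple[str, ...] = ("p53", "mdm2", "pten")


class ParameterError(KeyError):
    """A required parameter is missing or unknown."""


class ValidationError(ValueError):
    """A parameter or state invariant is violated."""


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants, copy numbers, thresholds and PK constants.

    Defaults are the calibrated RKO-like fixture (2 Mdm2 gene copies); the
    SJSA-1-like fixture (50 copies, lower p53 threshold) ships as
    ``configs/sjsa1.yaml``.  Every value is overridable via config.
    """

    # --- gene copy numbers and switching -----------------------------------
    G_p53: int = 2                  # gene copies
    G_mdm2: int = 2                 # 2 for RKO-like, 50 for SJSA-1-like
    G_pten: int = 2
    q0_p53: float = 1.0e-4          # 1/s per active copy (deactivation)
    q0_mdm2: float = 1.0e-4
    q0_pten: float = 1.0e-4
    q1_p53: float = 1.0e-4          # 1/s per inactive copy (constitutive)
    q1_mdm2: float = 1.0e-9        # 1/s per copy per (dimer)^2
    q1_pten: float = 1.0e-9
    activation_exponent: float = 2.0    # tetramer = two dimers; 1.8 = Hill fit
    activation_uses_total_phospho: bool = False  # count complexed phospho-p53 too

    # --- transcription / translation ---------------------------------------
    s_mrna_p53: float = 0.03        # molecules/s per active copy
    s_mrna_mdm2: float = 0.02
    s_mrna_pten: float = 0.03
    d_mrna_p53: float = 3.0e-4      # 1/s
    d_mrna_mdm2: float = 2.0e-4
    d_mrna_pten: float = 3.0e-4
    s_prot_p53: float = 0.03        # 1/s per mRNA (yields dimer units for p53)
    s_prot_mdm2: float = 0.03
    s_prot_pten: float = 0.03

    # --- p53 nuclear module -------------------------------------------------
    k_phos_p53: float = 3.0e-4      # 1/s
    k_dephos_p53: float = 6.0e-4    # 1/s
    a1: float = 3.0e-5              # 1/s per molecule (Mdm2–p53 association)
    a1p: float = 3.0e-7             # reduced association for phospho-p53
    d1: float = 1.0e-4              # 1/s (complex dissociation)
    k_ub: float = 1.0e-2            # 1/s (in-complex ubiquitin transfer)
    k_deub: float = 1.0e-3          # 1/s (HAUSP, level folded in)
    d_p53_basal: float = 3.0e-5     # 1/s
    d_p53_biub: float = 1.0e-3      # 1/s; proxy for poly-ubiquitin degradation

    # --- Mdm2 module ---------------------------------------------------------
    k_phos_m2: float = 3.0e-8       # 1/s per phospho-Akt molecule
    k_dephos_m2: float = 3.0e-3     # 1/s
    i_m2: float = 1.0e-3            # 1/s nuclear import
    e_m2: float = 5.0e-4            # 1/s nuclear export
    d_m2: float = 1.0e-4            # 1/s
    complex_degradation: bool = True  # complexes decay as units at d_m2

    # --- PTEN–PIP3–Akt module ------------------------------------------------
    k_pip: float = 1.0e-3           # 1/s (PI3K acting on PIP2)
    k_hyd: float = 3.0e-8           # 1/s per PTEN molecule
    k_akt: float = 1.0e-8           # 1/s per PIP3 molecule
    k_deakt: float = 1.0e-3         # 1/s
    d_pten: float = 3.0e-5          # 1/s
    PIP_tot: float = 1.0e5          # molecules (PIP2 + PIP3, conserved)
    Akt_tot: float = 1.0e5          # molecules (conserved)

    # --- Nutlin pharmacodynamics --------------------------------------------
    b1: float = 1.0e-7              # 1/s per molecule (Nutlin–Mdm2 association)
    u1: float = 1.0e-3              # 1/s (dissociation)
    i1: float = 600.0               # molecules/s per µM extracellular (uptake)
    e1: float = 5.0e-4              # 1/s (efflux)

    # --- pharmacokinetics ----------------------------------------------------
    Ka_plasma: float = 0.2          # 1/µM equilibrium association constant
    Bmax_plasma: float = 400.0      # µM total plasma binding sites
    k_a: float = 1.0                # 1/h gastro-enteric release
    k_e: float = 5.0                # 1/h elimination of free drug
    alpha: float = 1.7              # µM per mg/kg (conversion incl. Vd)
    Ka_medium: float = 0.04         # 1/µM, culture-medium binding
    Bmax_medium: float = 100.0      # µM

    # --- viability rule and geometry ----------------------------------------
    P_th: float = 4500.0           # dimers of nuclear phospho-p53
    tau: float = 1.0                # h, minimum time over threshold
    t_assess: float = 48.0          # h
    recovery_mean_h: float = 0.0    # mean of exponential recovery delay; 0 = off
    viability_free_only: bool = False  # restrict signal to free phospho forms
    V: float = 2.0e-12              # L, cell volume
    pten_enabled: bool = True

    # ------------------------------------------------------------------

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "ParameterSet":
        """Build a parameter set from a flat key/value mapping.

        Config files are complete by contract: unknown keys and missing
        keys are both rejected, naming the offending parameter.
        """
        known = set(cls.field_names())
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {', '.join(unknown)}")
        missing = sorted(known - set(mapping))
        if missing:
            raise ParameterError(f"missing parameter(s): {', '.join(missing)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in mapping:
                raw = mapping[f.name]
                if f.type in ("int", int):
                    kwargs[f.name] = int(raw)  # type: ignore[arg-type]
                elif f.type in ("bool", bool):
                    kwargs[f.name] = bool(raw)
                else:
                    kwargs[f.name] = float(raw)  # type: ignore[arg-type]
        return validate_parameters(cls(**kwargs))

    def to_mapping(self) -> dict[str, object]:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "ParameterSet":
        return validate_parameters(dataclasses.replace(self, **kwargs))

    def gene_params(self, gene: str) -> tuple[int, float, float]:
        """(copies, q0, q1) for a gene id."""
        if gene not in GENES:
            raise ParameterError(f"unknown gene id: {gene!r}")
        return (
            getattr(self, f"G_{gene}"),
            getattr(self, f"q0_{gene}"),
            getattr(self, f"q1_{gene}"),
        )


def validate_parameters(params: ParameterSet | Mapping[str, object]) -> ParameterSet:
    """Check every parameter invariant; return the validated set.

    Raises :class:`ParameterError` for missing/unknown keys (mapping input)
    and :class:`ValidationError` naming the violated constraint.
    """
    if isinstance(params, Mapping):
        return ParameterSet.from_mapping(params)
    p = params
    for name in ("G_p53", "G_mdm2", "G_pten"):
        v = getattr(p, name)
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
    rate_fields = [
        f.name for f in dataclasses.fields(ParameterSet)
        if f.type in ("float", float)
    ]
    for name in rate_fields:
        v = getattr(p, name)
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
    if not p.d_p53_biub > p.d_p53_basal:
        raise ValidationError(
            "d_p53_biub must exceed d_p53_basal "
            f"(got {p.d_p53_biub} <= {p.d_p53_basal}): bi-ubiquitinated p53 "
            "stands in for fast poly-ubiquitin-mediated degradation"
        )
    if not p.a1p < p.a1:
        raise ValidationError(
            f"a1p must be < a1 (got {p.a1p} >= {p.a1}): phosphorylation "
            "protects p53 through a lower Mdm2 association rate"
        )
    if not p.PIP_tot > 0:
        raise ValidationError(f"PIP_tot must be > 0, got {p.PIP_tot}")
    if not p.Akt_tot > 0:
        raise ValidationError(f"Akt_tot must be > 0, got {p.Akt_tot}")
    if not p.P_th > 0:
        raise ValidationError(f"P_th must be > 0, got {p.P_th}")
    if not p.tau > 0:
        raise ValidationError(f"tau must be > 0, got {p.tau}")
    if not p.t_assess > p.tau:
        raise ValidationError(
            f"t_assess must exceed tau (got {p.t_assess} <= {p.tau})"
        )
    if not p.V > 0:
        raise ValidationError(f"V must be > 0, got {p.V}")
    return p


@dataclass
class CellState:
    """Full single-cell state: integer active gene copies + continuous amounts."""

    A_p53: int
    A_mdm2: int
    A_pten: int
    y: np.ndarray  # continuous species, order = SPECIES

    def __getitem__(self, name: str) -> float:
        return float(self.y[SPECIES_INDEX[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.y[SPECIES_INDEX[name]] = value

    @property
    def genes(self) -> tuple[int, int, int]:
        return (self.A_p53, self.A_mdm2, self.A_pten)

    def copy(self) -> "CellState":
        return CellState(self.A_p53, self.A_mdm2, self.A_pten, self.y.copy())

    def validate(self, params: ParameterSet, atol: float = 1e-6) -> None:
        for gene, a in zip(GENES, self.genes):
            g = getattr(params, f"G_{gene}")
            if not (0 <= a <= g):
                raise ValidationError(f"A_{gene}={a} outside [0, {g}]")
        if np.any(self.y < -atol):
            bad = SPECIES[int(np.argmin(self.y))]
            raise ValidationError(f"negative amount for {bad}: {self.y.min()}")
        if self["PIP3"] > params.PIP_tot * (1 + 1e-9) + atol:
            raise ValidationError("PIP3 exceeds PIP_tot")
        if self["Akt_p"] > params.Akt_tot * (1 + 1e-9) + atol:
            raise ValidationError("Akt_p exceeds Akt_tot")


@dataclass
class Event:
    """A discrete event along a trajectory."""

    time_h: float
    kind: str                  # "switch" | "dose" | "threshold"
    gene: str | None = None
    direction: int | None = None   # +1 activation, -1 deactivation
    info: dict = field(default_factory=dict)


@dataclass
class ResumeState:
    """Everything needed to continue a simulation bit-identically."""

    t_s: float
    y: np.ndarray              # continuous species at t_s
    genes: tuple[int, int, int]
    hazard_remaining: float    # E - Lambda accumulated in the open interval
    rng_state: dict


@dataclass
class Trajectory:
    """Time grid, state snapshots and event log of one simulated cell."""

    times_h: np.ndarray                  # strictly increasing, hours
    species: np.ndarray                  # (n_times, N_SPECIES)
    genes: np.ndarray                    # (n_times, 3) int
    events: list[Event]
    seed: int | None = None
    resume: ResumeState | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_h) <= 0):
            raise ValidationError("trajectory times must be strictly increasing")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.species[:, SPECIES_INDEX[name]]

    def nuclear_phospho_p53(self, free_only: bool = False) -> np.ndarray:
        """The viability signal: nuclear phospho-p53 (dimers).

        By default includes phospho-p53 sequestered in Mdm2 complexes; pass
        ``free_only=True`` for the free-forms-only variant.
        """
        sig = self["P_p"] + self["P_pu"] + self["P_puu"]
        if not free_only:
            sig = sig + self["C_Pp"] + self["C_Ppu"]
        return sig

    def nuclear_phospho_mdm2(self) -> np.ndarray:
        """Active + Nutlin-bound nuclear phospho-Mdm2."""
        return self["M2_pn"] + self["M2_pni"]


# ---------------------------------------------------------------------------
# Baseline (pre-treatment) state
# ---------------------------------------------------------------------------

def steady_state(
    params: ParameterSet,
    t_max_h: float = 2000.0,
    rtol: float = 1e-10,
    atol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic drug-free fixed point of the mean-field system.

    Gene activities are treated as continuous variables obeying the
    mean-field telegraph ODE dA/dt = act·(G−A) − q0·A, coupled to the full
    reaction network.  Returns ``(y, a)`` with ``y`` the continuous species
    and ``a`` the (fractional) expected active copies per gene.

    Raises :class:`ValidationError` with the residual norm if the long
    integration has not converged to a fixed point.
    """
    from scipy.integrate import solve_ivp

    from .network_odes import combined_rhs
    from .gene_switch import activation_propensity, deactivation_propensity

    def meanfield_rhs(t: float, z: np.ndarray) -> np.ndarray:
        y, a = z[:N_SPECIES], z[N_SPECIES:]
        dy = combined_rhs(y, a, params, n_ext=0.0)
        p_active = _p_active(y, params)
        da = np.empty(3)
        for k, gene in enumerate(GENES):
            g, q0, _ = params.gene_params(gene)
            ak = min(max(float(a[k]), 0.0), float(g))  # solver overshoot guard
            act = activation_propensity(gene, ak, g, p_active, params)
            da[k] = act - deactivation_propensity(ak, q0)
        return np.concatenate([dy, da])

    z0 = np.zeros(N_SPECIES + 3)
    # start genes half-active to avoid the absorbing all-zero start
    z0[N_SPECIES:] = [params.G_p53 / 2, params.G_mdm2 / 2, params.G_pten / 2]
    sol = solve_ivp(
        meanfield_rhs, (0.0, t_max_h * 3600.0), z0,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise ValidationError(f"steady-state integration failed: {sol.message}")
    z = sol.y[:, -1]
    res = meanfield_rhs(0.0, z)
    scale = np.linalg.norm(z) + 1.0
    if np.linalg.norm(res) * 3600.0 > 1e-4 * scale:
        raise ValidationError(
            "steady-state solve did not converge: residual norm "
            f"{np.linalg.norm(res):.3e} (state norm {scale:.3e})"
        )
    return z[:N_SPECIES], z[N_SPECIES:]


def _p_active(y: np.ndarray, params: ParameterSet) -> float:
    """Transcriptionally available phospho-p53 dimers (for gene activation)."""
    idx = SPECIES_INDEX
    p = y[idx["P_p"]] + y[idx["P_pu"]]
    if params.activation_uses_total_phospho:
        p = p + y[idx["P_puu"]] + y[idx["C_Pp"]] + y[idx["C_Ppu"]]
    return max(float(p), 0.0)


def initial_state(params: ParameterSet) -> CellState:
    """Pre-treatment baseline: deterministic steady state, genes rounded.

    Nutlin pools are zero (drug-naive cell).  Gene copies are set to the
    rounded expected number of active copies at the fixed point.
    """
    y, a = steady_state(params)
    y = np.maximum(y, 0.0)
    for name in ("N_free", "M2_i", "M2_pi", "M2_pni"):
        y[SPECIES_INDEX[name]] = 0.0
    genes = [int(round(ai)) for ai in a]
    genes = [min(max(g, 0), getattr(params, f"G_{name}"))
             for g, name in zip(genes, GENES)]
    state = CellState(genes[0], genes[1], genes[2], y)
    state.validate(params)
    return state
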