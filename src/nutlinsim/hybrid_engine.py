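"""Hybrid stochastic simulation: exact gene-switch sampling over the ODE flow.

Gene activation/deactivation is a jump process whose propensities depend on
the continuously evolving state (through transcriptionally active
phospho-p53).  Between jumps all other species follow the deterministic
reaction network.  Jump times are sampled exactly by the
integrated-propensity method: an auxiliary cumulative-hazard state
Λ(t) = ∫λ_total dt is integrated together with the system and the event
fires when Λ reaches an Exp(1) draw (located by the solver's root finder);
the switching channel is then chosen with probability proportional to the
per-channel propensities at the event time.

The integrator restarts at fixed checkpoints (default every hour), at dose
times and at events.  Because of this, resuming a run from the saved state
and RNG state at a checkpoint reproduces the remainder bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    GENES,
    N_SPECIES,
    CellState,
    Event,
    ParameterSet,
    ResumeState,
    Trajectory,
    _p_active,
    initial_state,
)
from .pk import BindingParams, DoseSchedule, PKResult, simulate_pk

__all__ = [
    "SimulationSpec",
    "PopulationSummary",
    "simulate_cell",
    "simulate_population",
]

_H = 3600.0  # seconds per hour


@dataclass
class SimulationSpec:
    """Everything one cell simulation needs.

    ``exposure`` is either a constant extracellular *free* Nutlin
    concentration (µM, the in-vitro mode) or a :class:`DoseSchedule`
    (in-vivo mode; the engine integrates the PK model with the plasma
    binding constants from ``params`` and feeds the free concentration to
    the cell).
    """

    params: ParameterSet
    exposure: float | DoseSchedule = 0.0
    t_end_h: float = 48.0
    grid_dt_h: float = 0.1        # output grid resolution
    seed: int = 0
    record_events: bool = True
    checkpoint_h: float = 1.0     # integrator restart interval (resume points)
    rtol: float = 1e-8
    atol: float = 1e-6            # molecules
    p_active_override: float | None = None  # freeze the activation signal
    initial: CellState | None = None        # default: baseline steady state

    def __post_init__(self) -> None:
        if self.t_end_h <= 0:
            raise ValueError("t_end_h must be > 0")
        if self.grid_dt_h <= 0:
            raise ValueError("grid_dt_h must be > 0")

    def exposure_fn(self) -> tuple[Callable[[float], float], list[float]]:
        """(free extracellular concentration as a function of time in s,
        dose times in s)."""
        if isinstance(self.exposure, DoseSchedule):
            p = self.params
            binding = BindingParams(p.Ka_plasma, p.Bmax_plasma)
            grid = np.arange(0.0, self.t_end_h + 0.02, 0.01)
            pkres = simulate_pk(self.exposure, binding, p.k_e, grid)
            times_s = pkres.times_h * _H
            free = pkres.free_uM

            def n_ext(t_s: float) -> float:
                return float(np.interp(t_s, times_s, free))

            dose_times = [t0 * _H for t0, _ in self.exposure.doses
                          if 0.0 <= t0 < self.t_end_h]
            return n_ext, dose_times
        conc = float(self.exposure)
        if conc < 0:
            raise ValueError("constant exposure must be >= 0")
        return (lambda t_s: conc), []


def _propensities(
    y: np.ndarray,
    genes: Sequence[int],
    params: ParameterSet,
    p_active_override: float | None,
) -> np.ndarray:
    """Per-channel switch propensities, order:
    (p53 +, p53 −, mdm2 +, mdm2 −, pten +, pten −)."""
    from .gene_switch import activation_propensity, deactivation_propensity

    if p_active_override is not None:
        p_act = p_active_override
    else:
        p_act = _p_active(y, params)
    lam = np.empty(6)
    for k, gene in enumerate(GENES):
        g, q0, _ = params.gene_params(gene)
        lam[2 * k] = activation_propensity(gene, genes[k], g, p_act, params)
        lam[2 * k + 1] = deactivation_propensity(genes[k], q0)
    return lam


def simulate_cell(
    spec: SimulationSpec,
    resume: ResumeState | None = None,
) -> Trajectory:
    """Simulate one cell over ``[0, t_end_h]`` (or continue from ``resume``).

    The returned trajectory carries snapshots on the regular output grid,
    the gene-switch and dose event log, and a :class:`ResumeState` from
    which the simulation can be continued bit-identically (valid at
    checkpoint boundaries).
    """
    params = spec.params
    n_ext_fn, dose_times_s = spec.exposure_fn()
    t_end_s = spec.t_end_h * _H

    if resume is not None:
        t = resume.t_s
        y = resume.y.copy()
        genes = list(resume.genes)
        rng = np.random.default_rng()
        rng.bit_generator.state = resume.rng_state
        hazard_target = resume.hazard_remaining
    else:
        t = 0.0
        state0 = spec.initial if spec.initial is not None else initial_state(params)
        y = state0.y.copy()
        genes = list(state0.genes)
        rng = np.random.default_rng(spec.seed)
        hazard_target = rng.exponential()

    # segment boundaries: checkpoints, dose times, horizon
    n_chk = int(math.ceil(spec.t_end_h / spec.checkpoint_h))
    boundaries = sorted(set(
        [min((k + 1) * spec.checkpoint_h * _H, t_end_s) for k in range(n_chk)]
        + dose_times_s + [t_end_s]
    ))
    boundaries = [b for b in boundaries if b > t + 1e-9]

    grid_s = np.arange(0.0, t_end_s + 0.5 * spec.grid_dt_h * _H,
                       spec.grid_dt_h * _H)
    grid_s = grid_s[grid_s <= t_end_s + 1e-9]
    if resume is not None:
        grid_s = grid_s[grid_s >= t - 1e-9]
    out_species = np.empty((grid_s.size, N_SPECIES))
    out_genes = np.empty((grid_s.size, 3), dtype=int)
    filled = np.zeros(grid_s.size, dtype=bool)

    events: list[Event] = []
    if spec.record_events:
        for td in dose_times_s:
            events.append(Event(time_h=td / _H, kind="dose"))

    from .network_odes import make_fast_rhs

    fast = make_fast_rhs(params)
    q0_0, q1_0 = params.q0_p53, params.q1_p53
    q0_1, q1_1 = params.q0_mdm2, params.q1_mdm2
    q0_2, q1_2 = params.q0_pten, params.q1_pten
    G0, G1, G2 = params.G_p53, params.G_mdm2, params.G_pten
    hexp = params.activation_exponent
    use_total = params.activation_uses_total_phospho
    override = spec.p_active_override

    def rhs(tt: float, z: np.ndarray) -> np.ndarray:
        yy = z[:N_SPECIES]
        dy = fast(yy, genes[0], genes[1], genes[2], n_ext_fn(tt))
        if override is not None:
            p_act = override
        else:
            p_act = yy[6] + yy[7]          # P_p + P_pu
            if use_total:
                p_act += yy[8] + yy[11] + yy[12]
            if p_act < 0.0:
                p_act = 0.0
        ph = p_act * p_act if hexp == 2.0 else p_act ** hexp
        lam_sum = (q1_0 * (G0 - genes[0]) + q0_0 * genes[0]
                   + q1_1 * (G1 - genes[1]) * ph + q0_1 * genes[1]
                   + q1_2 * (G2 - genes[2]) * ph + q0_2 * genes[2])
        return np.append(dy, lam_sum)

    def record(dense, a: float, b: float, last: bool) -> None:
        if last:
            mask = (grid_s >= a - 1e-9) & (grid_s <= b + 1e-9) & ~filled
        else:
            mask = (grid_s >= a - 1e-9) & (grid_s < b - 1e-9) & ~filled
        pts = grid_s[mask]
        if pts.size:
            vals = dense(pts)
            out_species[mask] = vals[:N_SPECIES].T
            out_genes[mask] = genes
            filled[mask] = True

    for b in boundaries:
        while t < b - 1e-9:
            def hit(tt: float, z: np.ndarray, target=hazard_target) -> float:
                return z[N_SPECIES] - target

            hit.terminal = True
            hit.direction = 1.0

            z0 = np.append(y, 0.0)
            sol = solve_ivp(
                rhs, (t, b), z0, method="LSODA", dense_output=True,
                events=hit, rtol=spec.rtol, atol=spec.atol,
            )
            if not sol.success:
                raise RuntimeError(
                    f"ODE integration failed at t={t / _H:.3f} h "
                    f"(genes={genes}): {sol.message}"
                )
            if sol.t_events[0].size:
                t_ev = float(sol.t_events[0][0])
                z_ev = sol.sol(t_ev)
                record(sol.sol, t, t_ev, last=False)
                y = np.maximum(z_ev[:N_SPECIES], 0.0)
                lam = _propensities(y, genes, params, spec.p_active_override)
                total = lam.sum()
                if total <= 0.0:
                    # numerically located event in a zero-intensity region
                    t = t_ev
                    hazard_target = rng.exponential()
                    continue
                channel = int(rng.choice(6, p=lam / total))
                gene_idx, direction = divmod(channel, 2)
                step = +1 if direction == 0 else -1
                genes[gene_idx] += step
                if spec.record_events:
                    events.append(Event(
                        time_h=t_ev / _H, kind="switch",
                        gene=GENES[gene_idx], direction=step,
                        info={"propensities": lam.tolist()},
                    ))
                t = t_ev
                hazard_target = rng.exponential()
            else:
                record(sol.sol, t, b, last=(b == boundaries[-1]))
                z_end = sol.y[:, -1]
                y = np.maximum(z_end[:N_SPECIES], 0.0)
                hazard_target -= float(z_end[N_SPECIES])
                t = b

    if not filled.all():
        # grid points at segment seams: fill from neighbours
        idx = np.where(~filled)[0]
        for i in idx:
            j = i - 1 if i > 0 else i + 1
            out_species[i] = out_species[j]
            out_genes[i] = out_genes[j]

    resume_state = ResumeState(
        t_s=t,
        y=y.copy(),
        genes=(genes[0], genes[1], genes[2]),
        hazard_remaining=hazard_target,
        rng_state=rng.bit_generator.state,
    )
    return Trajectory(
        times_h=grid_s / _H,
        species=out_species,
        genes=out_genes,
        events=events,
        seed=spec.seed if resume is None else None,
        resume=resume_state,
    )


@dataclass
class PopulationSummary:
    """Per-species median and quartiles over a cell population."""

    times_h: np.ndarray
    median: np.ndarray   # (n_times, n_species)
    q1: np.ndarray
    q3: np.ndarray

    def series(self, name: str, which: str = "median") -> np.ndarray:
        from .model_core import SPECIES_INDEX

        return getattr(self, {"median": "median", "q1": "q1", "q3": "q3"}[which]
                       )[:, SPECIES_INDEX[name]]


def simulate_population(
    spec: SimulationSpec,
    n_cells: int,
    base_seed: int | None = None,
    initial: CellState | None = None,
) -> tuple[list[Trajectory], PopulationSummary, list[tuple[int, str]]]:
    """Simulate ``n_cells`` independent cells (streams seeded
    ``base_seed + cell_index``) and summarise per-species quartiles.

    Returns ``(trajectories, summary, failures)`` where failures is a list
    of ``(cell_index, message)`` for cells whose integration failed (they
    are excluded from the summary).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if base_seed is None:
        base_seed = spec.seed
    if initial is None and spec.initial is None:
        initial = initial_state(spec.params)  # shared baseline, computed once
    elif initial is None:
        initial = spec.initial

    trajs: list[Trajectory] = []
    failures: list[tuple[int, str]] = []
    import dataclasses as _dc

    for i in range(n_cells):
        cell_spec = _dc.replace(spec, seed=base_seed + i, initial=initial)
        try:
            trajs.append(simulate_cell(cell_spec))
        except RuntimeError as exc:  # pragma: no cover - solver failure path
            failures.append((i, str(exc)))
    if not trajs:
        raise RuntimeError(f"all {n_cells} cells failed: {failures[:3]}")
    stack = np.stack([tr.species for tr in trajs])  # (cells, times, species)
    summary = PopulationSummary(
        times_h=trajs[0].times_h,
        median=np.median(stack, axis=0),
        q1=np.quantile(stack, 0.25, axis=0),
        q3=np.quantile(stack, 0.75, axis=0),
    )
    return trajs, summary, failures
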