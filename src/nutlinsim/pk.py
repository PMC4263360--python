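"""Extracellular drug model: protein binding and oral pharmacokinetics.

Plasma (or culture-medium) proteins bind Nutlin saturably; binding is in
quasi-steady state, so the free concentration ``x`` solves

    N_tot = x + Bmax * Ka * x / (1 + Ka * x),

i.e. the non-negative root of ``Ka x² + (1 + Ka Bmax − Ka N_tot) x − N_tot``.

Oral delivery in mice is one-compartment with exponential gastro-enteric
release and linear elimination of the *free* drug only:

    dN_tot/dt = alpha * k_a * Σ_j D_j exp(−k_a (t − t0_j)) 1{t ≥ t0_j}
                − k_e * free(N_tot)

with dose ``D_j`` in mg/kg and ``alpha`` converting mg/kg to µM (including
the distribution volume).  Times in this module are in hours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .model_core import ValidationError

__all__ = [
    "BindingParams",
    "DoseSchedule",
    "PKResult",
    "PKFit",
    "free_from_total",
    "pk_rhs",
    "simulate_pk",
    "fit_pk",
]


@dataclass(frozen=True)
class BindingParams:
    """Saturable binding: equilibrium association constant and site count."""

    Ka: float     # 1/µM
    Bmax: float   # µM

    def __post_init__(self) -> None:
        if self.Ka < 0 or self.Bmax < 0:
            raise ValidationError(
                f"binding constants must be >= 0 (Ka={self.Ka}, Bmax={self.Bmax})"
            )


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered oral dosing events plus release/conversion constants."""

    doses: tuple[tuple[float, float], ...]  # (time h, dose mg/kg)
    k_a: float      # 1/h gastro-enteric release
    alpha: float    # µM per mg/kg
    label: str = ""

    def __post_init__(self) -> None:
        times = [t for t, _ in self.doses]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise ValidationError("dose times must be non-decreasing")
        if any(d <= 0 for _, d in self.doses):
            raise ValidationError("doses must be > 0")
        if self.k_a < 0 or self.alpha < 0:
            raise ValidationError("k_a and alpha must be >= 0")

    @classmethod
    def single(cls, dose: float, k_a: float, alpha: float,
               t0: float = 0.0) -> "DoseSchedule":
        return cls(((t0, dose),), k_a, alpha, label=f"{dose:g} mg/kg single")

    @classmethod
    def split(cls, total_dose: float, n: int, interval_h: float,
              k_a: float, alpha: float, t0: float = 0.0) -> "DoseSchedule":
        """Total dose split into ``n`` equal boli ``interval_h`` apart."""
        d = total_dose / n
        return cls(
            tuple((t0 + i * interval_h, d) for i in range(n)),
            k_a, alpha,
            label=f"{total_dose:g} mg/kg in {n}x every {interval_h:g} h",
        )

    def input_rate(self, t: float) -> float:
        """Drug appearance rate alpha·k_a·Σ D_j e^{−k_a(t−t0_j)} (µM/h)."""
        rate = 0.0
        for t0, d in self.doses:
            if t >= t0:
                rate += d * math.exp(-self.k_a * (t - t0))
        return self.alpha * self.k_a * rate


def free_from_total(N_tot: float, binding: BindingParams) -> float:
    """Free concentration from total under saturable binding (µM).

    Unique non-negative root of the binding quadratic, evaluated on the
    numerically stable branch (no cancellation when ``Ka·N_tot >> 1``).
    Always lies in ``[0, N_tot]``.
    """
    if N_tot < 0:
        raise ValidationError(f"N_tot must be >= 0, got {N_tot}")
    Ka, Bmax = binding.Ka, binding.Bmax
    if N_tot == 0.0:
        return 0.0
    if Ka == 0.0 or Bmax == 0.0:
        return float(N_tot)
    b = 1.0 + Ka * (Bmax - N_tot)
    disc = math.sqrt(b * b + 4.0 * Ka * N_tot)
    if b <= 0.0:
        x = (-b + disc) / (2.0 * Ka)
    else:
        x = 2.0 * N_tot / (b + disc)
    return float(min(max(x, 0.0), N_tot))


def pk_rhs(
    N_tot: float,
    t: float,
    schedule: DoseSchedule,
    binding: BindingParams,
    k_e: float,
) -> float:
    """dN_tot/dt (µM/h): exponential GI release minus free-only elimination."""
    return schedule.input_rate(t) - k_e * free_from_total(max(N_tot, 0.0), binding)


@dataclass
class PKResult:
    """Extracellular concentration time series (µM, hours)."""

    times_h: np.ndarray
    total_uM: np.ndarray
    free_uM: np.ndarray
    schedule: DoseSchedule | None = None

    def free_at(self, t_h: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the free concentration."""
        return np.interp(t_h, self.times_h, self.free_uM)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_h": self.times_h,
            "total_uM": self.total_uM,
            "free_uM": self.free_uM,
        })


def simulate_pk(
    schedule: DoseSchedule,
    binding: BindingParams,
    k_e: float,
    t_grid: np.ndarray | Sequence[float],
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> PKResult:
    """Integrate the PK equation on ``t_grid`` (hours).

    Integration is split at dose times (the release term has corners there).
    Returns both the total and the free concentration; the free series is
    the exposure input of the cellular drug-uptake equation.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be an increasing 1-D array")
    if not schedule.doses:
        z = np.zeros_like(t_grid)
        return PKResult(t_grid, z, z.copy(), schedule)

    dose_times = sorted({t0 for t0, _ in schedule.doses})
    breaks = sorted({t_grid[0], t_grid[-1],
                     *[t for t in dose_times if t_grid[0] < t < t_grid[-1]]})
    total = np.empty_like(t_grid)
    n = 0.0
    filled = 0
    for a, b in zip(breaks, breaks[1:]):
        mask = (t_grid >= a) & (t_grid <= b) if b == breaks[-1] else \
               (t_grid >= a) & (t_grid < b)
        pts = t_grid[mask]
        sol = solve_ivp(
            lambda t, y: [pk_rhs(y[0], t, schedule, binding, k_e)],
            (a, b), [n], method="LSODA", dense_output=True,
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"PK integration failed on [{a}, {b}]: {sol.message}")
        if pts.size:
            total[filled:filled + pts.size] = sol.sol(pts)[0]
            filled += pts.size
        n = float(sol.y[0, -1])
    total = np.maximum(total, 0.0)
    free = np.array([free_from_total(v, binding) for v in total])
    return PKResult(t_grid, total, free, schedule)


@dataclass
class PKFit:
    """Least-squares PK parameter estimates."""

    k_a: float
    k_e: float
    alpha: float
    residual_norm: float
    identifiable: bool = True
    message: str = ""


def fit_pk(
    times_h: np.ndarray | Sequence[float],
    conc_uM: np.ndarray | Sequence[float],
    dose: float,
    binding: BindingParams,
    t0: float = 0.0,
    x0: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> PKFit:
    """Fit ``(k_a, k_e, alpha)`` of a single oral dose to a total-concentration
    table by least squares (parameters log-transformed to stay positive).

    Raises on fewer than 4 time points; warns (and flags the result) when the
    data are too flat to identify the parameters.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc_uM, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValidationError("empty concentration table")
    if t.size < 4:
        raise ValidationError(f"need >= 4 time points, got {t.size}")
    if np.any(c < 0):
        raise ValidationError("concentrations must be >= 0")
    order = np.argsort(t)
    t, c = t[order], c[order]

    grid = np.unique(np.concatenate([[t0], t]))

    def model(theta: np.ndarray) -> np.ndarray:
        k_a, k_e, alpha = np.exp(theta)
        sched = DoseSchedule.single(dose, k_a, alpha, t0=t0)
        res = simulate_pk(sched, binding, k_e, grid, rtol=1e-8, atol=1e-10)
        return np.interp(t, res.times_h, res.total_uM)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model(theta) - c

    fit = least_squares(residuals, np.log(np.asarray(x0, dtype=float)),
                        method="lm", xtol=1e-14, ftol=1e-14)
    k_a, k_e, alpha = np.exp(fit.x)
    resid = float(np.linalg.norm(fit.fun))

    identifiable = True
    message = ""
    spread = np.ptp(c)
    if spread < 1e-12 * (np.abs(c).max() + 1e-300) or spread == 0.0:
        identifiable = False
        message = "flat concentration data: parameters not identifiable"
    else:
        _, sv, _ = np.linalg.svd(fit.jac, full_matrices=False)
        if sv[-1] < 1e-10 * sv[0]:
            identifiable = False
            message = ("ill-conditioned fit (singular value ratio "
                       f"{sv[-1] / sv[0]:.2e}): wide confidence region")
    if not identifiable:
        warnings.warn(message, stacklevel=2)
    return PKFit(float(k_a), float(k_e), float(alpha), resid,
                 identifiable, message)
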