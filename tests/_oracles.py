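"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the SSA is a textbook
direct-method Gillespie simulation with discrete mRNA copy numbers, and the
telegraph statistics are closed forms.
"""

from __future__ import annotations

import math

import numpy as np


def ssa_gene_mrna(
    G: int,
    q_on: float,
    q_off: float,
    s_mrna: float,
    d_mrna: float,
    t_end: float,
    rng: np.random.Generator,
    A0: int,
    R0: int,
) -> tuple[int, int]:
    """Exact SSA of the reduced network: ``G`` independent telegraph gene
    copies (constant activation rate ``q_on`` per inactive copy, deactivation
    ``q_off`` per active copy), mRNA born at ``s_mrna`` per active copy and
    degraded at ``d_mrna`` per molecule.  Returns ``(A, R)`` at ``t_end``.
    """
    t = 0.0
    A, R = A0, R0
    while True:
        a1 = q_on * (G - A)
        a2 = q_off * A
        a3 = s_mrna * A
        a4 = d_mrna * R
        a_tot = a1 + a2 + a3 + a4
        if a_tot <= 0.0:
            return A, R
        t += rng.exponential(1.0 / a_tot)
        if t > t_end:
            return A, R
        u = rng.uniform() * a_tot
        if u < a1:
            A += 1
        elif u < a1 + a2:
            A -= 1
        elif u < a1 + a2 + a3:
            R += 1
        else:
            R -= 1


def telegraph_on_fraction(act: float, q0: float) -> float:
    """Stationary per-copy ON probability of the telegraph process."""
    return act / (act + q0)


def occupancy_se(p: float, act: float, q0: float, t_total: float) -> float:
    """Standard error of the time-averaged ON fraction over ``t_total``.

    The ON indicator is a two-state Markov chain with relaxation rate
    ``act + q0``; the long-run variance of its time average is
    ``2 p (1-p) tau / T`` with ``tau = 1/(act+q0)``.
    """
    tau = 1.0 / (act + q0)
    return math.sqrt(2.0 * p * (1.0 - p) * tau / t_total)


def bateman_total(t: np.ndarray, dose: float, alpha: float, k_a: float,
                  k_e: float, t0: float = 0.0) -> np.ndarray:
    """Closed-form total concentration for a single oral dose with no
    protein binding (free = total): the two-exponential Bateman function."""
    dt = np.maximum(t - t0, 0.0)
    return (alpha * dose * k_a / (k_a - k_e)
            * (np.exp(-k_e * dt) - np.exp(-k_a * dt)) * (t >= t0))
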