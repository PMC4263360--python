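"""Telegraph (ON/OFF) gene switching for the p53, Mdm2 and PTEN genes.

Each gene has a fixed number of copies.  A single active copy deactivates at
a constant rate ``q0`` and deactivation events are independent, so the total
deactivation propensity is ``q0 * A`` for ``A`` active copies.  Activation of
the p53-target genes (Mdm2, PTEN) is driven by transcriptionally active p53:
p53 dimers bind DNA cooperatively as tetramers, so the activation propensity
scales as the square of the free phospho-p53 dimer count (an exponent of 1.8,
the measured Hill coefficient, is available via config).  The p53 gene itself
is constitutively activated.

Gene switches are simulated exactly as an inhomogeneous Poisson process by
the integrated-propensity method: the cumulative hazard Λ(t) = ∫λ dt is
accumulated alongside the ODE solution until it reaches an Exp(1) variate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import GENES, ParameterSet, ValidationError

__all__ = [
    "GenePropensity",
    "deactivation_propensity",
    "activation_propensity",
    "gene_propensities",
    "sample_next_switch",
]


@dataclass(frozen=True)
class GenePropensity:
    """Propensity pair of one gene at one instant."""

    gene: str
    activation: float      # 1/s
    deactivation: float    # 1/s
    time: float            # s

    def __post_init__(self) -> None:
        if self.activation < 0 or self.deactivation < 0:
            raise ValidationError(
                f"negative propensity for gene {self.gene}: "
                f"act={self.activation}, deact={self.deactivation}"
            )


def deactivation_propensity(A_g: float, q0_g: float) -> float:
    """Total deactivation propensity ``q0 * A`` (1/s).

    ``A_g`` may be fractional in mean-field use.
    """
    if A_g < 0 or q0_g < 0:
        raise ValidationError(f"negative input: A_g={A_g}, q0_g={q0_g}")
    return q0_g * A_g


def activation_propensity(
    gene: str,
    A_g: float,
    G_g: int,
    P_active: float,
    params: ParameterSet,
) -> float:
    """Total activation propensity of a gene (1/s).

    For the p53-target genes (Mdm2, PTEN) the rate per inactive copy is
    ``q1 * P_active**h`` with ``h`` the tetramerization exponent (default 2);
    the p53 gene activates constitutively at ``q1_p53`` per inactive copy.
    """
    if gene not in GENES:
        raise ValidationError(f"unknown gene id: {gene!r}")
    if A_g < 0 or A_g > G_g or P_active < 0:
        raise ValidationError(
            f"invalid inputs for {gene}: A_g={A_g}, G_g={G_g}, P_active={P_active}"
        )
    free = G_g - A_g
    q1 = getattr(params, f"q1_{gene}")
    if gene == "p53":
        return q1 * free
    return q1 * free * P_active ** params.activation_exponent


def gene_propensities(
    genes: Sequence[float],
    P_active: float,
    params: ParameterSet,
    t: float = 0.0,
) -> list[GenePropensity]:
    """Propensities of all three genes at one instant."""
    out = []
    for gene, a in zip(GENES, genes):
        g, q0, _ = params.gene_params(gene)
        out.append(
            GenePropensity(
                gene=gene,
                activation=activation_propensity(gene, a, g, P_active, params),
                deactivation=deactivation_propensity(a, q0),
                time=t,
            )
        )
    return out


def sample_next_switch(
    propensity_fn: Callable[[float], np.ndarray | float],
    t0: float,
    rng: np.random.Generator,
    horizon: float,
    max_step: float | None = None,
) -> tuple[float, int] | tuple[None, None]:
    """First jump of an inhomogeneous Poisson process on ``[t0, horizon]``.

    ``propensity_fn(t)`` returns per-channel intensities (array) or a single
    total intensity.  The cumulative hazard Λ(t) is integrated as an ODE and
    the event fires when Λ reaches an Exp(1) draw; the channel is then chosen
    with probability proportional to the channel intensities at the event
    time.  Returns ``(event_time, channel_index)`` or ``(None, None)`` if no
    event occurs before the horizon.
    """
    target = rng.exponential()

    def lam_total(t: float) -> float:
        lam = np.atleast_1d(np.asarray(propensity_fn(t), dtype=float))
        if np.any(lam < 0):
            raise ValidationError(f"negative intensity at t={t}: {lam}")
        return float(lam.sum())

    def rhs(t: float, y: np.ndarray) -> list[float]:
        return [lam_total(t)]

    def hit(t: float, y: np.ndarray) -> float:
        return y[0] - target

    hit.terminal = True
    hit.direction = 1.0

    kwargs = {}
    if max_step is not None:
        kwargs["max_step"] = max_step
    sol = solve_ivp(
        rhs, (t0, horizon), [0.0], method="LSODA", events=hit,
        rtol=1e-10, atol=1e-12, **kwargs,
    )
    if not sol.success:
        raise RuntimeError(f"hazard integration failed: {sol.message}")
    if sol.t_events[0].size == 0:
        return None, None
    t_ev = float(sol.t_events[0][0])
    lam = np.atleast_1d(np.asarray(propensity_fn(t_ev), dtype=float))
    total = lam.sum()
    if total <= 0:
        # event located at the edge of a vanishing-intensity region
        return None, None
    channel = int(rng.choice(len(lam), p=lam / total))
    return t_ev, channel
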