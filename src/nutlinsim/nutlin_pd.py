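"""Nutlin pharmacodynamics: competitive inactivation of Mdm2.

Nutlin occupies the p53-binding pocket of Mdm2, so each of the three Mdm2
pools (cytoplasmic, cytoplasmic-phospho, nuclear-phospho) exists in an
active (drug-free) and an inactive (Nutlin-bound) form; one Nutlin molecule
is carried per inactive Mdm2.  Inactive pools still undergo
(de)phosphorylation, nuclear transport and degradation.  Intracellular free
Nutlin obeys linear uptake from the extracellular free concentration and
linear efflux; binding/dissociation exchange drug with the inactive pools.
Degradation of an inactive Mdm2 destroys its bound Nutlin (no recycling of
the drug from degraded complexes).

``i1`` absorbs the µM→molecules conversion (membrane permeability × cell
volume × Avogadro), so the uptake term is literally ``i1 * N_ext``.
"""

from __future__ import annotations

import numpy as np

from .model_core import N_SPECIES, SPECIES_INDEX, CellState, ParameterSet, ValidationError

__all__ = ["nutlin_pd_rhs", "total_intracellular_nutlin"]

_I = SPECIES_INDEX


def nutlin_pd_rhs(
    y: np.ndarray, n_ext: float, params: ParameterSet
) -> np.ndarray:
    """Derivatives of the inactive Mdm2 pools and free intracellular Nutlin,
    plus the matching binding/dissociation coupling on the active pools.

    ``n_ext`` is the extracellular *free* Nutlin concentration (µM).
    """
    if n_ext < 0:
        raise ValidationError(f"N_ext must be >= 0, got {n_ext}")
    p = params
    dy = np.zeros(N_SPECIES)
    M2, M2_p, M2_pn = y[_I["M2"]], y[_I["M2_p"]], y[_I["M2_pn"]]
    M2_i, M2_pi, M2_pni = y[_I["M2_i"]], y[_I["M2_pi"]], y[_I["M2_pni"]]
    N = y[_I["N_free"]]
    Akt_p = y[_I["Akt_p"]]

    bN = p.b1 * N
    phos = p.k_phos_m2 * Akt_p

    dy[_I["M2_i"]] = (bN * M2 + p.k_dephos_m2 * M2_pi
                      - p.u1 * M2_i - phos * M2_i - p.d_m2 * M2_i)
    dy[_I["M2_pi"]] = (bN * M2_p + phos * M2_i - p.u1 * M2_pi
                       - p.k_dephos_m2 * M2_pi - p.i_m2 * M2_pi
                       + p.e_m2 * M2_pni - p.d_m2 * M2_pi)
    dy[_I["M2_pni"]] = (bN * M2_pn + p.i_m2 * M2_pi - p.u1 * M2_pni
                        - p.e_m2 * M2_pni - p.d_m2 * M2_pni)
    dy[_I["N_free"]] = (p.i1 * n_ext - p.e1 * N
                        - bN * (M2 + M2_p + M2_pn)
                        + p.u1 * (M2_i + M2_pi + M2_pni))
    # matching exchange on the active pools
    dy[_I["M2"]] = -bN * M2 + p.u1 * M2_i
    dy[_I["M2_p"]] = -bN * M2_p + p.u1 * M2_pi
    dy[_I["M2_pn"]] = -bN * M2_pn + p.u1 * M2_pni
    return dy


def total_intracellular_nutlin(state: CellState | np.ndarray) -> float:
    """Total drug in the cell: free plus one molecule per inactive Mdm2."""
    y = state.y if isinstance(state, CellState) else np.asarray(state)
    return float(y[_I["N_free"]] + y[_I["M2_i"]] + y[_I["M2_pi"]]
                 + y[_I["M2_pni"]])
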