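"""Deterministic reaction network: p53–Mdm2 and PTEN–PIP3–Akt modules.

All reactions are mass action.  The canonical description is a
machine-readable :class:`ReactionScheme` (a flat list of reactions with
stoichiometry and rate law); the hand-coded right-hand sides used by the
solver are checked against the scheme evaluator in the test suite.

Mechanism summary
-----------------
* p53 is synthesised directly into the nucleus (cytoplasmic p53 neglected),
  in dimer units.  It is reversibly phosphorylated; phospho-p53 is the
  transcriptionally active form.
* Nuclear phospho-Mdm2 binds p53 (association ``a1``; reduced ``a1p`` for
  phospho-p53 — phosphorylation protects p53 through weaker binding, not a
  changed degradation rate) and transfers ubiquitin within the complex
  (``k_ub``), releasing Mdm2 and the next ubiquitination state.  Only mono-
  and bi-ubiquitination are modelled; bi-ubiquitinated p53 degrades fast
  (``d_p53_biub``) as a proxy for poly-ubiquitin-mediated degradation.
  HAUSP deubiquitinates at ``k_deub`` (its constant level folded in).
* Mdm2 is cytoplasmic; phosphorylation by active Akt gates nuclear import.
* PTEN (p53-induced, cytoplasm only) hydrolyses PIP3 to PIP2, lowering
  active Akt and hence nuclear Mdm2 — the positive feedback on p53.
  PIP2+PIP3 and Akt totals are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_core import (
    N_SPECIES,
    SPECIES,
    SPECIES_INDEX,
    ParameterSet,
)

__all__ = [
    "Reaction",
    "build_reaction_scheme",
    "scheme_rhs",
    "scheme_to_table",
    "p53_mdm2_rhs",
    "mdm2_cytoplasm_rhs",
    "pten_pip_akt_rhs",
    "combined_rhs",
]

# indices, resolved once
_I = SPECIES_INDEX


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction: rate = value * prod(factors)."""

    name: str
    constant: str                 # ParameterSet field the rate comes from
    value: float                  # resolved numeric rate constant (1/s basis)
    factors: tuple[str, ...]      # species or virtual species in the rate law
    delta: tuple[tuple[str, int], ...]  # stoichiometry changes


def _factor_value(
    name: str,
    y: np.ndarray,
    genes: Sequence[float],
    params: ParameterSet,
    n_ext: float,
) -> float:
    if name in SPECIES_INDEX:
        return float(y[SPECIES_INDEX[name]])
    if name == "A_p53":
        return float(genes[0])
    if name == "A_mdm2":
        return float(genes[1])
    if name == "A_pten":
        return float(genes[2])
    if name == "PIP2":
        return float(params.PIP_tot - y[_I["PIP3"]])
    if name == "Akt0":
        return float(params.Akt_tot - y[_I["Akt_p"]])
    if name == "N_ext":
        return float(n_ext)
    raise KeyError(f"unknown rate-law factor {name!r}")


def build_reaction_scheme(params: ParameterSet) -> list[Reaction]:
    """The full reaction list, rate constants resolved from ``params``."""
    rxns: list[Reaction] = []

    def add(name, constant, value, factors, delta):
        rxns.append(Reaction(name, constant, float(value), tuple(factors),
                             tuple(delta.items())))

    p = params
    # transcription / mRNA decay / translation
    add("tx_p53", "s_mrna_p53", p.s_mrna_p53, ["A_p53"], {"R_p53": +1})
    add("tx_mdm2", "s_mrna_mdm2", p.s_mrna_mdm2, ["A_mdm2"], {"R_mdm2": +1})
    add("tx_pten", "s_mrna_pten", p.s_mrna_pten, ["A_pten"], {"R_pten": +1})
    for g in ("p53", "mdm2", "pten"):
        add(f"deg_R_{g}", f"d_mrna_{g}", getattr(p, f"d_mrna_{g}"),
            [f"R_{g}"], {f"R_{g}": -1})
    add("tl_p53", "s_prot_p53", p.s_prot_p53, ["R_p53"], {"P": +1})
    add("tl_mdm2", "s_prot_mdm2", p.s_prot_mdm2, ["R_mdm2"], {"M2": +1})
    # PTEN production is zeroed when the feedback is disabled
    add("tl_pten", "s_prot_pten",
        p.s_prot_pten if p.pten_enabled else 0.0, ["R_pten"], {"PTEN": +1})

    # p53 (de)phosphorylation, all ubiquitination states
    for src, dst in (("P", "P_p"), ("P_u", "P_pu"), ("P_uu", "P_puu")):
        add(f"phos_{src}", "k_phos_p53", p.k_phos_p53, [src], {src: -1, dst: +1})
        add(f"dephos_{dst}", "k_dephos_p53", p.k_dephos_p53, [dst],
            {dst: -1, src: +1})

    # complex formation / dissociation / in-complex ubiquitin transfer
    assoc = [("P", "C_P", "a1", p.a1), ("P_u", "C_Pu", "a1", p.a1),
             ("P_p", "C_Pp", "a1p", p.a1p), ("P_pu", "C_Ppu", "a1p", p.a1p)]
    for x, c, kname, kval in assoc:
        add(f"assoc_{x}", kname, kval, ["M2_pn", x],
            {"M2_pn": -1, x: -1, c: +1})
        add(f"dissoc_{x}", "d1", p.d1, [c], {c: -1, "M2_pn": +1, x: +1})
    ub = [("C_P", "P_u"), ("C_Pu", "P_uu"), ("C_Pp", "P_pu"), ("C_Ppu", "P_puu")]
    for c, prod in ub:
        add(f"ub_{c}", "k_ub", p.k_ub, [c], {c: -1, "M2_pn": +1, prod: +1})

    # HAUSP deubiquitination
    for src, dst in (("P_u", "P"), ("P_uu", "P_u"), ("P_pu", "P_p"),
                     ("P_puu", "P_pu")):
        add(f"deub_{src}", "k_deub", p.k_deub, [src], {src: -1, dst: +1})

    # p53 degradation: basal on 0/1-ub forms, fast on bi-ub forms
    for x in ("P", "P_u", "P_p", "P_pu"):
        add(f"deg_{x}", "d_p53_basal", p.d_p53_basal, [x], {x: -1})
    for x in ("P_uu", "P_puu"):
        add(f"deg_{x}", "d_p53_biub", p.d_p53_biub, [x], {x: -1})
    # complexes: p53 moiety degrades basally releasing Mdm2; optionally the
    # Mdm2 moiety degrades destroying the whole unit
    for c in ("C_P", "C_Pu", "C_Pp", "C_Ppu"):
        add(f"deg_p53_{c}", "d_p53_basal", p.d_p53_basal, [c],
            {c: -1, "M2_pn": +1})
        add(f"deg_m2_{c}", "d_m2",
            p.d_m2 if p.complex_degradation else 0.0, [c], {c: -1})

    # Mdm2 cytoplasm: Akt-gated phosphorylation, transport, degradation
    add("phos_M2", "k_phos_m2", p.k_phos_m2, ["Akt_p", "M2"],
        {"M2": -1, "M2_p": +1})
    add("dephos_M2p", "k_dephos_m2", p.k_dephos_m2, ["M2_p"],
        {"M2_p": -1, "M2": +1})
    add("imp_M2p", "i_m2", p.i_m2, ["M2_p"], {"M2_p": -1, "M2_pn": +1})
    add("exp_M2pn", "e_m2", p.e_m2, ["M2_pn"], {"M2_pn": -1, "M2_p": +1})
    for x in ("M2", "M2_p", "M2_pn"):
        add(f"deg_{x}", "d_m2", p.d_m2, [x], {x: -1})

    # Nutlin pharmacodynamics: binding inactivates each Mdm2 pool
    for x, xi in (("M2", "M2_i"), ("M2_p", "M2_pi"), ("M2_pn", "M2_pni")):
        add(f"bind_{x}", "b1", p.b1, ["N_free", x],
            {x: -1, "N_free": -1, xi: +1})
        add(f"unbind_{xi}", "u1", p.u1, [xi], {xi: -1, x: +1, "N_free": +1})
    add("phos_M2i", "k_phos_m2", p.k_phos_m2, ["Akt_p", "M2_i"],
        {"M2_i": -1, "M2_pi": +1})
    add("dephos_M2pi", "k_dephos_m2", p.k_dephos_m2, ["M2_pi"],
        {"M2_pi": -1, "M2_i": +1})
    add("imp_M2pi", "i_m2", p.i_m2, ["M2_pi"], {"M2_pi": -1, "M2_pni": +1})
    add("exp_M2pni", "e_m2", p.e_m2, ["M2_pni"], {"M2_pni": -1, "M2_pi": +1})
    # degradation of inactive Mdm2 destroys its bound Nutlin
    for xi in ("M2_i", "M2_pi", "M2_pni"):
        add(f"deg_{xi}", "d_m2", p.d_m2, [xi], {xi: -1})

    # Nutlin uptake / efflux
    add("uptake_N", "i1", p.i1, ["N_ext"], {"N_free": +1})
    add("efflux_N", "e1", p.e1, ["N_free"], {"N_free": -1})

    # PTEN–PIP3–Akt
    add("deg_PTEN", "d_pten", p.d_pten, ["PTEN"], {"PTEN": -1})
    add("pip3_prod", "k_pip", p.k_pip, ["PIP2"], {"PIP3": +1})
    add("pip3_hyd", "k_hyd", p.k_hyd, ["PTEN", "PIP3"], {"PIP3": -1})
    add("akt_act", "k_akt", p.k_akt, ["PIP3", "Akt0"], {"Akt_p": +1})
    add("akt_deact", "k_deakt", p.k_deakt, ["Akt_p"], {"Akt_p": -1})
    return rxns


def scheme_rhs(
    y: np.ndarray,
    genes: Sequence[float],
    params: ParameterSet,
    n_ext: float = 0.0,
    scheme: list[Reaction] | None = None,
) -> np.ndarray:
    """Evaluate the full RHS directly from the reaction list (audit path)."""
    if scheme is None:
        scheme = build_reaction_scheme(params)
    dy = np.zeros(N_SPECIES)
    for rxn in scheme:
        rate = rxn.value
        for f in rxn.factors:
            rate *= _factor_value(f, y, genes, params, n_ext)
        for sp, coef in rxn.delta:
            dy[SPECIES_INDEX[sp]] += coef * rate
    return dy


def scheme_to_table(params: ParameterSet):
    """Reaction list as a tidy table (species, reaction, rate law, constant)."""
    import pandas as pd

    rows = []
    for rxn in build_reaction_scheme(params):
        law = rxn.constant + "".join(f" * {f}" for f in rxn.factors)
        for sp, coef in rxn.delta:
            rows.append({
                "species": sp,
                "reaction": rxn.name,
                "stoichiometry": coef,
                "rate_law": law,
                "constant": rxn.constant,
                "value_per_s": rxn.value,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hand-coded right-hand sides (solver hot path)
# ---------------------------------------------------------------------------

def p53_mdm2_rhs(
    y: np.ndarray, genes: Sequence[float], params: ParameterSet
) -> np.ndarray:
    """Nuclear p53 module: synthesis, phosphorylation, complexes,
    ubiquitination, deubiquitination, degradation.

    Includes the complex-cycling terms on nuclear Mdm2 (``M2_pn``); the
    transport/degradation terms of ``M2_pn`` live in
    :func:`mdm2_cytoplasm_rhs`.
    """
    p = params
    dy = np.zeros(N_SPECIES)
    R_p53 = y[_I["R_p53"]]
    P, P_u, P_uu = y[_I["P"]], y[_I["P_u"]], y[_I["P_uu"]]
    P_p, P_pu, P_puu = y[_I["P_p"]], y[_I["P_pu"]], y[_I["P_puu"]]
    C_P, C_Pu = y[_I["C_P"]], y[_I["C_Pu"]]
    C_Pp, C_Ppu = y[_I["C_Pp"]], y[_I["C_Ppu"]]
    M2_pn = y[_I["M2_pn"]]

    dy[_I["R_p53"]] = p.s_mrna_p53 * genes[0] - p.d_mrna_p53 * R_p53

    kp, kd = p.k_phos_p53, p.k_dephos_p53
    a1Mn, a1pMn = p.a1 * M2_pn, p.a1p * M2_pn
    dC = p.d_m2 if p.complex_degradation else 0.0

    dy[_I["P"]] = (p.s_prot_p53 * R_p53 - kp * P + kd * P_p
                   - a1Mn * P + p.d1 * C_P + p.k_deub * P_u
                   - p.d_p53_basal * P)
    dy[_I["P_u"]] = (-kp * P_u + kd * P_pu - a1Mn * P_u + p.d1 * C_Pu
                     + p.k_ub * C_P + p.k_deub * (P_uu - P_u)
                     - p.d_p53_basal * P_u)
    dy[_I["P_uu"]] = (-kp * P_uu + kd * P_puu + p.k_ub * C_Pu
                      - p.k_deub * P_uu - p.d_p53_biub * P_uu)
    dy[_I["P_p"]] = (kp * P - kd * P_p - a1pMn * P_p + p.d1 * C_Pp
                     + p.k_deub * P_pu - p.d_p53_basal * P_p)
    dy[_I["P_pu"]] = (kp * P_u - kd * P_pu - a1pMn * P_pu + p.d1 * C_Ppu
                      + p.k_ub * C_Pp + p.k_deub * (P_puu - P_pu)
                      - p.d_p53_basal * P_pu)
    dy[_I["P_puu"]] = (kp * P_uu - kd * P_puu + p.k_ub * C_Ppu
                       - p.k_deub * P_puu - p.d_p53_biub * P_puu)

    loss = p.d1 + p.k_ub + p.d_p53_basal + dC
    dy[_I["C_P"]] = a1Mn * P - loss * C_P
    dy[_I["C_Pu"]] = a1Mn * P_u - loss * C_Pu
    dy[_I["C_Pp"]] = a1pMn * P_p - loss * C_Pp
    dy[_I["C_Ppu"]] = a1pMn * P_pu - loss * C_Ppu

    # complex cycling on nuclear Mdm2: binding consumes it, dissociation,
    # ubiquitin transfer and p53-moiety degradation release it
    Csum = C_P + C_Pu + C_Pp + C_Ppu
    dy[_I["M2_pn"]] = (-a1Mn * (P + P_u) - a1pMn * (P_p + P_pu)
                       + (p.d1 + p.k_ub + p.d_p53_basal) * Csum)
    return dy


def mdm2_cytoplasm_rhs(
    y: np.ndarray, genes: Sequence[float], params: ParameterSet
) -> np.ndarray:
    """Active Mdm2 pools: synthesis, Akt-gated phosphorylation, nuclear
    transport and degradation.  Nutlin coupling lives in
    :mod:`nutlinsim.nutlin_pd`; complex cycling in :func:`p53_mdm2_rhs`.
    """
    p = params
    dy = np.zeros(N_SPECIES)
    R = y[_I["R_mdm2"]]
    M2, M2_p, M2_pn = y[_I["M2"]], y[_I["M2_p"]], y[_I["M2_pn"]]
    Akt_p = y[_I["Akt_p"]]

    dy[_I["R_mdm2"]] = p.s_mrna_mdm2 * genes[1] - p.d_mrna_mdm2 * R
    phos = p.k_phos_m2 * Akt_p
    dy[_I["M2"]] = (p.s_prot_mdm2 * R - phos * M2 + p.k_dephos_m2 * M2_p
                    - p.d_m2 * M2)
    dy[_I["M2_p"]] = (phos * M2 - p.k_dephos_m2 * M2_p - p.i_m2 * M2_p
                      + p.e_m2 * M2_pn - p.d_m2 * M2_p)
    dy[_I["M2_pn"]] = p.i_m2 * M2_p - p.e_m2 * M2_pn - p.d_m2 * M2_pn
    return dy


def pten_pip_akt_rhs(
    y: np.ndarray, genes: Sequence[float], params: ParameterSet
) -> np.ndarray:
    """PTEN–PIP3–Akt positive-feedback module.

    PIP2 = PIP_tot − PIP3 and inactive Akt = Akt_tot − Akt_p are implicit,
    so both totals are conserved by construction.  With ``pten_enabled``
    false, PTEN production is zeroed (all other parameters unchanged).
    """
    p = params
    dy = np.zeros(N_SPECIES)
    R = y[_I["R_pten"]]
    PTEN, PIP3, Akt_p = y[_I["PTEN"]], y[_I["PIP3"]], y[_I["Akt_p"]]

    dy[_I["R_pten"]] = p.s_mrna_pten * genes[2] - p.d_mrna_pten * R
    prod = p.s_prot_pten * R if p.pten_enabled else 0.0
    dy[_I["PTEN"]] = prod - p.d_pten * PTEN
    dy[_I["PIP3"]] = p.k_pip * (p.PIP_tot - PIP3) - p.k_hyd * PTEN * PIP3
    dy[_I["Akt_p"]] = (p.k_akt * PIP3 * (p.Akt_tot - Akt_p)
                       - p.k_deakt * Akt_p)
    return dy


def combined_rhs(
    y: np.ndarray,
    genes: Sequence[float],
    params: ParameterSet,
    n_ext: float = 0.0,
) -> np.ndarray:
    """Full deterministic RHS: network modules plus Nutlin pharmacodynamics."""
    from .nutlin_pd import nutlin_pd_rhs

    return (p53_mdm2_rhs(y, genes, params)
            + mdm2_cytoplasm_rhs(y, genes, params)
            + pten_pip_akt_rhs(y, genes, params)
            + nutlin_pd_rhs(y, n_ext, params))


def make_fast_rhs(params: ParameterSet):
    """Flattened scalar implementation of :func:`combined_rhs` (solver hot
    path).  Checked against the modular sum and the reaction-scheme
    evaluator in the test suite.

    Returns ``f(y, g0, g1, g2, n_ext) -> dy`` with gene activities passed as
    scalars.
    """
    p = params
    s_mr_p53, s_mr_m2, s_mr_pt = p.s_mrna_p53, p.s_mrna_mdm2, p.s_mrna_pten
    d_mr_p53, d_mr_m2, d_mr_pt = p.d_mrna_p53, p.d_mrna_mdm2, p.d_mrna_pten
    s_p53, s_m2 = p.s_prot_p53, p.s_prot_mdm2
    s_pt = p.s_prot_pten if p.pten_enabled else 0.0
    kp, kd = p.k_phos_p53, p.k_dephos_p53
    a1, a1p, d1, k_ub, k_deub = p.a1, p.a1p, p.d1, p.k_ub, p.k_deub
    db, dbb = p.d_p53_basal, p.d_p53_biub
    kpm, kdm, im, em, dm = (p.k_phos_m2, p.k_dephos_m2, p.i_m2, p.e_m2,
                            p.d_m2)
    closs = d1 + k_ub + db + (dm if p.complex_degradation else 0.0)
    crel = d1 + k_ub + db
    b1, u1, i1, e1 = p.b1, p.u1, p.i1, p.e1
    k_pip, k_hyd, k_akt, k_deakt = p.k_pip, p.k_hyd, p.k_akt, p.k_deakt
    d_pt, PIPt, Aktt = p.d_pten, p.PIP_tot, p.Akt_tot

    def rhs(y, g0, g1, g2, n_ext):
        (R_p53, R_m2, R_pt, P, P_u, P_uu, P_p, P_pu, P_puu,
         C_P, C_Pu, C_Pp, C_Ppu, M2, M2_p, M2_pn, M2_i, M2_pi, M2_pni,
         PTEN, PIP3, Akt_p, N) = y

        aM = a1 * M2_pn
        apM = a1p * M2_pn
        phosM = kpm * Akt_p
        bN = b1 * N
        Csum = C_P + C_Pu + C_Pp + C_Ppu

        return np.array([
            s_mr_p53 * g0 - d_mr_p53 * R_p53,
            s_mr_m2 * g1 - d_mr_m2 * R_m2,
            s_mr_pt * g2 - d_mr_pt * R_pt,
            (s_p53 * R_p53 - kp * P + kd * P_p - aM * P + d1 * C_P
             + k_deub * P_u - db * P),
            (-kp * P_u + kd * P_pu - aM * P_u + d1 * C_Pu + k_ub * C_P
             + k_deub * (P_uu - P_u) - db * P_u),
            (-kp * P_uu + kd * P_puu + k_ub * C_Pu - k_deub * P_uu
             - dbb * P_uu),
            (kp * P - kd * P_p - apM * P_p + d1 * C_Pp + k_deub * P_pu
             - db * P_p),
            (kp * P_u - kd * P_pu - apM * P_pu + d1 * C_Ppu + k_ub * C_Pp
             + k_deub * (P_puu - P_pu) - db * P_pu),
            (kp * P_uu - kd * P_puu + k_ub * C_Ppu - k_deub * P_puu
             - dbb * P_puu),
            aM * P - closs * C_P,
            aM * P_u - closs * C_Pu,
            apM * P_p - closs * C_Pp,
            apM * P_pu - closs * C_Ppu,
            (s_m2 * R_m2 - phosM * M2 + kdm * M2_p - dm * M2
             - bN * M2 + u1 * M2_i),
            (phosM * M2 - kdm * M2_p - im * M2_p + em * M2_pn - dm * M2_p
             - bN * M2_p + u1 * M2_pi),
            (im * M2_p - em * M2_pn - dm * M2_pn
             - aM * (P + P_u) - apM * (P_p + P_pu) + crel * Csum
             - bN * M2_pn + u1 * M2_pni),
            bN * M2 + kdm * M2_pi - u1 * M2_i - phosM * M2_i - dm * M2_i,
            (bN * M2_p + phosM * M2_i - u1 * M2_pi - kdm * M2_pi
             - im * M2_pi + em * M2_pni - dm * M2_pi),
            (bN * M2_pn + im * M2_pi - u1 * M2_pni - em * M2_pni
             - dm * M2_pni),
            s_pt * R_pt - d_pt * PTEN,
            k_pip * (PIPt - PIP3) - k_hyd * PTEN * PIP3,
            k_akt * PIP3 * (Aktt - Akt_p) - k_deakt * Akt_p,
            (i1 * n_ext - e1 * N - bN * (M2 + M2_p + M2_pn)
             + u1 * (M2_i + M2_pi + M2_pni)),
        ])

    return rhs
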