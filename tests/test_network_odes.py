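import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import nutlinsim as ns
from nutlinsim.model_core import N_SPECIES, SPECIES, SPECIES_INDEX
from nutlinsim.network_odes import (
    build_reaction_scheme,
    combined_rhs,
    make_fast_rhs,
    mdm2_cytoplasm_rhs,
    p53_mdm2_rhs,
    pten_pip_akt_rhs,
    scheme_rhs,
    scheme_to_table,
)

I = SPECIES_INDEX


@pytest.mark.parametrize("variant", [
    {},
    {"pten_enabled": False},
    {"complex_degradation": False},
    {"activation_exponent": 1.8},
])
def test_hand_coded_rhs_matches_reaction_scheme(rko_params, random_states,
                                                variant):
    """The solver RHS (modular and flattened) must equal the rate evaluation
    of the machine-readable reaction list on random states."""
    p = rko_params.replace(**variant)
    scheme = build_reaction_scheme(p)
    fast = make_fast_rhs(p)
    for y, genes, n_ext in random_states(12):
        ref = scheme_rhs(y, genes, p, n_ext, scheme)
        mod = combined_rhs(y, genes, p, n_ext)
        flat = fast(y, *genes, n_ext)
        scale = np.max(np.abs(ref)) + 1e-30
        assert np.max(np.abs(mod - ref)) / scale < 1e-9
        assert np.max(np.abs(flat - ref)) / scale < 1e-9


def test_every_species_and_constant_appears_in_scheme(rko_params):
    scheme = build_reaction_scheme(rko_params)
    touched = {sp for rxn in scheme for sp, _ in rxn.delta}
    assert touched == set(SPECIES)
    constants = {rxn.constant for rxn in scheme}
    for name in ("a1", "a1p", "d1", "k_ub", "k_deub", "b1", "u1", "i1", "e1",
                 "k_pip", "k_hyd", "k_akt", "k_deakt", "d_p53_biub"):
        assert name in constants


def test_scheme_table_is_exportable(rko_params):
    df = scheme_to_table(rko_params)
    assert set(df.columns) == {"species", "reaction", "stoichiometry",
                               "rate_law", "constant", "value_per_s"}
    assert len(df) > 50


def test_zero_state_has_zero_derivative(rko_params):
    y = np.zeros(N_SPECIES)
    dy = combined_rhs(y, (0, 0, 0), rko_params, n_ext=0.0)
    dy[I["PIP3"]] = 0.0  # PIP3 is produced from the conserved PIP pool
    assert np.all(dy == 0.0)


def test_ubiquitination_requires_nuclear_mdm2(rko_params):
    """Without nuclear Mdm2 (and no complexes to discharge), mono-ub p53
    has no production route."""
    y = np.zeros(N_SPECIES)
    y[I["P"]] = 500.0
    y[I["P_u"]] = 100.0
    dy = p53_mdm2_rhs(y, (0, 0, 0), rko_params)
    assert dy[I["P_u"]] < 0.0


def test_no_akt_means_no_mdm2_phosphorylation_source(rko_params):
    y = np.zeros(N_SPECIES)
    y[I["M2"]] = 1000.0
    y[I["M2_p"]] = 200.0
    dy = mdm2_cytoplasm_rhs(y, (0, 0, 0), rko_params)
    assert dy[I["M2_p"]] <= 0.0


def test_pure_transport_conserves_phospho_mdm2(rko_params):
    """With only import/export active, M2_p + M2_pn is conserved."""
    p = dataclasses.replace(
        rko_params, s_mrna_mdm2=0.0, s_prot_mdm2=0.0, k_phos_m2=0.0,
        k_dephos_m2=0.0, d_m2=0.0)
    y = np.zeros(N_SPECIES)
    y[I["M2_p"]] = 800.0
    y[I["M2_pn"]] = 100.0
    dy = mdm2_cytoplasm_rhs(y, (0, 0, 0), p)
    assert dy[I["M2_p"]] + dy[I["M2_pn"]] == pytest.approx(0.0, abs=1e-12)


def test_mdm2_chain_steady_state_matches_linear_solve(rko_params):
    """The cytoplasmic Mdm2 chain is linear at fixed mRNA and Akt; its fixed
    point from long integration must match the direct linear-algebra solve."""
    p = rko_params
    R, Akt = 150.0, 4.0e4
    idx = [I["M2"], I["M2_p"], I["M2_pn"]]

    def rhs3(t, m):
        y = np.zeros(N_SPECIES)
        y[I["R_mdm2"]] = R
        y[I["Akt_p"]] = Akt
        y[idx] = m
        dy = mdm2_cytoplasm_rhs(y, (0, 0, 0), p)
        return dy[idx]

    # independent oracle: assemble A x + b from unit-vector evaluations
    b = np.asarray(rhs3(0.0, np.zeros(3)))
    A = np.column_stack([np.asarray(rhs3(0.0, e)) - b for e in np.eye(3)])
    x_lin = np.linalg.solve(A, -b)

    sol = solve_ivp(rhs3, (0, 5e5), [0.0, 0.0, 0.0], method="LSODA",
                    rtol=1e-12, atol=1e-10)
    assert np.allclose(sol.y[:, -1], x_lin, rtol=1e-6)


class TestPtenModule:
    def test_pip3_saturation_stops_production(self, rko_params):
        y = np.zeros(N_SPECIES)
        y[I["PIP3"]] = rko_params.PIP_tot
        dy = pten_pip_akt_rhs(y, (0, 0, 0), rko_params)
        assert dy[I["PIP3"]] <= 0.0

    def test_no_pten_fixed_point_closed_form(self, rko_params):
        """Without PTEN, PIP3 relaxes to PIP_tot and active Akt to
        k_akt*PIP_tot*Akt_tot/(k_akt*PIP_tot + k_deakt)."""
        p = rko_params
        idx = [I["PIP3"], I["Akt_p"]]

        def rhs2(t, v):
            y = np.zeros(N_SPECIES)
            y[idx] = v
            return pten_pip_akt_rhs(y, (0, 0, 0), p)[idx]

        sol = solve_ivp(rhs2, (0, 1e6), [0.0, 0.0], method="LSODA",
                        rtol=1e-12, atol=1e-9)
        akt_expected = (p.k_akt * p.PIP_tot * p.Akt_tot
                        / (p.k_akt * p.PIP_tot + p.k_deakt))
        assert sol.y[0, -1] == pytest.approx(p.PIP_tot, rel=1e-6)
        assert sol.y[1, -1] == pytest.approx(akt_expected, rel=1e-6)

    def test_disabled_pten_zeroes_production_only(self, rko_params):
        p = rko_params.replace(pten_enabled=False)
        y = np.zeros(N_SPECIES)
        y[I["R_pten"]] = 10.0
        y[I["PTEN"]] = 500.0
        dy = pten_pip_akt_rhs(y, (0, 0, 0), p)
        assert dy[I["PTEN"]] == pytest.approx(-p.d_pten * 500.0)
        # transcription of the PTEN gene itself is untouched
        dy_on = pten_pip_akt_rhs(y, (0, 0, 1), rko_params)
        assert dy_on[I["R_pten"]] > 0.0


def test_deterministic_fixed_point_unique_from_random_starts(rko_params):
    """Drug-free, genes frozen at their mean-field activity: the network
    relaxes to the same fixed point from random initial conditions."""
    y_ss, a = ns.steady_state(rko_params)
    rng = np.random.default_rng(7)
    finals = []
    for _ in range(4):
        y0 = rng.uniform(0.5, 2.0, N_SPECIES) * (y_ss + 10.0)
        y0[I["PIP3"]] = min(y0[I["PIP3"]], rko_params.PIP_tot)
        y0[I["Akt_p"]] = min(y0[I["Akt_p"]], rko_params.Akt_tot)
        sol = solve_ivp(lambda t, y: combined_rhs(y, a, rko_params, 0.0),
                        (0, 3e6), y0, method="LSODA", rtol=1e-10, atol=1e-8)
        assert sol.success
        finals.append(sol.y[:, -1])
    scale = np.abs(y_ss) + 1e-3 * np.max(np.abs(y_ss))
    for f in finals:
        assert np.max(np.abs(f - y_ss) / scale) < 1e-4
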