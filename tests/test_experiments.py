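import dataclasses

import numpy as np
import pytest

import nutlinsim as ns
from nutlinsim.model_core import N_SPECIES, SPECIES_INDEX, Trajectory
from nutlinsim.experiments import (
    SPLIT_PATTERNS,
    ViabilityRule,
    assess_viability,
    binomial_ci,
    build_schedule,
    compare_pten,
    run_dose_response_invitro,
)
from nutlinsim.pk import BindingParams, simulate_pk

I = SPECIES_INDEX

RULE = ViabilityRule(P_th=1000.0, tau=1.0, t_assess=10.0)


def make_traj(signal_fn, t_end=12.0, dt=0.02):
    """Synthetic trajectory whose free phospho-p53 follows ``signal_fn``."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    sp = np.zeros((t.size, N_SPECIES))
    sp[:, I["P_p"]] = np.array([signal_fn(x) for x in t])
    return Trajectory(t, sp, np.zeros((t.size, 3), dtype=int), [], seed=0)


def square_pulse(t0, width, height):
    return lambda t: height if t0 <= t < t0 + width else 0.0


class TestAssessViability:
    def test_signal_below_threshold_is_viable(self):
        out = assess_viability(make_traj(lambda t: 500.0), RULE)
        assert out.viable and out.trigger_time_h is None

    def test_long_pulse_triggers_at_start_plus_tau(self):
        out = assess_viability(make_traj(square_pulse(2.0, 2.0, 2000.0)), RULE)
        assert not out.viable
        assert out.trigger_time_h == pytest.approx(3.0, abs=0.05)

    def test_two_short_pulses_do_not_trigger(self):
        """Contiguity is required: two 0.6*tau excursions with a gap are
        harmless even though they total more than tau."""
        fn = lambda t: 2000.0 if (2.0 <= t < 2.6) or (4.0 <= t < 4.6) else 0.0
        assert assess_viability(make_traj(fn), RULE).viable

    def test_pulse_exactly_tau_triggers(self):
        out = assess_viability(make_traj(square_pulse(1.0, 1.05, 1500.0)), RULE)
        assert not out.viable

    def test_short_trajectory_rejected(self):
        with pytest.raises(ns.ValidationError):
            assess_viability(make_traj(lambda t: 0.0, t_end=5.0), RULE)

    def test_excursion_after_assessment_ignored(self):
        out = assess_viability(make_traj(square_pulse(9.5, 2.0, 2000.0)), RULE)
        assert out.viable

    def test_monotone_in_signal_and_threshold(self):
        """A pointwise-larger signal can only lose viability; a larger
        threshold can only regain it."""
        base = make_traj(square_pulse(2.0, 1.5, 1200.0))
        big = make_traj(square_pulse(2.0, 1.5, 2400.0))
        assert not assess_viability(base, RULE).viable
        assert not assess_viability(big, RULE).viable
        higher = dataclasses.replace(RULE, P_th=3000.0)
        assert assess_viability(base, higher).viable
        assert assess_viability(big, higher).viable

    def test_recovery_recounts_cell_viable(self):
        rule = dataclasses.replace(RULE, recovery_mean_h=0.01)
        traj = make_traj(square_pulse(1.0, 2.0, 2000.0))
        rng = np.random.default_rng(0)
        out = assess_viability(traj, rule, rng)
        assert out.viable and out.recovery_time_h is not None
        assert out.recovery_time_h > out.trigger_time_h
        slow = dataclasses.replace(RULE, recovery_mean_h=1e6)
        out2 = assess_viability(traj, slow, np.random.default_rng(0))
        assert not out2.viable

    def test_threshold_crossings_logged_on_request(self):
        traj = make_traj(square_pulse(2.0, 2.0, 2000.0))
        assess_viability(traj, RULE, log_events=True)
        kinds = [(e.direction, e.time_h) for e in traj.events
                 if e.kind == "threshold"]
        assert any(d == 1 and abs(t - 2.0) < 0.05 for d, t in kinds)
        assert any(d == -1 and abs(t - 4.0) < 0.05 for d, t in kinds)

    def test_complexed_phospho_counts_unless_restricted(self):
        t = np.arange(0.0, 12.01, 0.02)
        sp = np.zeros((t.size, N_SPECIES))
        sp[:, I["C_Pp"]] = 1500.0
        traj = Trajectory(t, sp, np.zeros((t.size, 3), dtype=int), [])
        assert not assess_viability(traj, RULE).viable
        free_rule = dataclasses.replace(RULE, free_only=True)
        assert assess_viability(traj, free_rule).viable


def test_binomial_ci_brackets_the_estimate():
    lo, hi = binomial_ci(30, 100)
    assert lo < 0.3 < hi
    assert binomial_ci(0, 50)[0] == 0.0
    assert binomial_ci(50, 50)[1] == 1.0


class TestSchedules:
    def test_split_patterns(self, rko_params):
        s = build_schedule(200.0, "4x12h", rko_params)
        assert [t for t, _ in s.doses] == [0.0, 12.0, 24.0, 36.0]
        assert all(d == 50.0 for _, d in s.doses)
        with pytest.raises(ns.ValidationError, match="split"):
            build_schedule(200.0, "5x1h", rko_params)

    def test_zero_interval_split_equals_single_bolus(self, rko_params):
        """Four simultaneous quarter-doses are one bolus (no binding)."""
        single = ns.DoseSchedule.single(100.0, 1.0, 1.7)
        split = ns.DoseSchedule.split(100.0, 4, 0.0, 1.0, 1.7)
        grid = np.linspace(0.0, 48.0, 97)
        b = BindingParams(0.0, 0.0)
        r1 = simulate_pk(single, b, 0.5, grid)
        r2 = simulate_pk(split, b, 0.5, grid)
        assert np.allclose(r1.total_uM, r2.total_uM, rtol=1e-9, atol=1e-12)

    def test_split_preserves_total_exposure(self, rko_params):
        """Equal total dose gives equal AUC of total drug (no binding):
        splitting changes the shape, not the exposure."""
        b = BindingParams(0.0, 0.0)
        grid = np.linspace(0.0, 400.0, 2001)
        auc1 = np.trapezoid(
            simulate_pk(ns.DoseSchedule.single(200.0, 1.0, 1.7), b, 0.5,
                        grid).total_uM, grid)
        auc4 = np.trapezoid(
            simulate_pk(ns.DoseSchedule.split(200.0, 4, 24.0, 1.0, 1.7), b,
                        0.5, grid).total_uM, grid)
        assert auc4 == pytest.approx(auc1, rel=1e-4)


@pytest.fixture(scope="module")
def quick_rule():
    return ViabilityRule(P_th=4500.0, tau=1.0, t_assess=6.0)


class TestDoseResponse:
    def test_untreated_cells_all_viable(self, rko_params, quick_rule):
        res = run_dose_response_invitro([0.0], rko_params, quick_rule,
                                        n_cells=4, seed=0)
        assert res[0].viable_fraction == 1.0

    def test_fixed_seed_reproducible(self, rko_params, quick_rule):
        kw = dict(rule=quick_rule, n_cells=3, seed=9)
        a = run_dose_response_invitro([30.0], rko_params, **kw)
        b = run_dose_response_invitro([30.0], rko_params, **kw)
        assert a[0].viable_fraction == b[0].viable_fraction
        assert [o.viable for o in a[0].outcomes] == \
               [o.viable for o in b[0].outcomes]

    def test_negative_concentration_rejected(self, rko_params):
        with pytest.raises(ns.ValidationError):
            run_dose_response_invitro([-1.0], rko_params, n_cells=1)


def test_compare_pten_is_a_no_op_without_pten_production(rko_params):
    """With PTEN translation already zero, disabling the feedback changes
    nothing: matched seeds give identical outcomes."""
    p = rko_params.replace(s_prot_pten=0.0)
    rule = ViabilityRule(P_th=4500.0, tau=1.0, t_assess=6.0)
    cmp_ = compare_pten(10.0, p, rule=rule, n_cells=3, seed=4)
    assert cmp_.difference == 0.0
    assert [o.viable for o in cmp_.on.outcomes] == \
           [o.viable for o in cmp_.off.outcomes]
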