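"""Staircase-engine checks: the 3-down/1-up rule, reversals, termination,
threshold estimation, and session aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cohermetrics.observers import PsychometricObserver
from cohermetrics.staircase import (CONVERGENCE_P, SessionResult, StaircaseConfig,
                                    estimate_threshold, run_session, run_staircase,
                                    update_staircase)


def make_state(config, **kw):
    state = config.start_state()
    for key, val in kw.items():
        setattr(state, key, val)
    return state


class TestUpdateRule:
    def test_third_consecutive_correct_moves_down(self):
        cfg = StaircaseConfig(total_elements=200)
        st_ = make_state(cfg, level=64, step=16, consecutive_correct=2,
                         direction="descending")
        update_staircase(st_, cfg, correct=True)
        assert st_.level == 48
        assert st_.consecutive_correct == 0
        assert st_.reversal_levels == []

    def test_error_reverses_and_halves_step(self):
        cfg = StaircaseConfig(total_elements=200)
        st_ = make_state(cfg, level=40, step=16, direction="descending")
        update_staircase(st_, cfg, correct=False)
        assert st_.reversal_levels == [40]  # recorded at the pre-move level
        assert st_.step == 8
        assert st_.direction == "ascending"

    def test_partial_correct_run_does_not_move(self):
        cfg = StaircaseConfig(total_elements=200)
        st_ = make_state(cfg, level=40, step=8, consecutive_correct=1,
                         direction="descending")
        update_staircase(st_, cfg, correct=True)
        assert st_.level == 40
        assert st_.consecutive_correct == 2

    def test_sixth_floor_reversal_terminates(self):
        cfg = StaircaseConfig(total_elements=200)
        st_ = make_state(cfg, level=20, step=1, direction="descending",
                         floor_reversals=5)
        update_staircase(st_, cfg, correct=False)
        assert st_.terminated

    def test_update_after_termination_rejected(self):
        cfg = StaircaseConfig(total_elements=200)
        st_ = make_state(cfg, terminated=True)
        with pytest.raises(RuntimeError):
            update_staircase(st_, cfg, correct=True)

    def test_level_clamped_at_boundaries_without_spurious_reversal(self):
        cfg = StaircaseConfig(total_elements=200)
        st_ = make_state(cfg, level=195, step=200, direction="ascending")
        update_staircase(st_, cfg, correct=False)  # same direction: no reversal
        assert st_.level == 200
        assert st_.reversal_levels == []

    @given(responses=st.lists(st.booleans(), min_size=1, max_size=400))
    def test_trajectory_invariants(self, responses):
        """Step sizes never grow, levels stay in range, termination is exact."""
        cfg = StaircaseConfig(total_elements=50)
        st_ = cfg.start_state()
        last_step = st_.step
        for r in responses:
            if st_.terminated:
                break
            update_staircase(st_, cfg, r)
            assert st_.step <= last_step
            last_step = st_.step
            assert 0 <= st_.level <= cfg.total_elements
        assert st_.terminated == (st_.floor_reversals >= 6)


class TestEstimate:
    def test_mean_of_last_six_reversals(self):
        cfg = StaircaseConfig(total_elements=200)
        st_ = make_state(cfg, terminated=True,
                         reversal_levels=[80, 40, 20, 14, 18, 12, 16, 10],
                         reversal_steps=[100, 50, 1, 1, 1, 1, 1, 1])
        # last six: 20, 14, 18, 12, 16, 10 -> mean 15 of 200 elements
        assert estimate_threshold(st_, cfg) == pytest.approx(7.5)

    def test_constant_reversals_give_exact_level(self):
        cfg = StaircaseConfig(total_elements=50)
        st_ = make_state(cfg, terminated=True, reversal_levels=[7] * 6,
                         reversal_steps=[1] * 6)
        assert estimate_threshold(st_, cfg) == pytest.approx(100 * 7 / 50)

    def test_estimate_before_termination_rejected(self):
        cfg = StaircaseConfig(total_elements=200)
        with pytest.raises(RuntimeError):
            estimate_threshold(cfg.start_state(), cfg)

    def test_floor_only_switch_selects_floor_reversals(self):
        cfg = StaircaseConfig(total_elements=200, estimate_from="floor_only")
        st_ = make_state(cfg, terminated=True,
                         reversal_levels=[80, 10, 12, 10, 12, 10, 12, 10],
                         reversal_steps=[100, 1, 1, 1, 1, 1, 1, 1])
        assert estimate_threshold(st_, cfg) == pytest.approx(100 * 11 / 200)


class TestRunStaircase:
    def test_deterministic_step_observer_recovers_its_edge(self):
        """An observer correct above T elements and wrong at/below localises T."""
        cfg = StaircaseConfig(total_elements=200)
        for T in (10, 35, 80):
            st_ = run_staircase(None, cfg, seed=0,
                                trial_fn=lambda c, rng, T=T: c * 2.0 > T)
            est_elements = estimate_threshold(st_, cfg) * 2.0
            assert abs(est_elements - T) <= 1.0

    def test_perfect_observer_descends_to_floor(self):
        """Correct whenever any signal is present: threshold pinned near zero."""
        cfg = StaircaseConfig(total_elements=200)
        st_ = run_staircase(None, cfg, seed=1, trial_fn=lambda c, rng: c > 0.0)
        assert estimate_threshold(st_, cfg) <= 100 * 3 / 200

    def test_chance_observer_stays_high(self):
        cfg = StaircaseConfig(total_elements=50)
        ests = []
        for child in np.random.SeedSequence(8).spawn(500):
            rng = np.random.default_rng(child)
            st_ = run_staircase(None, cfg, rng,
                                trial_fn=lambda c, r: bool(r.random() < 0.5))
            ests.append(estimate_threshold(st_, cfg))
        assert np.mean(ests) > 60.0

    def test_trial_log_reproducible_under_seed(self):
        obs = PsychometricObserver(20.0)
        cfg = StaircaseConfig(total_elements=200)
        a = run_staircase(obs, cfg, seed=42)
        b = run_staircase(obs, cfg, seed=42)
        assert a.trial_log == b.trial_log
        assert a.reversal_levels == b.reversal_levels

    def test_non_terminating_run_aborts_with_diagnostic(self):
        # always correct even at zero signal: monotone descent, no reversal
        cfg = StaircaseConfig(total_elements=200, max_trials=200)
        with pytest.raises(RuntimeError, match="failed to terminate"):
            run_staircase(None, cfg, seed=0, trial_fn=lambda c, rng: True)


class TestSession:
    def test_fewer_than_four_staircases_rejected(self):
        with pytest.raises(ValueError):
            run_session(PsychometricObserver(20.0), StaircaseConfig(), 0, n_staircases=3)

    def test_session_threshold_is_mean_of_staircases(self):
        res = SessionResult([8.0, 10.0, 12.0, 14.0], states=[None] * 4)
        assert res.session_threshold_pct == pytest.approx(11.0)

    def test_averaging_shrinks_variance(self):
        obs = PsychometricObserver(20.0)
        cfg = StaircaseConfig(total_elements=200)
        singles, sessions = [], []
        for i, child in enumerate(np.random.SeedSequence(9).spawn(150)):
            st_ = run_staircase(obs, cfg, np.random.default_rng(child))
            singles.append(estimate_threshold(st_, cfg))
            sessions.append(run_session(obs, cfg, 10_000 + i).session_threshold_pct)
        assert np.var(sessions) < np.var(singles)

    def test_convergence_at_the_793_equilibrium(self):
        """The 3-down/1-up equilibrium solves p^3 = 1/2."""
        assert CONVERGENCE_P == pytest.approx(0.7937, abs=5e-5)
        assert CONVERGENCE_P ** 3 == pytest.approx(0.5)
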