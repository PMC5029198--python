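"""Stimulus-engine checks: signal counts, displacement geometry, noise symmetry."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cohermetrics.stimuli import (CoherenceSpec, DisplayGeometry, ElementSpec,
                                  collapse_to_static_form, empirical_coherence,
                                  generate_bar_sequence, generate_rdk_sequence,
                                  generate_temporal_form_sequence, read_frames,
                                  signal_count, write_frames)


class TestGeometryAndSpecs:
    def test_update_rate_must_divide_refresh(self):
        DisplayGeometry(refresh_hz=75.0, update_hz=18.75)  # 4 frames per update
        with pytest.raises(ValueError):
            DisplayGeometry(refresh_hz=75.0, update_hz=20.0)

    def test_stimulus_duration_rounds_to_printed_value(self, geometry, dots):
        seq = generate_rdk_sequence(geometry, dots, CoherenceSpec(50.0, "up"), 0)
        assert seq.duration_s == pytest.approx(8 / 18.75)
        assert round(seq.duration_s, 2) == 0.43

    @pytest.mark.parametrize("bad", [-1.0, 100.5])
    def test_coherence_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            CoherenceSpec(bad, "up")

    def test_zero_elements_rejected(self):
        with pytest.raises(ValueError):
            ElementSpec(kind="dot", count=0)

    @given(c=st.floats(0.0, 100.0), n=st.sampled_from([50, 200]))
    def test_signal_count_rounds_to_nearest_element(self, c, n):
        k = signal_count(c, n)
        assert 0 <= k <= n
        assert abs(k - c / 100.0 * n) <= 0.5


class TestRdk:
    def test_full_coherence_moves_every_dot_up(self, geometry, dots):
        seq = generate_rdk_sequence(geometry, dots, CoherenceSpec(100.0, "up"), 11)
        disp = seq.displacements()
        assert np.allclose(disp[:, :, 1], 0.12)
        assert np.allclose(disp[:, :, 0], 0.0)
        assert empirical_coherence(seq) == 100.0

    def test_frame_and_element_counts(self, geometry, dots):
        seq = generate_rdk_sequence(geometry, dots, CoherenceSpec(30.0, "down"), 3)
        assert seq.frames.shape == (8, 200, 2)
        assert seq.element_roles.shape == (7, 200)

    def test_displacement_magnitude_constant(self, geometry, dots):
        seq = generate_rdk_sequence(geometry, dots, CoherenceSpec(35.0, "up"), 5)
        mags = np.linalg.norm(seq.displacements(), axis=2)
        assert np.allclose(mags, 0.12)

    def test_positions_stay_inside_window(self, geometry, dots):
        seq = generate_rdk_sequence(geometry, dots, CoherenceSpec(0.0, "up"), 9)
        assert np.all(seq.frames >= 0.0)
        assert np.all(seq.frames[:, :, 0] < geometry.window_width_deg)
        assert np.all(seq.frames[:, :, 1] < geometry.window_height_deg)

    def test_half_coherence_labels_exactly_100_per_update(self, geometry, dots):
        labels = set()
        for seed in range(50):
            seq = generate_rdk_sequence(geometry, dots, CoherenceSpec(50.0, "up"), seed)
            assert np.all(seq.element_roles.sum(axis=1) == 100)
            for u in range(7):
                labels.add(frozenset(np.flatnonzero(seq.element_roles[u])))
        # assignment re-randomised each update: label sets differ across updates
        assert len(labels) > 300

    def test_zero_coherence_noise_is_directionally_unbiased(self, geometry, dots):
        means = []
        for seed in range(1000):
            seq = generate_rdk_sequence(geometry, dots, CoherenceSpec(0.0, "up"), seed)
            means.append(seq.displacements()[:, :, 1].mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-12

    def test_seed_determinism_bit_for_bit(self, geometry, dots):
        spec = CoherenceSpec(42.0, "down")
        a = generate_rdk_sequence(geometry, dots, spec, 123)
        b = generate_rdk_sequence(geometry, dots, spec, 123)
        c = generate_rdk_sequence(geometry, dots, spec, 124)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.element_roles, b.element_roles)
        assert not np.array_equal(a.frames, c.frames)

    def test_requires_dot_elements(self, geometry, bars):
        with pytest.raises(ValueError):
            generate_rdk_sequence(geometry, bars, CoherenceSpec(50.0, "up"), 0)

    def test_empirical_coherence_exceeds_nominal(self, geometry, dots):
        vals = [empirical_coherence(generate_rdk_sequence(
            geometry, dots, CoherenceSpec(60.0, "up"), s)) for s in range(200)]
        assert np.mean(vals) >= 60.0


class TestBars:
    def test_full_coherence_down(self, geometry, bars):
        seq = generate_bar_sequence(geometry, bars, CoherenceSpec(100.0, "down"), 2)
        assert np.allclose(seq.displacements()[:, :, 1], -0.12)

    def test_forty_percent_gives_twenty_signal_bars(self, geometry, bars):
        seq = generate_bar_sequence(geometry, bars, CoherenceSpec(40.0, "up"), 4)
        assert np.all(seq.element_roles.sum(axis=1) == 20)

    def test_noise_directions_are_fair_coins(self, geometry, bars):
        ups = total = 0
        for seed in range(29):  # 29 x 350 bar-updates > 10^4
            seq = generate_bar_sequence(geometry, bars, CoherenceSpec(0.0, "up"), seed)
            dy = seq.displacements()[:, :, 1]
            ups += int((dy > 0).sum())
            total += dy.size
        # binomial 99% CI around 0.5
        half_width = 2.576 * np.sqrt(0.25 / total)
        assert abs(ups / total - 0.5) < half_width

    def test_empirical_coherence_at_zero_is_about_fifty(self, geometry, bars):
        vals = np.array([empirical_coherence(generate_bar_sequence(
            geometry, bars, CoherenceSpec(0.0, "up"), s)) for s in range(1000)])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 50.0) < 3 * se


class TestStaticForm:
    def test_full_coherence_vertical_streaks(self, geometry, dots):
        img = collapse_to_static_form(geometry, dots, CoherenceSpec(100.0, "vertical"), 6)
        extent_y = img.trails[:, :, 1].max(axis=0) - img.trails[:, :, 1].min(axis=0)
        extent_x = img.trails[:, :, 0].max(axis=0) - img.trails[:, :, 0].min(axis=0)
        assert np.allclose(extent_y, 7 * 0.12)
        assert np.allclose(extent_x, 0.0)

    def test_position_count_is_images_times_dots(self, geometry, dots):
        img = collapse_to_static_form(geometry, dots, CoherenceSpec(37.0, "horizontal"), 8)
        assert img.dot_positions.shape == (8 * 200, 2)

    def test_signal_assignment_fixed_across_sequence(self, geometry, dots):
        img = collapse_to_static_form(geometry, dots, CoherenceSpec(50.0, "vertical"), 1)
        sig = img.trails[:, img.signal_mask, :]
        steps = np.diff(sig, axis=0)
        # every signal step lies on the vertical axis, same sign per dot
        assert np.allclose(steps[:, :, 0], 0.0)
        assert np.all(np.abs(steps[:, :, 1].sum(axis=0)) == pytest.approx(7 * 0.12))

    def test_zero_coherence_orientation_unconstrained(self, geometry, dots):
        vertical_like = []
        for seed in range(200):
            img = collapse_to_static_form(geometry, dots, CoherenceSpec(0.0, "vertical"), seed)
            net = img.trails[-1] - img.trails[0]
            vertical_like.append((np.abs(net[:, 1]) > np.abs(net[:, 0])).mean())
        # random-walk trails: no preference for the nominal axis
        assert abs(np.mean(vertical_like) - 0.5) < 0.02


class TestTemporalForm:
    def test_exactly_half_the_dots_move_each_update(self, geometry, dots):
        for c in (0.0, 40.0, 100.0):
            seq = generate_temporal_form_sequence(
                geometry, dots, CoherenceSpec(c, "vertical"), 13)
            disp = np.linalg.norm(seq.displacements(), axis=2)
            assert np.all((disp > 1e-12).sum(axis=1) == 100)
            assert np.all(seq.element_roles.sum(axis=1) == 100)

    def test_populations_alternate_strictly(self, geometry, dots):
        seq = generate_temporal_form_sequence(
            geometry, dots, CoherenceSpec(50.0, "horizontal"), 21)
        for u in range(7):
            moving = np.flatnonzero(seq.element_roles[u])
            assert np.all(seq.populations[moving] == (1 if u % 2 == 0 else 2))

    def test_full_coherence_membership_matches_side(self, geometry, dots):
        seq = generate_temporal_form_sequence(
            geometry, dots, CoherenceSpec(100.0, "vertical"), 17)
        left = seq.frames[0][:, 0] < geometry.window_width_deg / 2.0
        assert np.all(seq.populations[left] == 1)
        assert np.all(seq.populations[~left] == 2)

    def test_zero_coherence_membership_independent_of_side(self, geometry, dots):
        assoc = []
        for seed in range(300):
            seq = generate_temporal_form_sequence(
                geometry, dots, CoherenceSpec(0.0, "vertical"), seed)
            left = seq.frames[0][:, 0] < geometry.window_width_deg / 2.0
            assoc.append((seq.populations[left] == 1).mean() - 0.5)
        assoc = np.asarray(assoc)
        se = assoc.std(ddof=1) / np.sqrt(len(assoc))
        assert abs(assoc.mean()) < 3 * se + 1e-12

    def test_empirical_coherence_rejects_form_tasks(self, geometry, dots):
        seq = generate_temporal_form_sequence(
            geometry, dots, CoherenceSpec(50.0, "vertical"), 0)
        with pytest.raises(ValueError):
            empirical_coherence(seq)


class TestExport:
    def test_frame_table_round_trip(self, geometry, dots, tmp_path):
        seq = generate_rdk_sequence(geometry, dots, CoherenceSpec(25.0, "up"), 77)
        path = tmp_path / "frames.csv"
        write_frames(seq, path)
        back = read_frames(path)
        assert back.task_kind == "rdk_motion"
        assert back.signal_direction == "up"
        assert np.allclose(back.frames, seq.frames)
        assert np.array_equal(back.element_roles, seq.element_roles)
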