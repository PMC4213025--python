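"""Trajectory reading, resampling, kinematic decomposition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import termwalk as tw
from termwalk.trajectory import _wrap_angle


def _traj(xy, dt=0.5, **kw):
    xy = np.asarray(xy, dtype=float)
    t = np.arange(len(xy)) * dt
    return tw.Trajectory(t=t, x=xy[:, 0], y=xy[:, 1], **kw)


# ---------------------------------------------------------------------------
# reading and validation


class TestReadTrajectory:
    def test_two_columns_synthesize_clock(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("0,0\n1,0\n1,1\n")
        traj = tw.read_trajectory(p, dt=0.5)
        np.testing.assert_allclose(traj.t, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(traj.x, [0, 1, 1])

    def test_header_row_skipped(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("x,y\n0,0\n1,0\n1,1\n")
        traj = tw.read_trajectory(p, dt=0.5)
        assert traj.n_samples == 3

    @pytest.mark.parametrize("sep", [",", "\t", " "])
    def test_delimiters_autodetected(self, tmp_path, sep):
        p = tmp_path / "t.txt"
        p.write_text(f"0{sep}0\n1{sep}0\n2{sep}1\n")
        traj = tw.read_trajectory(p, dt=1.0)
        assert traj.n_samples == 3

    def test_three_columns_use_file_clock(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("0,0,0\n0.5,1,0\n1.0,1,1\n")
        traj = tw.read_trajectory(p)
        assert traj.dt == pytest.approx(0.5)

    def test_scale_applied_to_positions(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("0,0\n2,0\n4,0\n")
        traj = tw.read_trajectory(p, dt=0.5, scale=0.25)
        np.testing.assert_allclose(traj.x, [0, 0.5, 1.0])

    def test_non_numeric_row_reports_line(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("0,0\n1,oops\n2,2\n")
        with pytest.raises(ValueError, match="row 2"):
            tw.read_trajectory(p, dt=0.5)

    def test_irregular_clock_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("0,0,0\n0.5,1,0\n1.5,1,1\n")
        with pytest.raises(ValueError, match="non-constant"):
            tw.read_trajectory(p)

    def test_too_few_rows(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("0,0\n")
        with pytest.raises(ValueError):
            tw.read_trajectory(p, dt=0.5)

    def test_missing_dt_for_xy(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("0,0\n1,0\n")
        with pytest.raises(ValueError, match="dt"):
            tw.read_trajectory(p)


class TestTrajectoryInvariants:
    def test_points_outside_arena_rejected(self):
        with pytest.raises(ValueError, match="arena"):
            _traj([(0, 0), (300, 0), (0, 5)], arena_diameter=205.0,
                  arena_center=(0.0, 0.0))

    def test_strictly_increasing_time_required(self):
        with pytest.raises(ValueError, match="increasing"):
            tw.Trajectory(t=[0, 0.5, 0.5], x=[0, 1, 2], y=[0, 0, 0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            tw.Trajectory(t=[0, 0.5], x=[0, 1, 2], y=[0, 0, 0])


# ---------------------------------------------------------------------------
# resampling


class TestResample:
    def test_dt_multiplied(self):
        traj = _traj(np.zeros((9, 2)) + np.arange(9)[:, None], dt=0.5)
        assert tw.resample(traj, 4).dt == pytest.approx(2.0)

    def test_coarse_step_is_vector_sum(self):
        traj = _traj([(0, 0), (1, 0), (1, 1)], dt=0.5)
        coarse = tw.resample(traj, 2)
        steps = tw.compute_steps(coarse)
        np.testing.assert_allclose(steps.lengths, [np.sqrt(2)])

    def test_identity_factor(self):
        traj = _traj([(0, 0), (1, 0), (1, 1)], dt=0.5)
        same = tw.resample(traj, 1)
        np.testing.assert_array_equal(same.x, traj.x)
        np.testing.assert_array_equal(same.t, traj.t)

    def test_non_integer_factor_rejected(self):
        traj = _traj([(0, 0), (1, 0), (1, 1)])
        with pytest.raises(ValueError):
            tw.resample(traj, 0)
        with pytest.raises(ValueError):
            tw.resample(traj, 1.5)

    @given(st.integers(2, 5), st.integers(2, 4))
    def test_composition(self, a, b):
        rng = np.random.default_rng(7)
        traj = _traj(rng.normal(size=(200, 2)), dt=0.5)
        once = tw.resample(traj, a * b)
        twice = tw.resample(tw.resample(traj, a), b)
        np.testing.assert_array_equal(once.x, twice.x)
        np.testing.assert_array_equal(once.t, twice.t)

    def test_resampling_conserves_total_displacement(self, rng):
        traj = _traj(rng.normal(size=(101, 2)), dt=0.5)
        for f in (2, 5, 10):
            coarse = tw.resample(traj, f)
            assert coarse.x[-1] == traj.x[: len(coarse.x) * f : f][-1]
            # coarse displacement equals summed fine displacements exactly
            fine_dx = np.diff(traj.x)
            coarse_dx = np.diff(coarse.x)
            np.testing.assert_allclose(
                coarse_dx,
                np.add.reduceat(fine_dx, np.arange(0, len(coarse_dx) * f, f)),
                rtol=0, atol=1e-12,
            )


# ---------------------------------------------------------------------------
# steps and turning angles


class TestComputeSteps:
    def test_three_four_five(self):
        steps = tw.compute_steps(_traj([(0, 0), (3, 4)]))
        np.testing.assert_allclose(steps.lengths, [5.0])

    def test_collinear_turn_zero(self):
        steps = tw.compute_steps(_traj([(0, 0), (1, 0), (2, 0)]))
        np.testing.assert_allclose(steps.turns, [0.0])

    def test_reversal_wraps_to_minus_pi(self):
        steps = tw.compute_steps(_traj([(0, 0), (1, 0), (0, 0)]))
        np.testing.assert_allclose(steps.turns, [-np.pi])

    def test_turns_undefined_across_zero_steps(self):
        steps = tw.compute_steps(_traj([(0, 0), (1, 0), (1, 0), (2, 0)]))
        assert np.isnan(steps.turns).all()

    def test_wrap_range(self):
        angles = np.linspace(-10, 10, 1001)
        wrapped = _wrap_angle(angles)
        assert (wrapped >= -np.pi).all() and (wrapped < np.pi).all()

    @given(
        st.floats(-100, 100),
        st.floats(-100, 100),
        st.floats(0, 2 * np.pi),
    )
    def test_rigid_motion_invariance(self, tx, ty, phi):
        rng = np.random.default_rng(3)
        xy = rng.normal(size=(50, 2)) * 5
        base = tw.compute_steps(_traj(xy))
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        moved = xy @ R.T + [tx, ty]
        other = tw.compute_steps(_traj(moved))
        np.testing.assert_allclose(other.lengths, base.lengths, atol=1e-9)
        np.testing.assert_allclose(
            np.sin(other.turns), np.sin(base.turns), atol=1e-9
        )
        np.testing.assert_allclose(
            np.cos(other.turns), np.cos(base.turns), atol=1e-9
        )


class TestWaitingBouts:
    def test_hand_enumeration(self):
        steps = tw.StepSeries(
            dt=0.5, lengths=[0.4, 0, 0, 0.3, 0], headings=np.zeros(5),
            turns=np.zeros(3),
        )
        bouts = tw.extract_waiting_bouts(steps)
        assert [b.duration for b in bouts] == [1.0, 0.5]
        assert [b.start_index for b in bouts] == [1, 4]

    def test_no_zero_steps(self):
        steps = tw.StepSeries(
            dt=0.5, lengths=[1.0, 2.0], headings=np.zeros(2), turns=np.zeros(0)
        )
        assert tw.extract_waiting_bouts(steps) == []

    def test_minimum_bout_is_one_interval(self):
        steps = tw.StepSeries(
            dt=0.5, lengths=[0.0, 1.0], headings=np.zeros(2), turns=np.zeros(0)
        )
        (bout,) = tw.extract_waiting_bouts(steps)
        assert bout.duration == 0.5

    @given(st.lists(st.sampled_from([0.0, 1.0]), min_size=1, max_size=60))
    def test_total_wait_identity(self, pattern):
        lengths = np.array(pattern)
        steps = tw.StepSeries(
            dt=0.5, lengths=lengths, headings=np.zeros(len(lengths)),
            turns=np.zeros(max(len(lengths) - 1, 0)),
        )
        waits = tw.extract_waiting_bouts(steps)
        assert tw.total_waiting_time(waits) == pytest.approx(
            0.5 * np.count_nonzero(lengths == 0), abs=0
        )


class TestZones:
    def _arena_traj(self, points):
        return _traj(points, arena_diameter=205.0, arena_center=(0.0, 0.0))

    def test_center_is_interior(self):
        traj = self._arena_traj([(0, 0), (1, 0), (0, 1)])
        zones = tw.label_zones(traj, wall_band=10.0, waits=[])
        assert zones.labels[0] == "interior"

    def test_near_boundary_is_wall(self):
        traj = self._arena_traj([(97.5, 0), (0, 0), (0, 1)])
        zones = tw.label_zones(traj, wall_band=10.0, waits=[])
        assert zones.labels[0] == "wall"

    def test_waiting_takes_precedence_over_wall(self):
        traj = self._arena_traj([(97.5, 0), (97.5, 0), (0, 0)])
        steps = tw.compute_steps(traj)
        waits = tw.extract_waiting_bouts(steps)
        zones = tw.label_zones(traj, wall_band=10.0, waits=waits)
        assert zones.labels[0] == "waiting"
        assert zones.labels[1] == "waiting"

    def test_requires_arena(self):
        traj = _traj([(0, 0), (1, 0)])
        with pytest.raises(ValueError, match="arena"):
            tw.label_zones(traj, waits=[])


class TestTurningHistogram:
    def test_collinear_mass_at_zero(self):
        xy = np.column_stack([np.arange(50.0), np.zeros(50)])
        centers, probs = tw.turning_angle_histogram(tw.compute_steps(_traj(xy)))
        assert probs.max() == pytest.approx(1.0)
        assert abs(centers[np.argmax(probs)]) <= 5.0  # the bin containing 0 deg

    def test_probabilities_sum_to_one(self, rng):
        xy = np.cumsum(rng.normal(size=(500, 2)), axis=0)
        _, probs = tw.turning_angle_histogram(tw.compute_steps(_traj(xy)))
        assert probs.sum() == pytest.approx(1.0)

    def test_uniform_headings_flat(self):
        from scipy.stats import chisquare

        rng = np.random.default_rng(99)
        headings = rng.uniform(0, 2 * np.pi, 10**5)
        xy = np.vstack(
            [[0, 0], np.cumsum(np.column_stack([np.cos(headings), np.sin(headings)]), axis=0)]
        )
        steps = tw.compute_steps(_traj(xy))
        turns = steps.turns[np.isfinite(steps.turns)]
        counts, _ = np.histogram(turns, bins=36, range=(-np.pi, np.pi))
        assert chisquare(counts).pvalue > 0.01

    def test_error_when_no_turns(self):
        steps = tw.compute_steps(_traj([(0, 0), (0, 0), (0, 0)]))
        with pytest.raises(ValueError):
            tw.turning_angle_histogram(steps)
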