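"""Order parameters: analytic cases, oracle equivalence, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shoalstates.errors import InsufficientDataError, ParameterError
from shoalstates.io import FrameView
from shoalstates.order import (
    local_polarization,
    polarization,
    rotation,
    shell_profile,
    smooth_series,
)
from shoalstates.synth import make_archetype


def _frame(positions, headings, speeds=None, valid=None):
    positions = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    n = len(positions)
    return FrameView(
        frame_index=0,
        ids=np.arange(n),
        positions=positions,
        velocities=headings.copy(),
        headings=headings,
        speeds=np.ones(n) if speeds is None else np.asarray(speeds, dtype=float),
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool),
    )


def _brute_polarization(headings):
    sx = sy = 0.0
    for ux, uy in headings:
        sx += ux
        sy += uy
    return math.hypot(sx / len(headings), sy / len(headings))


def _brute_rotation(positions, headings):
    cx = sum(p[0] for p in positions) / len(positions)
    cy = sum(p[1] for p in positions) / len(positions)
    total = 0.0
    for (x, y), (ux, uy) in zip(positions, headings):
        rx, ry = x - cx, y - cy
        d = math.hypot(rx, ry)
        if d > 1e-12:
            total += (rx * uy - ry * ux) / d
    return total / len(positions)


class TestPolarization:
    def test_identical_headings_give_one(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 100, (50, 2))
        u = np.tile([math.cos(0.7), math.sin(0.7)], (50, 1))
        assert polarization(_frame(pos, u)) == pytest.approx(1.0, abs=1e-12)

    def test_antiparallel_pairs_cancel(self):
        rng = np.random.default_rng(1)
        ang = rng.uniform(0, 2 * np.pi, 10)
        u = np.concatenate(
            [np.column_stack((np.cos(ang), np.sin(ang))),
             -np.column_stack((np.cos(ang), np.sin(ang)))]
        )
        pos = rng.uniform(0, 100, (20, 2))
        assert polarization(_frame(pos, u)) == pytest.approx(0.0, abs=1e-12)

    def test_three_headings_at_120_degrees_cancel(self):
        ang = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        u = np.column_stack((np.cos(ang), np.sin(ang)))
        assert polarization(_frame(np.zeros((3, 2)), u)) == pytest.approx(0.0, abs=1e-12)

    def test_no_valid_fish_is_nan(self):
        f = _frame([[0, 0]], [[1, 0]], valid=[False])
        assert math.isnan(polarization(f))


class TestRotation:
    def test_perfect_ccw_mill_gives_one(self):
        theta = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        pos = np.column_stack((np.cos(theta), np.sin(theta)))
        u = np.column_stack((-np.sin(theta), np.cos(theta)))
        signed, mag = rotation(_frame(pos, u))
        assert mag == pytest.approx(1.0, abs=1e-12)
        assert signed > 0  # counter-clockwise positive

    def test_mirror_symmetric_translation_has_zero_rotation(self):
        pos = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        u = np.tile([1.0, 0.0], (4, 1))
        signed, _ = rotation(_frame(pos, u))
        assert signed == pytest.approx(0.0, abs=1e-12)

    def test_two_ccw_one_cw_thirds(self):
        theta = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        pos = np.column_stack((np.cos(theta), np.sin(theta)))
        u = np.column_stack((-np.sin(theta), np.cos(theta)))
        u[2] = -u[2]  # one fish swims clockwise
        signed, mag = rotation(_frame(pos, u))
        assert mag == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_single_fish_is_nan(self):
        signed, mag = rotation(_frame([[0, 0]], [[1, 0]]))
        assert math.isnan(signed) and math.isnan(mag)


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=2, max_value=20), st.integers(min_value=0, max_value=10_000))
def test_order_parameters_match_per_fish_loop_oracle(n, seed):
    """Vectorised order parameters equal an explicit per-fish loop to 1e-12."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-50, 50, (n, 2))
    ang = rng.uniform(0, 2 * np.pi, n)
    u = np.column_stack((np.cos(ang), np.sin(ang)))
    f = _frame(pos, u)
    assert polarization(f) == pytest.approx(_brute_polarization(u), abs=1e-12)
    signed, mag = rotation(f)
    expected = _brute_rotation(pos, u)
    assert signed == pytest.approx(expected, abs=1e-12)
    assert mag == pytest.approx(abs(expected), abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(
    st.integers(min_value=2, max_value=15),
    st.integers(min_value=0, max_value=10_000),
    st.floats(min_value=-3.0, max_value=3.0),
    st.floats(min_value=-100, max_value=100),
    st.floats(min_value=-100, max_value=100),
)
def test_order_parameters_invariant_under_rigid_motion(n, seed, angle, tx, ty):
    """Global rotation + translation leave both order parameters unchanged."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-10, 10, (n, 2))
    ang = rng.uniform(0, 2 * np.pi, n)
    u = np.column_stack((np.cos(ang), np.sin(ang)))
    c, s = math.cos(angle), math.sin(angle)
    R = np.array([[c, -s], [s, c]])
    f1 = _frame(pos, u)
    f2 = _frame(pos @ R.T + [tx, ty], u @ R.T)
    assert polarization(f2) == pytest.approx(polarization(f1), abs=1e-9)
    assert rotation(f2)[1] == pytest.approx(rotation(f1)[1], abs=1e-9)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        x = np.full(100, 0.4)
        assert smooth_series(x, 30) == pytest.approx(x)

    def test_alternating_series_span3(self):
        x = np.array([0, 1, 0, 1, 0, 1, 0], dtype=float)
        out = smooth_series(x, 3)
        assert out[1:-1] == pytest.approx([1 / 3, 2 / 3, 1 / 3, 2 / 3, 1 / 3])

    def test_interior_impulse_mass_preserved(self):
        x = np.zeros(200)
        x[100] = 1.0
        assert smooth_series(x, 30).sum() == pytest.approx(1.0)

    def test_span_exceeding_length_gives_global_mean(self):
        x = np.array([0.0, 1.0, 0.5])
        out = smooth_series(x, 99)
        # symmetric truncation: only the centre sample sees the full window
        assert out[1] == pytest.approx(0.5)

    def test_output_length_and_nan_passthrough(self):
        x = np.array([0.1, np.nan, 0.3, 0.5])
        out = smooth_series(x, 3)
        assert len(out) == 4
        assert math.isnan(out[1])

    def test_invalid_span_rejected(self):
        with pytest.raises(ParameterError):
            smooth_series(np.ones(5), 0)


class TestLocalPolarization:
    def test_isolated_focal_scores_one(self):
        f = _frame([[0, 0], [100, 0]], [[1, 0], [-1, 0]])
        assert local_polarization(f, 0, radius=10) == pytest.approx(1.0)

    def test_aligned_neighbor_scores_one(self):
        f = _frame([[0, 0], [5, 0]], [[1, 0], [1, 0]])
        assert local_polarization(f, 0, radius=15.6) == pytest.approx(1.0)

    def test_radius_filter_and_cancellation(self):
        f = _frame(
            [[0, 0], [5, 0], [100, 0]],
            [[1, 0], [-1, 0], [0, 1]],
        )
        assert local_polarization(f, 0, radius=15.6) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_focal_id(self):
        f = _frame([[0, 0]], [[1, 0]])
        with pytest.raises(LookupError):
            local_polarization(f, 99, radius=10)


class TestShellProfile:
    def test_single_ring_occupies_outer_shell(self):
        # all fish at 0.9 R with tangential headings: R = 0.9R ring radius,
        # so d/width = 6 exactly -> absorbed by shell 6
        f = make_archetype("mill", 36, 0, radius=10.0)
        prof = shell_profile([f])
        assert prof.occupancy[5] == 36
        assert prof.occupancy[:5].sum() == 0
        assert prof.rotation[5] == pytest.approx(1.0, abs=1e-12)

    def test_rigid_rotation_speed_increases_linearly(self):
        rng = np.random.default_rng(3)
        omega = 0.8
        r = np.sqrt(rng.uniform(4, 400, 200))
        th = rng.uniform(0, 2 * np.pi, 200)
        pos = np.column_stack((r * np.cos(th), r * np.sin(th)))
        pos -= pos.mean(axis=0)  # centre so radii are exact COM distances
        r = np.hypot(pos[:, 0], pos[:, 1])
        u = np.column_stack((-pos[:, 1] / r, pos[:, 0] / r))
        f = _frame(pos, u, speeds=omega * r)
        prof = shell_profile([f])
        occupied = np.flatnonzero(prof.occupancy > 0)
        assert np.all(np.diff(prof.mean_speed[occupied]) > 0)
        width = prof.outer_radius / 6
        mids = (occupied + 0.5) * width
        slope = np.polyfit(mids, prof.mean_speed[occupied], 1)[0]
        assert slope == pytest.approx(omega, rel=0.2)

    def test_peripheral_fish_assigned_to_outer_shell(self):
        # 5 on a tight ring define R; one far straggler at 1.7 R
        theta = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        pos = np.vstack((np.column_stack((10 * np.cos(theta), 10 * np.sin(theta))), [[17.5, 0.0]]))
        u = np.tile([1.0, 0.0], (6, 1))
        prof = shell_profile([_frame(pos, u)])
        assert prof.occupancy[5] >= 1  # straggler lands in shell 6 despite r > R

    def test_too_few_fish_raises(self):
        f = _frame([[0, 0], [1, 0]], [[1, 0], [1, 0]])
        with pytest.raises(InsufficientDataError):
            shell_profile([f])
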