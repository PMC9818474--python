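"""Screening statistics: Q_max, asymmetry coefficients, R, decision rule."""

import numpy as np
import pytest

from mwrisk import (
    MwrClass,
    RBranch,
    classify_mwr,
    compute_asymmetry,
    compute_qmax,
    compute_r,
    group_temperatures,
    score_thermogram,
)

from .conftest import make_thermogram, random_thermogram


def brute_force_score(tg):
    """Independent recomputation of all statistics from the raw vectors."""
    pool_mw = list(tg.t_int_right) + list(tg.t_int_left)
    pool_ir = list(tg.t_skin_right) + list(tg.t_skin_left)
    q = max(max(pool_mw) - sum(pool_mw) / 20.0, max(pool_ir) - sum(pool_ir) / 20.0)
    d_int = [abs(tg.t_int_left[i] - tg.t_int_right[i]) for i in range(10)]
    d_skin = [abs(tg.t_skin_left[i] - tg.t_skin_right[i]) for i in range(10)]
    k_int, n_int = max(d_int), d_int.index(max(d_int))
    k_skin, n_skin = max(d_skin), d_skin.index(max(d_skin))
    if n_int == n_skin:
        r = k_int + k_skin
    elif k_int >= k_skin:
        r = k_int + d_skin[n_int]
    else:
        r = k_skin + d_int[n_skin]
    return q, k_int, k_skin, r


class TestQmax:
    def test_constant_field_scores_zero(self):
        tg = make_thermogram(
            skin_right=np.full(10, 33.0), skin_left=np.full(10, 33.0),
            int_right=np.full(10, 33.0), int_left=np.full(10, 33.0),
        )
        q, _ = compute_qmax(group_temperatures(tg))
        assert q == 0.0

    def test_single_hot_internal_point(self):
        internal = np.full(10, 34.0)
        internal[5] = 36.0
        tg = make_thermogram(int_left=internal)
        q, comps = compute_qmax(group_temperatures(tg))
        # 36.0 - mean(19 x 34.0, 36.0) = 36.0 - 34.1
        assert q == pytest.approx(1.9)
        assert comps["t_max_mw"] == 36.0

    def test_reference_points_excluded_from_pools(self):
        tg = make_thermogram(int_ref=np.full(2, 44.0), skin_ref=np.full(2, 44.0))
        q, _ = compute_qmax(group_temperatures(tg))
        assert q == 0.0

    def test_matches_brute_force_on_random_exams(self, rng):
        for _ in range(50):
            tg = random_thermogram(rng)
            q, _ = compute_qmax(group_temperatures(tg))
            assert q == pytest.approx(brute_force_score(tg)[0])


class TestAsymmetry:
    def test_symmetric_exam_scores_zero_at_point_zero(self, symmetric_exam):
        a = compute_asymmetry(group_temperatures(symmetric_exam))
        assert (a.k_int, a.k_skin, a.n_int, a.n_skin) == (0.0, 0.0, 0, 0)

    def test_single_hot_point_localised(self):
        internal = np.full(10, 34.0)
        internal[4] = 35.8
        a = compute_asymmetry(group_temperatures(make_thermogram(int_left=internal)))
        assert a.k_int == pytest.approx(1.8)
        assert a.n_int == 4

    def test_absolute_convention_detects_right_side(self):
        internal = np.full(10, 34.0)
        internal[4] = 35.8
        a = compute_asymmetry(group_temperatures(make_thermogram(int_right=internal)))
        assert a.k_int == pytest.approx(1.8)
        assert a.n_int == 4

    def test_matches_brute_force_on_random_exams(self, rng):
        for _ in range(50):
            tg = random_thermogram(rng)
            a = compute_asymmetry(group_temperatures(tg))
            _, k_int, k_skin, _ = brute_force_score(tg)
            assert a.k_int == pytest.approx(k_int)
            assert a.k_skin == pytest.approx(k_skin)


class TestR:
    def test_symmetric_exam(self, symmetric_exam):
        g = group_temperatures(symmetric_exam)
        r, branch = compute_r(g, compute_asymmetry(g))
        assert r == 0.0
        assert branch is RBranch.SAME_POINT

    def test_same_point_branch_sums_both_coefficients(self):
        internal = np.full(10, 34.0)
        internal[4] = 35.8
        skin = np.full(10, 31.0)
        skin[4] = 32.1
        g = group_temperatures(make_thermogram(int_left=internal, skin_left=skin))
        r, branch = compute_r(g, compute_asymmetry(g))
        assert branch is RBranch.SAME_POINT
        assert r == pytest.approx(1.8 + 1.1)

    def test_cross_channel_branch_adds_other_sensor_difference(self):
        # k_int = 1.8 at point 4; k_skin = 2.0 at point 7;
        # internal difference at point 7 is 0.9 -> R = 2.0 + 0.9
        internal = np.full(10, 34.0)
        internal[4] = 35.8
        internal[7] = 34.9
        skin = np.full(10, 31.0)
        skin[7] = 33.0
        g = group_temperatures(make_thermogram(int_left=internal, skin_left=skin))
        r, branch = compute_r(g, compute_asymmetry(g))
        assert branch is RBranch.CROSS_CHANNEL
        assert r == pytest.approx(2.9)

    def test_channel_tie_resolved_toward_internal(self):
        internal = np.full(10, 34.0)
        internal[2] = 35.5
        skin = np.full(10, 31.0)
        skin[6] = 32.5  # k_int == k_skin == 1.5 at different points
        g = group_temperatures(make_thermogram(int_left=internal, skin_left=skin))
        r, branch = compute_r(g, compute_asymmetry(g))
        assert branch is RBranch.CROSS_CHANNEL
        assert r == pytest.approx(1.5 + 0.0)  # skin difference at point 2 is 0


class TestClassify:
    @pytest.mark.parametrize(
        "q,r,expected",
        [
            (2.45, 3.2, MwrClass.MALIGNANT_SUSPECTED),
            (1.7, 1.9, MwrClass.BENIGN),
            (0.0, 0.0, MwrClass.BENIGN),
            (2.5, 1.0, MwrClass.AMBIGUOUS),
            (1.0, 3.0, MwrClass.AMBIGUOUS),
            (2.0, 2.5, MwrClass.AMBIGUOUS),  # boundary equality is not strict
        ],
    )
    def test_three_way_rule(self, q, r, expected):
        assert classify_mwr(q, r) is expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_mwr(float("nan"), 1.0)


class TestInvariances:
    def test_global_temperature_shift_leaves_statistics_unchanged(self, rng):
        for _ in range(20):
            tg = random_thermogram(rng)
            s0 = score_thermogram(tg)
            tg.t_skin_right += 1.7
            tg.t_skin_left += 1.7
            tg.t_int_right += 1.7
            tg.t_int_left += 1.7
            s1 = score_thermogram(tg)
            for attr in ("q_max", "k_int", "k_skin", "r"):
                assert getattr(s1, attr) == pytest.approx(getattr(s0, attr))

    def test_breast_swap_leaves_statistics_unchanged(self, rng):
        for _ in range(20):
            tg = random_thermogram(rng)
            s0, s1 = score_thermogram(tg), score_thermogram(tg.swap_breasts())
            for attr in ("q_max", "k_int", "k_skin", "r"):
                assert getattr(s1, attr) == pytest.approx(getattr(s0, attr))

    def test_heating_left_internal_point_monotone_under_signed_convention(self):
        internal = np.full(10, 34.0)
        internal[3] = 35.0
        g0 = group_temperatures(make_thermogram(int_left=internal))
        k0 = compute_asymmetry(g0, signed=True).k_int
        internal2 = internal.copy()
        internal2[6] += 0.4
        g1 = group_temperatures(make_thermogram(int_left=internal2))
        k1 = compute_asymmetry(g1, signed=True).k_int
        assert k1 >= k0

    def test_r_agrees_with_brute_force_oracle(self, rng):
        for _ in range(200):
            tg = random_thermogram(rng)
            s = score_thermogram(tg)
            assert s.r == pytest.approx(brute_force_score(tg)[3])
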