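"""Trimming, mobility transform, per-segment fits, and DP optimality."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from mitoribo import segmentation as seg
from mitoribo import synthetic_data as sd
from mitoribo.io_formats import PLDDTProfile


# ---------------------------------------------------------------------------
# trim_range
# ---------------------------------------------------------------------------


def test_trim_leading_targeting_sequence():
    profile = PLDDTProfile(np.arange(1, 1395), np.full(1394, 50.0))
    trimmed = seg.trim_range(profile, (1, 59))
    assert trimmed.residue_index[0] == 60
    assert trimmed.residue_index[-1] == 1394
    assert len(trimmed) == 1394 - 59


def test_trim_empty_is_identity():
    profile = PLDDTProfile(np.arange(1, 11), np.full(10, 50.0))
    assert seg.trim_range(profile, None) is profile
    same = seg.trim_range(profile, (5, 4))  # empty range
    assert np.array_equal(same.residue_index, profile.residue_index)


def test_trim_interior_rejected():
    profile = PLDDTProfile(np.arange(1, 201), np.full(200, 50.0))
    with pytest.raises(ValueError, match="interior"):
        seg.trim_range(profile, (100, 120))


def test_trim_trailing():
    profile = PLDDTProfile(np.arange(1, 101), np.full(100, 50.0))
    trimmed = seg.trim_range(profile, (90, 100))
    assert trimmed.residue_index[-1] == 89


# ---------------------------------------------------------------------------
# mobility proxy
# ---------------------------------------------------------------------------


def test_mobility_proxy_inverse_transform():
    profile = PLDDTProfile(np.arange(1, 4), np.array([100.0, 40.0, 70.0]))
    m = seg.mobility_proxy(profile)
    assert m[0] == 0.0 and m[1] == 60.0
    # order-reversing: higher confidence -> lower mobility
    assert (np.argsort(m) == np.argsort(-profile.plddt)).all()


def test_mobility_proxy_custom_transform():
    profile = PLDDTProfile(np.arange(1, 4), np.array([100.0, 50.0, 0.0]))
    m = seg.mobility_proxy(profile, transform=lambda p: (100.0 - p) ** 2)
    assert m[2] == pytest.approx(10000.0)


# ---------------------------------------------------------------------------
# fit_segment
# ---------------------------------------------------------------------------


def test_fit_constant_vector_any_order():
    for order in (0, 1, 2):
        coefs, ssr = seg.fit_segment(np.full(10, 7.0), order)
        assert ssr == pytest.approx(0.0, abs=1e-9)
        assert coefs[0] == pytest.approx(7.0)


def test_fit_linear_exact():
    coefs, ssr = seg.fit_segment(np.array([0.0, 1.0, 2.0]), 1)
    assert coefs[0] == pytest.approx(0.0, abs=1e-12)
    assert coefs[1] == pytest.approx(1.0)
    assert ssr == pytest.approx(0.0, abs=1e-12)


def test_fit_order_zero_is_mean_ssr():
    rng = np.random.default_rng(0)
    v = rng.uniform(0, 100, size=10)
    coefs, ssr = seg.fit_segment(v, 0)
    assert coefs[0] == pytest.approx(v.mean())
    assert ssr == pytest.approx(float(np.sum((v - v.mean()) ** 2)))


def test_fit_too_short_errors():
    with pytest.raises(ValueError):
        seg.fit_segment(np.array([1.0, 2.0]), 2)


# ---------------------------------------------------------------------------
# optimal_partition
# ---------------------------------------------------------------------------


def test_partition_exact_blocks():
    mob = np.array([10.0] * 4 + [50.0] * 4 + [20.0] * 4)
    res = seg.optimal_partition(mob, 3, order=0, min_len=1)
    assert res.boundaries == (4, 8, 12)
    assert res.total_ssr == pytest.approx(0.0, abs=1e-9)
    assert res.segments == [(1, 4), (5, 8), (9, 12)]


def test_partition_single_segment_matches_global_fit():
    rng = np.random.default_rng(1)
    mob = rng.uniform(0, 60, size=40)
    res = seg.optimal_partition(mob, 1, order=2)
    _, ssr = seg.fit_segment(mob, 2)
    assert res.total_ssr == pytest.approx(ssr, rel=1e-9)
    assert res.boundaries == (40,)


def test_partition_infeasible_errors():
    with pytest.raises(ValueError):
        seg.optimal_partition(np.zeros(10), 3, order=0, min_len=5)


def _exhaustive_min(y, n_segments, order, min_len):
    n = len(y)
    best = np.inf
    for cuts in combinations(range(1, n), n_segments - 1):
        bounds = [0, *cuts, n]
        if any(b - a < min_len for a, b in zip(bounds, bounds[1:])):
            continue
        ssr = sum(seg.fit_segment(y[a:b], order)[1] for a, b in zip(bounds, bounds[1:]))
        best = min(best, ssr)
    return best


@pytest.mark.parametrize("order", [0, 1, 2])
@pytest.mark.parametrize("n_segments", [2, 3, 4])
def test_dp_equals_exhaustive_enumeration(order, n_segments):
    """Exact DP matches the brute-force minimum on short random profiles."""
    rng = np.random.default_rng(100 * order + n_segments)
    for _ in range(4):
        n = int(rng.integers(15, 26))
        y = rng.uniform(0, 100, size=n)
        min_len = max(3, order + 1)
        if n < n_segments * min_len:
            continue
        res = seg.optimal_partition(y, n_segments, order=order, min_len=min_len)
        want = _exhaustive_min(y, n_segments, order, min_len)
        assert res.total_ssr == pytest.approx(want, rel=1e-8, abs=1e-8)


def test_partition_result_consistency():
    rng = np.random.default_rng(9)
    y = rng.uniform(0, 100, size=60)
    res = seg.optimal_partition(y, 3, order=1, min_len=5)
    assert res.boundaries[-1] == 60
    assert list(res.boundaries) == sorted(set(res.boundaries))
    assert res.total_ssr == pytest.approx(sum(res.segment_ssr), rel=1e-8)
    # fitted vector reproduces per-segment fits
    total = sum(
        float(np.sum((y[a - 1 : b] - res.per_residue_fitted[a - 1 : b]) ** 2))
        for a, b in res.segments
    )
    assert total == pytest.approx(res.total_ssr, rel=1e-8)


def test_breakpoint_recovery_on_noisy_fixture():
    """True breakpoints recovered within +-10 residues across seeds."""
    truth_last = [150, 300, 450, 600]
    params = [(90.0,), (50.0,), (75.0,), (30.0,)]
    for seed in range(1, 11):
        profile, truth = sd.plddt_profile_fixture(truth_last, params, noise_sd=2.0, seed=seed)
        mob = seg.mobility_proxy(profile)
        res = seg.optimal_partition(mob, 4, order=0, min_len=5,
                                    residue_index=profile.residue_index)
        for want, got in zip(truth, res.boundaries[:-1]):
            assert abs(want - got) <= 10, (seed, res.boundaries)


# ---------------------------------------------------------------------------
# residual curve
# ---------------------------------------------------------------------------


def test_residual_curve_monotone_and_step_profile():
    mob = np.array([10.0] * 30 + [60.0] * 30)
    curve = dict(seg.residual_curve(mob, [1, 2, 3], order=0, min_len=5))
    assert curve[2] == pytest.approx(0.0, abs=1e-9)
    assert curve[1] > curve[2] >= curve[3]


def test_residual_curve_constant_profile_zero():
    curve = seg.residual_curve(np.full(50, 5.0), [1, 2, 3, 4], order=0, min_len=5)
    assert all(s == pytest.approx(0.0, abs=1e-9) for _, s in curve)


def test_residual_curve_elbow_at_true_segment_count():
    profile, _ = sd.plddt_profile_fixture(
        [150, 300, 450, 600], [(90.0,), (50.0,), (75.0,), (30.0,)], noise_sd=2.0, seed=3
    )
    mob = seg.mobility_proxy(profile)
    curve = seg.residual_curve(mob, range(1, 7), order=0, min_len=5)
    ssrs = dict(curve)
    drops = {n: ssrs[n - 1] / ssrs[n] for n in range(2, 7)}
    assert max(drops, key=drops.get) == 4
    # monotone non-increasing throughout
    vals = [s for _, s in curve]
    assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))
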