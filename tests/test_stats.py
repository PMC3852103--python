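"""Unit and property tests for the six outlier statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from mirout import (
    MethodScores,
    SimulationConfig,
    copa_stat,
    generate_dataset,
    lsoss_stat,
    most_stat,
    ort_stat,
    os_stat,
    precompute_order_moments,
    score_all,
    select_top_quantile,
    ttest_stat,
)


def _scalar(fn, x, y, **kw):
    s, d = fn(np.asarray(x, float), np.asarray(y, float), **kw)
    return float(s[0]), bool(d[0])


class TestWorkedExamples:
    """Hand-computed values, cross-checked with the scalar oracles."""

    def test_ttest(self):
        val, degen = _scalar(ttest_stat, [0, 2], [3, 5])
        assert val == pytest.approx(3 / np.sqrt(2), abs=1e-12)
        assert not degen
        assert oracle.ttest_naive([0, 2], [3, 5])[0] == pytest.approx(val)

    def test_ttest_identical_groups_is_zero(self):
        val, degen = _scalar(ttest_stat, [1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert val == 0.0 and not degen

    def test_ttest_zero_variance_degenerate(self):
        val, degen = _scalar(ttest_stat, [1, 1], [1, 1])
        assert degen and val == 0.0

    def test_copa(self):
        val, _ = _scalar(copa_stat, [1, 2, 3, 4], [1, 2, 3, 12])
        assert val == pytest.approx(oracle.copa_naive([1, 2, 3, 4], [1, 2, 3, 12])[0])
        assert val == pytest.approx(4.5865, abs=1e-3)

    def test_copa_all_equal_degenerate(self):
        _, degen = _scalar(copa_stat, [2, 2, 2], [2, 2, 2])
        assert degen

    def test_os(self):
        val, _ = _scalar(os_stat, [-1, 0, 1], [-1, 0, 10])
        assert val == pytest.approx(10 / 1.4826, abs=1e-9)
        assert val == pytest.approx(6.745, abs=1e-3)

    def test_os_no_outliers_is_zero(self):
        val, _ = _scalar(os_stat, [-1, 0, 1, 2], [0.5, 1.0, 0.0])
        assert val == 0.0

    def test_ort(self):
        val, _ = _scalar(ort_stat, [1, 2, 3], [2, 2, 10])
        assert val == pytest.approx((10 - 2) / (1.4826 * 0.5), abs=1e-9)
        assert val == pytest.approx(10.791, abs=1e-3)

    def test_ort_no_outliers_is_zero(self):
        val, _ = _scalar(ort_stat, [1, 2, 3, 4], [2, 2, 3])
        assert val == 0.0

    def test_lsoss(self):
        val, _ = _scalar(lsoss_stat, [0, 0, 1, 1], [5, 5, 1, 1])
        assert val == pytest.approx(2 * (5 - 0.5) / np.sqrt(0.2), abs=1e-9)
        assert val == pytest.approx(20.125, abs=1e-3)

    def test_lsoss_constant_tumour_breaks_tie_at_k1(self):
        # SSE identical for every split; smallest k wins and the score is finite
        val, degen = _scalar(lsoss_stat, [0.0, 1.0, 2.0], [3.0, 3.0, 3.0])
        assert not degen
        expected, _ = oracle.lsoss_naive([0.0, 1.0, 2.0], [3.0, 3.0, 3.0])
        assert val == pytest.approx(expected)
        assert val == pytest.approx(1 * (3 - 1.0) / np.sqrt((2.0 + 0.0) / 3))

    def test_most_single_tumour_moments(self):
        table = precompute_order_moments(1, B=200000, seed=3)
        assert table.mu[0] == pytest.approx(0.0, abs=0.05)
        assert table.sigma[0] == pytest.approx(1.0, abs=0.05)


class TestOracleEquivalence:
    """Vectorised statistics agree with the naive scalar oracles to 1e-9."""

    @pytest.mark.parametrize("trial", range(40))
    def test_random_features(self, trial):
        rng = np.random.default_rng(500 + trial)
        n1, n2 = rng.integers(3, 13, size=2)
        x = rng.normal(0, 1 + rng.random(), n1)
        y = rng.normal(rng.random(), 1, n2)
        table = precompute_order_moments(int(n2), seed=9)
        checks = [
            (ttest_stat, oracle.ttest_naive, {}),
            (copa_stat, oracle.copa_naive, {}),
            (os_stat, oracle.os_naive, {}),
            (ort_stat, oracle.ort_naive, {}),
            (lsoss_stat, oracle.lsoss_naive, {}),
        ]
        for vec_fn, naive_fn, kw in checks:
            got, _ = _scalar(vec_fn, x, y, **kw)
            want, _ = naive_fn(list(x), list(y))
            assert got == pytest.approx(want, abs=1e-9), vec_fn.__name__
        got, _ = _scalar(most_stat, x, y, table=table)
        want, _ = oracle.most_naive(list(x), list(y), table.mu, table.sigma)
        assert got == pytest.approx(want, abs=1e-9)


class TestOrderMoments:
    def test_deterministic(self):
        a = precompute_order_moments(6, B=1000, seed=5)
        import mirout.stats as ms

        ms._ORDER_MOMENT_CACHE.pop((6, 1000, 5))
        b = precompute_order_moments(6, B=1000, seed=5)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)

    def test_mu_increasing_over_lower_half(self):
        # adding another large order statistic grows the expected top-k sum
        t = precompute_order_moments(10, B=20000, seed=7)
        half = 5
        assert np.all(np.diff(t.mu[:half]) > 0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            precompute_order_moments(4, B=50, seed=0)

    def test_wrong_table_size_rejected(self):
        table = precompute_order_moments(3, B=1000, seed=0)
        with pytest.raises(ValueError, match="precompute"):
            most_stat(np.ones((1, 4)), np.zeros((1, 5)), table)


# integer grids keep the arithmetic exact, so the invariances hold to the ulp
# and strict cutoff comparisons cannot flip through rounding noise
grid_values = st.integers(-50, 50)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.lists(grid_values, min_size=3, max_size=8),
    y=st.lists(grid_values, min_size=3, max_size=8),
    c=st.integers(-20, 20),
)
def test_location_invariance(x, y, c):
    """COPA/OS/ORT/MOST scores are unchanged by a common location shift."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    table = precompute_order_moments(len(y), seed=1)
    for fn, kw in [(copa_stat, {}), (os_stat, {}), (ort_stat, {}), (most_stat, {"table": table})]:
        base, d0 = _scalar(fn, x, y, **kw)
        shifted, d1 = _scalar(fn, x + c, y + c, **kw)
        assert d0 == d1
        if not d0:
            assert shifted == pytest.approx(base, rel=1e-12, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.lists(grid_values, min_size=3, max_size=8),
    y=st.lists(grid_values, min_size=3, max_size=8),
    c=st.sampled_from([0.25, 0.5, 2.0, 4.0, 16.0]),
)
def test_scale_invariance(x, y, c):
    """COPA/OS/ORT/MOST scores are unchanged by positive rescaling."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    table = precompute_order_moments(len(y), seed=1)
    for fn, kw in [(copa_stat, {}), (os_stat, {}), (ort_stat, {}), (most_stat, {"table": table})]:
        base, d0 = _scalar(fn, x, y, **kw)
        scaled, d1 = _scalar(fn, c * x, c * y, **kw)
        assert d0 == d1
        if not d0:
            assert scaled == pytest.approx(base, rel=1e-12, abs=1e-12)


def test_monotone_in_top_outlier():
    """Growing an already-outlying tumour value strictly raises OS and ORT."""
    x = [0.0, 0.5, 1.0, 1.5]
    y = [0.2, 0.4, 8.0]
    for fn in (os_stat, ort_stat):
        lo, _ = _scalar(fn, x, y)
        hi, _ = _scalar(fn, x, [0.2, 0.4, 9.0])
        assert lo > 0
        assert hi > lo


class TestScoreAll:
    def _recall(self, ms: MethodScores, truth) -> float:
        sel = select_top_quantile(ms, 0.05)
        return len(sel.selected_set & truth.de_features) / len(truth.de_features)

    def test_direction_both_recovers_down_shifts(self):
        cfg = SimulationConfig(
            n_normal=15, n_tumor=30, n_features=300, de_fraction=0.05,
            outlier_fraction=0.2, shift=4.0, direction="down", seed=5,
        )
        ds, truth = generate_dataset(cfg, 0)
        for ms_up, ms_both in zip(
            score_all(ds, ("ort", "os"), "up"), score_all(ds, ("ort", "os"), "both")
        ):
            assert self._recall(ms_up, truth) <= 0.25  # wrong side: near-chance
            assert self._recall(ms_both, truth) >= 0.8
            down = [d for d, f in zip(ms_both.direction, ms_both.feature_ids)
                    if f in truth.de_features]
            assert down.count("down") >= 0.8 * len(down)

    def test_empty_method_list_rejected(self):
        cfg = SimulationConfig(n_features=20, seed=0)
        ds, _ = generate_dataset(cfg, 0)
        with pytest.raises(ValueError):
            score_all(ds, [])
        with pytest.raises(ValueError, match="unknown"):
            score_all(ds, ["ort", "anova"])

    def test_scores_always_finite(self):
        cfg = SimulationConfig(n_features=50, seed=3)
        ds, _ = generate_dataset(cfg, 0)
        ds.values[0, :] = 1.0  # constant feature
        for ms in score_all(ds):
            assert np.all(np.isfinite(ms.scores))
            assert ms.degenerate[0]  # constant row flagged, scored 0
            assert ms.scores[0] == 0.0
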