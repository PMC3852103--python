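"""Tests for top-quantile selection, putative outliers and method ranking."""

import math

import numpy as np
import pytest

import _oracles as oracle
from mirout import (
    MethodScores,
    cross_dataset_de_consensus,
    putative_outliers,
    rank_methods,
    select_top_quantile,
)
from mirout.consensus import ConsensusEvaluation, SelectionResult


def _scores(method, ids, values, degenerate=None, ds="D0"):
    n = len(ids)
    return MethodScores(
        method=method,
        dataset_id=ds,
        feature_ids=list(ids),
        scores=np.asarray(values, float),
        direction=["up"] * n,
        degenerate=np.zeros(n, bool) if degenerate is None else np.asarray(degenerate),
    )


class TestSelectTopQuantile:
    def test_selection_size_is_ceil(self):
        ids = [f"f{i:03d}" for i in range(40)]
        sel = select_top_quantile(_scores("ort", ids, np.arange(40)), 0.05)
        assert len(sel.selected) == 2  # ceil(0.05 * 40)

    def test_407_features_gives_21(self):
        # ceil(0.05 * 407) on a panel of 407 probes
        ids = [f"f{i:03d}" for i in range(407)]
        sel = select_top_quantile(_scores("os", ids, np.arange(407)), 0.05)
        assert len(sel.selected) == 21

    def test_selects_by_magnitude(self):
        sel = select_top_quantile(
            _scores("ttest", list("abcdefghij"), [0, -9, 1, 2, -1, 3, 0, 1, -2, 0.5]),
            0.2,
        )
        assert set(sel.selected) == {"b", "f"}  # |-9| and |3|

    def test_boundary_ties_break_lexicographically(self):
        ids = ["z_f", "a_f", "m_f", "b_f"]
        sel = select_top_quantile(_scores("ort", ids, [5.0, 5.0, 5.0, 5.0]), 0.5)
        assert sel.selected == ("a_f", "b_f")

    def test_degenerate_never_selected(self):
        ids = list("abcd")
        degen = [False, True, False, False]
        sel = select_top_quantile(_scores("ort", ids, [1, 0, 2, 3], degen), 0.4)
        # m = 3 non-degenerate, ceil(1.2) = 2 selected, never 'b'
        assert len(sel.selected) == 2 and "b" not in sel.selected

    def test_all_degenerate_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            select_top_quantile(_scores("ort", ["a", "b"], [0, 0], [True, True]))

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1])
    def test_invalid_quantile(self, q):
        with pytest.raises(ValueError):
            select_top_quantile(_scores("ort", ["a", "b", "c"], [1, 2, 3]), q)


def _selection(method, feats, ds="D0"):
    return SelectionResult(method=method, dataset_id=ds, selected=tuple(feats), quantile=0.05)


class TestPutativeOutliers:
    def test_boundary_of_min_methods_rule(self):
        sels = [
            _selection(m, feats)
            for m, feats in [
                ("ttest", ["a", "x"]), ("copa", ["a", "y"]), ("os", ["a", "z"]),
                ("ort", ["b", "x"]), ("most", ["b", "y"]), ("lsoss", ["c", "z"]),
            ]
        ]
        ev = putative_outliers(sels, 3)
        assert ev.putative == frozenset({"a"})  # exactly 3 methods
        assert ev.accuracy["ttest"] == 50.0 and ev.accuracy["lsoss"] == 0.0

    def test_identical_selections_give_full_accuracy(self):
        sels = [_selection(m, ["a", "b"]) for m in ("t1", "t2", "t3", "t4", "t5", "t6")]
        ev = putative_outliers(sels, 3)
        assert all(v == 100.0 for v in ev.accuracy.values())

    def test_accuracy_fraction(self):
        base = [_selection(m, ["a", "b", "c", "d"]) for m in ("m1", "m2", "m3")]
        odd = _selection("m4", ["a", "b", "c", "d", "e", "f", "g", "h", "i", "j"])
        # putative with k=3: a-d (selected by >= 3 of 4)
        ev = putative_outliers(base + [odd], 3)
        assert ev.accuracy["m4"] == 40.0

    def test_inconsistent_dataset_ids_rejected(self):
        with pytest.raises(ValueError, match="datasets"):
            putative_outliers(
                [_selection("m1", ["a"], "D0"), _selection("m2", ["a"], "D1"),
                 _selection("m3", ["a"], "D0")], 1
            )

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force_counting(self, trial):
        rng = np.random.default_rng(9000 + trial)
        feats = [f"f{i}" for i in range(int(rng.integers(5, 31)))]
        methods = [f"m{j}" for j in range(int(rng.integers(3, 7)))]
        sels = {}
        for m in methods:
            size = int(rng.integers(1, len(feats) + 1))
            sels[m] = set(rng.choice(feats, size=size, replace=False))
        k_m = int(rng.integers(1, len(methods) + 1))
        want_put, want_acc = oracle.putative_naive(sels, k_m)
        ev = putative_outliers(
            [_selection(m, sorted(s)) for m, s in sels.items()], k_m
        )
        assert ev.putative == frozenset(want_put)
        for m in methods:
            assert ev.accuracy[m] == pytest.approx(want_acc[m])

    def test_union_intersection_identities_and_monotonicity(self):
        rng = np.random.default_rng(4)
        sels = {
            f"m{j}": set(rng.choice([f"f{i}" for i in range(20)], size=6, replace=False))
            for j in range(6)
        }
        as_list = [_selection(m, sorted(s)) for m, s in sels.items()]
        union = putative_outliers(as_list, 1).putative
        inter = putative_outliers(as_list, 6).putative
        assert union == frozenset(set().union(*sels.values()))
        assert inter == frozenset(set.intersection(*sels.values()))
        sizes = [len(putative_outliers(as_list, k).putative) for k in range(1, 7)]
        assert sizes == sorted(sizes, reverse=True)

    def test_full_accuracy_iff_subset_of_putative(self):
        sels = [
            _selection("m1", ["a", "b"]), _selection("m2", ["a", "b"]),
            _selection("m3", ["a", "c"]),
        ]
        ev = putative_outliers(sels, 2)
        for sel in sels:
            is_subset = sel.selected_set <= ev.putative
            assert (ev.accuracy[sel.method] == 100.0) == is_subset


def _eval(ds, acc):
    return ConsensusEvaluation(dataset_id=ds, putative=frozenset(), min_methods=3, accuracy=acc)


class TestRankMethods:
    def test_dominant_method_wins(self):
        evs = [
            _eval(f"D{i}", {"ort": o, "ttest": t})
            for i, (o, t) in enumerate(zip((80, 90, 85, 88), (50, 60, 55, 58)))
        ]
        r = rank_methods(evs)
        assert r.best_method == "ort"
        assert r.median["ort"] == pytest.approx(np.median([80, 90, 85, 88]))
        assert r.sd["ort"] == pytest.approx(np.std([80, 90, 85, 88], ddof=1))

    def test_median_tie_broken_by_smaller_sd(self):
        evs = [
            _eval(f"D{i}", {"a": a, "b": b})
            for i, (a, b) in enumerate(zip((78, 80, 82), (75, 80, 85)))
        ]
        assert rank_methods(evs).best_method == "a"

    def test_full_tie_broken_by_name(self):
        evs = [_eval(f"D{i}", {"zz": 80.0, "aa": 80.0}) for i in range(3)]
        assert rank_methods(evs).best_method == "aa"

    def test_single_dataset_warns(self):
        with pytest.warns(UserWarning, match="single dataset"):
            r = rank_methods([_eval("D0", {"ort": 90.0, "ttest": 40.0})])
        assert r.best_method == "ort" and r.sd["ort"] == 0.0

    def test_missing_method_rejected(self):
        with pytest.raises(ValueError, match="every evaluation"):
            rank_methods([_eval("D0", {"a": 1.0, "b": 2.0}), _eval("D1", {"a": 1.0})])


class TestCrossDatasetConsensus:
    SETS = {"D0": {"a", "b", "c"}, "D1": {"a", "b"}, "D2": {"a", "d"}, "D3": {"e"}}

    def test_at_least_three_of_four(self):
        assert cross_dataset_de_consensus(self.SETS, 3) == frozenset({"a"})

    def test_k1_is_union_and_kn_is_intersection(self):
        assert cross_dataset_de_consensus(self.SETS, 1) == frozenset("abcde")
        assert cross_dataset_de_consensus(self.SETS, 4) == frozenset()

    def test_k_exceeding_datasets_rejected(self):
        with pytest.raises(ValueError):
            cross_dataset_de_consensus(self.SETS, 5)
        with pytest.raises(ValueError):
            cross_dataset_de_consensus({}, 1)
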