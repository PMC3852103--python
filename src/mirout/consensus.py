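"""Top-quantile selection, cross-method putative outliers, method ranking.

Per dataset, each statistic nominates its top 5% (by default) of features
as differentially expressed. Features nominated by at least ``k_m`` (default
3) of the methods form the putative outlier set; a method's accuracy is the
percentage of its own nominations that are putative. Ranking methods by the
median (then SD) of their accuracies across datasets picks the statistic
whose selections agree best with the cross-method consensus — the rule used
to choose the method feeding the downstream target/pathway analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .stats import MethodScores


@dataclass
class SelectionResult:
    """Top-quantile feature selection of one method on one dataset."""

    method: str
    dataset_id: str
    selected: tuple[str, ...]
    quantile: float

    @property
    def selected_set(self) -> frozenset[str]:
        return frozenset(self.selected)


@dataclass
class ConsensusEvaluation:
    """Putative-outlier set and per-method accuracy for one dataset."""

    dataset_id: str
    putative: frozenset[str]
    min_methods: int
    accuracy: dict[str, float] = field(default_factory=dict)


@dataclass
class MethodRanking:
    """Median/SD of accuracies across datasets and the winning method."""

    median: dict[str, float]
    sd: dict[str, float]
    best_method: str


def select_top_quantile(scores: MethodScores, q: float = 0.05) -> SelectionResult:
    """Select the ceil(q * m) features with the largest score magnitude.

    ``m`` counts non-degenerate features only; degenerate features are
    never selected. Ties at the boundary are broken by lexicographic
    feature ID (smaller ID wins).
    """
    if not (0.0 < q < 1.0):
        raise ValueError("quantile q must lie in (0, 1)")
    ok = ~scores.degenerate
    m = int(ok.sum())
    if m == 0:
        raise ValueError(
            f"all features of {scores.dataset_id}/{scores.method} are degenerate"
        )
    n_select = math.ceil(q * m)
    pool = [
        (-abs(scores.scores[i]), scores.feature_ids[i])
        for i in range(len(scores.feature_ids))
        if ok[i]
    ]
    pool.sort()
    chosen = tuple(fid for _, fid in pool[:n_select])
    return SelectionResult(
        method=scores.method,
        dataset_id=scores.dataset_id,
        selected=chosen,
        quantile=q,
    )


def putative_outliers(
    selections: list[SelectionResult], k_m: int = 3
) -> ConsensusEvaluation:
    """Features selected by at least ``k_m`` methods, with per-method accuracy.

    Accuracy of a method is 100 x |own selection ∩ putative| / |own
    selection| — the percentage of its nominations that survive the
    cross-method consensus.
    """
    if not selections:
        raise ValueError("no selections given")
    dataset_ids = {s.dataset_id for s in selections}
    if len(dataset_ids) != 1:
        raise ValueError(f"selections span multiple datasets: {sorted(dataset_ids)}")
    if len(selections) < k_m:
        raise ValueError(
            f"min_methods={k_m} but only {len(selections)} selections supplied"
        )
    counts: dict[str, int] = {}
    for sel in selections:
        for fid in sel.selected_set:
            counts[fid] = counts.get(fid, 0) + 1
    putative = frozenset(fid for fid, c in counts.items() if c >= k_m)
    accuracy = {
        sel.method: 100.0 * len(sel.selected_set & putative) / len(sel.selected_set)
        for sel in selections
    }
    return ConsensusEvaluation(
        dataset_id=next(iter(dataset_ids)),
        putative=putative,
        min_methods=k_m,
        accuracy=accuracy,
    )


def rank_methods(evaluations: list[ConsensusEvaluation]) -> MethodRanking:
    """Rank methods by median accuracy across datasets.

    Ties on the median are broken by smaller standard deviation (sample SD,
    ddof=1), then lexicographic method name. With a single dataset the SD
    is undefined (reported as 0.0) and a warning is emitted.
    """
    if not evaluations:
        raise ValueError("no evaluations given")
    methods = set(evaluations[0].accuracy)
    for ev in evaluations[1:]:
        if set(ev.accuracy) != methods:
            missing = methods.symmetric_difference(ev.accuracy)
            raise ValueError(
                f"method(s) {sorted(missing)} not present in every evaluation"
            )
    if len(evaluations) < 2:
        warnings.warn(
            "method ranking over a single dataset: SD is undefined, reported as 0",
            stacklevel=2,
        )
    median: dict[str, float] = {}
    sd: dict[str, float] = {}
    for m in sorted(methods):
        acc = np.asarray([ev.accuracy[m] for ev in evaluations], dtype=float)
        median[m] = float(np.median(acc))
        sd[m] = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0
    best = min(sorted(methods), key=lambda m: (-median[m], sd[m], m))
    return MethodRanking(median=median, sd=sd, best_method=best)


def cross_dataset_de_consensus(
    selections: dict[str, set[str] | frozenset[str]], k_d: int
) -> frozenset[str]:
    """Features selected in at least ``k_d`` datasets (shared global IDs)."""
    if not selections:
        raise ValueError("no per-dataset selections given")
    if k_d > len(selections):
        raise ValueError(
            f"k_d={k_d} exceeds the number of datasets ({len(selections)})"
        )
    counts: dict[str, int] = {}
    for feats in selections.values():
        for fid in feats:
            counts[fid] = counts.get(fid, 0) + 1
    return frozenset(fid for fid, c in counts.items() if c >= k_d)
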