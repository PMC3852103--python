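"""Two-group outlier statistics for heterogeneous differential expression.

Cancer outlier profiles — features shifted in only a subset of tumour
samples — are poorly detected by mean-difference tests. This module
implements the six per-feature statistics used for cancer outlier profile
analysis of expression data:

``ttest``
    Pooled-variance two-sample t statistic.
``copa``
    Cancer Outlier Profile Analysis: the r-th percentile (default 90) of
    tumour values after median/MAD standardisation over all samples.
``os``
    Outlier Sum: sum of standardised tumour values strictly above the
    q75 + IQR cutoff of all standardised values.
``ort``
    Outlier Robust T: sum of (y - median(X)) / scale over tumour values
    strictly above q75(X) + IQR(X), with a pooled within-group MAD scale.
``most``
    Maximum Ordered Subset T: the ORT-style cumulative sum over the k
    largest tumour values, standardised by Monte-Carlo moments of normal
    order-statistic sums and maximised over k.
``lsoss``
    Least Sum of Ordered Subset Squares: splits the sorted tumour values
    into two subsets at the break k* minimising the within-subset sum of
    squares, then forms a t-like contrast between the top subset and the
    normal group.

All statistics are one-sided toward over-expression; under-expression is
scored by negating the matrix (see :func:`score_all`). Conventions shared
by all: the scaled MAD ``madn(v) = 1.4826 * median(|v - median(v)|)``;
quantiles by linear interpolation between order statistics at 1-based
position ``1 + (n - 1) p`` (numpy's ``method="linear"``); strict ``>`` for
outlier-set membership. Features whose scale estimate vanishes even after
the mean-absolute-deviation fallback are flagged degenerate and scored 0
rather than producing non-finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset

METHODS = ("ttest", "copa", "os", "ort", "most", "lsoss")

MADN_CONSTANT = 1.4826
_EPS = 0.0  # scale is degenerate only when exactly zero


# ---------------------------------------------------------------------------
# helpers


def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[None, :] if a.ndim == 1 else a


def _madn_scale(values: np.ndarray, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scaled MAD per row with mean-absolute-deviation fallback.

    Returns ``(scale, degenerate)``; degenerate rows (both estimates zero)
    get scale 1.0 so that downstream arithmetic stays finite — their scores
    are zeroed by the caller.
    """
    dev = np.abs(values - center[:, None])
    scale = MADN_CONSTANT * np.median(dev, axis=1)
    zero = scale <= _EPS
    if np.any(zero):
        fallback = MADN_CONSTANT * dev[zero].mean(axis=1)
        scale = scale.copy()
        scale[zero] = fallback
    degenerate = scale <= _EPS
    scale = np.where(degenerate, 1.0, scale)
    return scale, degenerate


def _pooled_madn(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ORT/MOST scale: madn over pooled within-group absolute deviations."""
    med_x = np.median(X, axis=1)
    med_y = np.median(Y, axis=1)
    dev = np.hstack([np.abs(X - med_x[:, None]), np.abs(Y - med_y[:, None])])
    scale = MADN_CONSTANT * np.median(dev, axis=1)
    zero = scale <= _EPS
    if np.any(zero):
        fallback = MADN_CONSTANT * dev[zero].mean(axis=1)
        scale = scale.copy()
        scale[zero] = fallback
    degenerate = scale <= _EPS
    scale = np.where(degenerate, 1.0, scale)
    return scale, med_x, degenerate


# ---------------------------------------------------------------------------
# statistics (vectorised over feature rows)


def ttest_stat(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled two-sample t statistic (tumour minus normal).

    Returns ``(scores, degenerate)``; features with zero pooled variance
    are flagged degenerate and scored 0.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    n1, n2 = X.shape[1], Y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("t-test requires at least 2 samples per group")
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    ss = ((X - mx[:, None]) ** 2).sum(axis=1) + ((Y - my[:, None]) ** 2).sum(axis=1)
    sp2 = ss / (n1 + n2 - 2)
    degenerate = sp2 <= 0.0
    denom = np.sqrt(np.where(degenerate, 1.0, sp2) * (1.0 / n1 + 1.0 / n2))
    scores = np.where(degenerate, 0.0, (my - mx) / denom)
    return scores, degenerate


def copa_stat(X: np.ndarray, Y: np.ndarray, r: float = 90.0) -> tuple[np.ndarray, np.ndarray]:
    """COPA: r-th percentile of tumour values standardised over all samples."""
    X, Y = _as_2d(X), _as_2d(Y)
    A = np.hstack([X, Y])
    med = np.median(A, axis=1)
    scale, degenerate = _madn_scale(A, med)
    Z = (Y - med[:, None]) / scale[:, None]
    scores = np.quantile(Z, r / 100.0, axis=1)
    return np.where(degenerate, 0.0, scores), degenerate


def os_stat(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outlier Sum: sum of standardised tumour values beyond q75 + IQR.

    Standardisation (median, madn) and the cutoff quartiles are computed
    over all samples; membership is strict (``>``); an empty outlier set
    scores 0.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    A = np.hstack([X, Y])
    med = np.median(A, axis=1)
    scale, degenerate = _madn_scale(A, med)
    Z_all = (A - med[:, None]) / scale[:, None]
    q75 = np.quantile(Z_all, 0.75, axis=1)
    q25 = np.quantile(Z_all, 0.25, axis=1)
    cutoff = q75 + (q75 - q25)
    Zy = (Y - med[:, None]) / scale[:, None]
    scores = np.where(Zy > cutoff[:, None], Zy, 0.0).sum(axis=1)
    return np.where(degenerate, 0.0, scores), degenerate


def ort_stat(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outlier Robust T statistic.

    Scale is the madn of pooled within-group absolute deviations; the
    outlier set is tumour values strictly above q75(X) + IQR(X); the score
    sums (y - median(X)) / scale over that set, 0 when empty.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise ValueError("ORT requires at least 2 samples per group")
    scale, med_x, degenerate = _pooled_madn(X, Y)
    q75 = np.quantile(X, 0.75, axis=1)
    q25 = np.quantile(X, 0.25, axis=1)
    cutoff = q75 + (q75 - q25)
    U = (Y - med_x[:, None]) / scale[:, None]
    scores = np.where(Y > cutoff[:, None], U, 0.0).sum(axis=1)
    return np.where(degenerate, 0.0, scores), degenerate


@dataclass(frozen=True)
class OrderStatTable:
    """Monte-Carlo moments of sums of the k largest of n iid N(0,1) draws.

    ``mu[k-1]`` and ``sigma[k-1]`` are the mean and standard deviation of
    the sum of the top k order statistics out of ``n`` standard normals,
    for k = 1..n.
    """

    n: int
    mu: np.ndarray
    sigma: np.ndarray
    replicates: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.mu) != self.n or len(self.sigma) != self.n:
            raise ValueError("moment arrays must have length n")


_ORDER_MOMENT_CACHE: dict[tuple[int, int, int], OrderStatTable] = {}


def precompute_order_moments(n2: int, B: int = 10000, seed: int = 0) -> OrderStatTable:
    """Monte-Carlo moments required by the MOST standardisation.

    Draws ``B`` samples of ``n2`` iid standard normals, sorts each
    descending and accumulates the running sums; their per-k mean and
    sample standard deviation form the table. Deterministic given
    ``seed``; results are cached in-process.
    """
    if n2 < 1:
        raise ValueError("n2 must be >= 1")
    if B < 100:
        raise ValueError("at least 100 Monte-Carlo replicates are required")
    key = (n2, B, seed)
    cached = _ORDER_MOMENT_CACHE.get(key)
    if cached is not None:
        return cached
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((B, n2))
    draws.sort(axis=1)
    sums = np.cumsum(draws[:, ::-1], axis=1)  # B x n2, column k-1 = top-k sum
    mu = sums.mean(axis=0)
    sigma = sums.std(axis=0, ddof=1)
    table = OrderStatTable(n=n2, mu=mu, sigma=sigma, replicates=B, seed=seed)
    _ORDER_MOMENT_CACHE[key] = table
    return table


def most_stat(
    X: np.ndarray, Y: np.ndarray, table: OrderStatTable
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum Ordered Subset T statistic.

    With scale and median(X) as in ORT, forms cumulative sums
    ``M_k = sum_{j<=k} (y_(j) - med(X)) / scale`` over the descending-sorted
    tumour values and returns ``max_k (M_k - mu_k) / sigma_k`` using the
    supplied order-statistic moment table.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    n2 = Y.shape[1]
    if table.n != n2:
        raise ValueError(
            f"order-statistic table is for n={table.n}, tumour group has n={n2}; "
            "precompute the table with precompute_order_moments(n2)"
        )
    scale, med_x, degenerate = _pooled_madn(X, Y)
    Ys = -np.sort(-Y, axis=1)  # descending
    M = np.cumsum((Ys - med_x[:, None]) / scale[:, None], axis=1)
    standardized = (M - table.mu[None, :]) / table.sigma[None, :]
    scores = standardized.max(axis=1)
    return np.where(degenerate, 0.0, scores), degenerate


def lsoss_stat(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least Sum of Ordered Subset Squares statistic.

    Sorted tumour values are split into a top subset of size k and the
    remainder; ``SSE(k)`` is the within-subset sum of squares for the split
    and ``k*`` its minimiser over k = 1..n2-1 (smallest k on ties). With
    pooled variance ``s^2 = (SS(X) + SSE(k*)) / (n1 + n2 - 3)`` the score is
    ``k* (mean(top-k*) - mean(X)) / s``.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    n1, n2 = X.shape[1], Y.shape[1]
    if n2 < 2:
        raise ValueError("LSOSS requires at least 2 tumour samples")
    Ys = -np.sort(-Y, axis=1)
    csum = np.cumsum(Ys, axis=1)
    csq = np.cumsum(Ys**2, axis=1)
    total, total_sq = csum[:, -1], csq[:, -1]
    k = np.arange(1, n2)  # candidate break points
    top_mean = csum[:, : n2 - 1] / k[None, :]
    ss_top = csq[:, : n2 - 1] - k[None, :] * top_mean**2
    rest_n = (n2 - k)[None, :]
    rest_mean = (total[:, None] - csum[:, : n2 - 1]) / rest_n
    ss_rest = (total_sq[:, None] - csq[:, : n2 - 1]) - rest_n * rest_mean**2
    sse = ss_top + ss_rest
    k_star_idx = np.argmin(sse, axis=1)  # first minimum = smallest k
    rows = np.arange(Ys.shape[0])
    k_star = k_star_idx + 1
    mean_top = csum[rows, k_star_idx] / k_star
    mx = X.mean(axis=1)
    ss_x = ((X - mx[:, None]) ** 2).sum(axis=1)
    s2 = (ss_x + sse[rows, k_star_idx]) / (n1 + n2 - 3)
    degenerate = s2 <= 0.0
    s = np.sqrt(np.where(degenerate, 1.0, s2))
    scores = np.where(degenerate, 0.0, k_star * (mean_top - mx) / s)
    return scores, degenerate


# ---------------------------------------------------------------------------
# dataset-level scoring


@dataclass
class MethodScores:
    """Per-feature scores of one statistic on one dataset.

    ``scores`` are signed: positive means the evidence points to
    over-expression in tumours, negative to under-expression; magnitude is
    the selection criterion. ``degenerate`` marks features whose scale or
    variance estimate vanished (score forced to 0, never selected).
    """

    method: str
    dataset_id: str
    feature_ids: list[str]
    scores: np.ndarray
    direction: list[str] = field(repr=False)
    degenerate: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if not (
            len(self.feature_ids)
            == len(self.scores)
            == len(self.direction)
            == len(self.degenerate)
        ):
            raise ValueError("score arrays must align with feature IDs")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite; degenerate features are flagged")


def _one_sided(method: str, X: np.ndarray, Y: np.ndarray, *, moment_seed: int):
    if method == "ttest":
        return ttest_stat(X, Y)
    if method == "copa":
        return copa_stat(X, Y)
    if method == "os":
        return os_stat(X, Y)
    if method == "ort":
        return ort_stat(X, Y)
    if method == "most":
        table = precompute_order_moments(Y.shape[1], seed=moment_seed)
        return most_stat(X, Y, table)
    if method == "lsoss":
        return lsoss_stat(X, Y)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def score_all(
    dataset: ExpressionDataset,
    methods: list[str] | tuple[str, ...] = METHODS,
    direction_mode: str = "both",
    moment_seed: int = 0,
) -> list[MethodScores]:
    """Score every feature of a dataset with each requested statistic.

    ``direction_mode`` controls the alternative: ``up`` evaluates the
    statistics as defined (over-expression), ``down`` evaluates them on the
    negated matrix, and ``both`` evaluates both and keeps, per feature, the
    direction with the larger magnitude — recorded in the sign of the score
    and the ``direction`` field. The t statistic is inherently two-sided;
    under ``both`` its sign carries the direction directly.

    ``moment_seed`` seeds the MOST order-statistic Monte Carlo; it is fixed
    by default so scoring is reproducible without further configuration.
    """
    if not methods:
        raise ValueError("at least one method is required")
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown method(s) {unknown}; expected among {METHODS}")
    if direction_mode not in ("up", "down", "both"):
        raise ValueError("direction_mode must be 'up', 'down' or 'both'")

    X = dataset.normal_matrix()
    Y = dataset.tumor_matrix()
    out: list[MethodScores] = []
    for method in methods:
        if method == "ttest":
            scores, degen = ttest_stat(X, Y)
            if direction_mode == "down":
                scores = -scores
            direction = ["up" if s >= 0 else "down" for s in scores]
            if direction_mode != "both":
                direction = [direction_mode] * len(scores)
        elif direction_mode == "both":
            up, degen_up = _one_sided(method, X, Y, moment_seed=moment_seed)
            down, degen_down = _one_sided(method, -X, -Y, moment_seed=moment_seed)
            use_down = np.abs(down) > np.abs(up)
            scores = np.where(use_down, -np.abs(down), up)
            degen = degen_up | degen_down
            direction = ["down" if d else "up" for d in use_down]
        else:
            sign = -1.0 if direction_mode == "down" else 1.0
            scores, degen = _one_sided(method, sign * X, sign * Y, moment_seed=moment_seed)
            direction = [direction_mode] * len(scores)
        scores = np.where(degen, 0.0, scores)
        out.append(
            MethodScores(
                method=method,
                dataset_id=dataset.dataset_id,
                feature_ids=dataset.feature_ids,
                scores=scores,
                direction=direction,
                degenerate=degen,
            )
        )
    return out
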