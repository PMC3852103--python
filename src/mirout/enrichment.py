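"""Hypergeometric over-representation analysis with BH-FDR adjustment.

Given a query gene list (here: consensus target genes of DE-miRNAs) and a
named gene-set collection over a gene universe, each set is tested for
over-representation with the hypergeometric upper tail P(X >= k) — the
probability that a random query of the same size overlaps the set at least
as much. P values are adjusted by Benjamini-Hochberg step-up. Filtering
uses either the adjusted value (GO / GeneGO-style collections) or the raw
p value (KEGG-style), with a 0.001 cutoff by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ENRICHMENT_COLUMNS = (
    "set_name",
    "set_size",
    "query_size",
    "overlap",
    "p_value",
    "fdr",
    "passes_threshold",
)


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit gene universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    label: str = "geneset"

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(g) for name, g in self.sets.items()}
        self.universe = frozenset(self.universe)
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if not genes <= self.universe:
                raise ValueError(f"gene set {name!r} is not contained in the universe")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sets)


def hypergeom_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``N`` universe size, ``K`` gene-set size, ``n`` query size, ``k``
    observed overlap. ``P(X >= 0)`` is 1 by convention.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    collection: GeneSetCollection,
    threshold: float = 0.001,
    threshold_on: str = "fdr",
) -> pd.DataFrame:
    """Over-representation table for a query gene set.

    Query genes outside the universe are dropped (their count is recorded
    in ``df.attrs["dropped_from_query"]``). One row per gene set, sorted by
    ascending p value (ties by set name); ``passes_threshold`` applies the
    cutoff to the raw p value or the FDR per ``threshold_on``.
    """
    if threshold_on not in ("fdr", "p"):
        raise ValueError("threshold_on must be 'fdr' or 'p'")
    if not collection.universe:
        raise ValueError("empty gene universe")
    query = frozenset(query)
    in_universe = query & collection.universe
    dropped = len(query) - len(in_universe)
    if not in_universe:
        raise ValueError("query is empty after intersection with the universe")
    N, n = len(collection.universe), len(in_universe)
    rows = []
    for name, genes in collection.sets.items():
        k = len(genes & in_universe)
        rows.append((name, len(genes), n, k, hypergeom_p(N, len(genes), n, k)))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:5])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    crit = df["fdr"] if threshold_on == "fdr" else df["p_value"]
    df["passes_threshold"] = crit < threshold
    df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    df.attrs["dropped_from_query"] = dropped
    df.attrs["collection"] = collection.label
    df.attrs["threshold"] = threshold
    df.attrs["threshold_on"] = threshold_on
    return df
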