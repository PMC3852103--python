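"""miRNA target maps, prediction intersection, cross-dataset gene consensus.

Target predictions arrive as (mirna_id, gene_id) pair tables, typically one
per prediction tool. Predictions from several tools are intersected to keep
only pairs every tool agrees on — a high-precision subset. Per-dataset
target gene sets (union of targets of that dataset's DE-miRNAs) are then
reduced to the genes shared by at least ``k_d`` datasets, with an exact
multiplicity breakdown (the |>=k| = sum of exact counts additivity).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import reduce


@dataclass(frozen=True)
class TargetMap:
    """Many-to-many miRNA -> target-gene relation as a set of unique pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for mir, gene in self.pairs:
            if not mir or not gene:
                raise ValueError("miRNA and gene IDs must be non-empty")

    @classmethod
    def from_pairs(cls, pairs) -> "TargetMap":
        return cls(pairs=frozenset((str(m), str(g)) for m, g in pairs))

    @property
    def by_mirna(self) -> dict[str, frozenset[str]]:
        view: dict[str, set[str]] = {}
        for mir, gene in self.pairs:
            view.setdefault(mir, set()).add(gene)
        return {m: frozenset(gs) for m, gs in view.items()}

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.pairs)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def intersect_predictions(tables: list[TargetMap]) -> TargetMap:
    """Pairs present in every prediction table (order-independent)."""
    if len(tables) < 2:
        raise ValueError("at least 2 prediction tables are required")
    pairs = reduce(frozenset.intersection, (t.pairs for t in tables))
    return TargetMap(pairs=pairs)


def combine_target_maps(primary: TargetMap, fallback: TargetMap | None) -> TargetMap:
    """Primary map, extended by fallback pairs for miRNAs the primary lacks.

    Mirrors the two-source retrieval strategy: a curated database where
    available, the intersection of several de-novo predictors otherwise.
    """
    if fallback is None:
        return primary
    known = primary.mirnas
    extra = frozenset(p for p in fallback.pairs if p[0] not in known)
    return TargetMap(pairs=primary.pairs | extra)


def targets_of(
    de_mirnas, target_map: TargetMap
) -> tuple[frozenset[str], tuple[str, ...]]:
    """Union of target genes of the given miRNAs.

    Returns ``(genes, missing)`` where ``missing`` lists miRNAs absent from
    the map (reported, not fatal).
    """
    view = target_map.by_mirna
    genes: set[str] = set()
    missing: list[str] = []
    for mir in sorted(set(de_mirnas)):
        if mir in view:
            genes |= view[mir]
        else:
            missing.append(mir)
    return frozenset(genes), tuple(missing)


@dataclass
class ConsensusGenes:
    """Gene-level cross-dataset consensus with multiplicity breakdown."""

    genes: frozenset[str]
    min_datasets: int
    multiplicity: dict[str, int] = field(repr=False)
    counts_by_multiplicity: dict[int, int] = field(default_factory=dict)


def gene_consensus(
    per_dataset_targets: dict[str, set[str] | frozenset[str]], k_d: int = 3
) -> ConsensusGenes:
    """Genes present in the target sets of at least ``k_d`` datasets.

    ``counts_by_multiplicity[j]`` is the number of genes appearing in
    exactly j datasets, so ``|consensus| = sum_{j >= k_d} counts[j]``.
    """
    if not per_dataset_targets:
        raise ValueError("no per-dataset target sets given")
    n = len(per_dataset_targets)
    if k_d > n:
        raise ValueError(f"k_d={k_d} exceeds the number of datasets ({n})")
    mult = Counter()
    for genes in per_dataset_targets.values():
        mult.update(set(genes))
    counts = Counter(mult.values())
    consensus = frozenset(g for g, c in mult.items() if c >= k_d)
    return ConsensusGenes(
        genes=consensus,
        min_datasets=k_d,
        multiplicity=dict(mult),
        counts_by_multiplicity={j: counts[j] for j in sorted(counts)},
    )
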