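"""Synthetic multi-dataset miRNA expression scenarios with planted truth.

Emulates the structure of a multi-platform cancer miRNA microarray
compendium: several datasets whose probe panels overlap only partially
(about 40-60% pairwise by default), log-scale expression, and
differentially expressed features that are shifted in only a fraction
``pi`` of the tumour samples — the cancer-outlier regime mean-difference
tests miss. Each scenario also plants a miRNA -> target-gene map and a
gene-set collection in which the targets of the shared DE-miRNAs are
over-represented, so the full selection -> target -> enrichment chain has a
known ground truth.

Baseline expression is iid mean-zero Gaussian on the log scale; the
statistics under study are location/scale-based, so a realistic baseline
mean adds nothing. Probe-panel overlap between two datasets is measured as
|A ∩ B| / min(|A|, |B|) and controlled by giving every dataset a common
core panel plus dataset-private features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .datasets import ExpressionDataset, GROUP_NORMAL, GROUP_TUMOR
from .enrichment import GeneSetCollection
from .targets import TargetMap


@dataclass
class SimulationConfig:
    """Parameters of a synthetic multi-dataset scenario.

    Expression model: each feature's baseline is iid Normal(0, sigma^2)
    log-expression; each DE feature has ``mu`` added to (direction ``up``)
    or subtracted from (``down``) exactly ``max(1, round(pi * n_tumor))``
    tumour samples. ``direction="mixed"`` splits DE features half up, half
    down (extra feature up on odd counts).

    Scenario model: ``n_datasets`` panels of ``n_features`` probes share a
    common core sized so all pairwise overlaps fall in
    ``probe_overlap_range``; a fraction ``shared_de_fraction`` of each
    dataset's DE features is a common core subset, the rest are private.
    Target/pathway truth: every miRNA gets ``targets_per_mirna`` target
    genes from an ``n_genes`` universe; shared DE-miRNAs draw a fraction
    ``target_signal_fraction`` of theirs from a ``n_signal_genes`` signal
    pool, from which the planted pathways are predominantly built.
    """

    n_normal: int = 20
    n_tumor: int = 40
    n_features: int = 500
    de_fraction: float = 0.05
    outlier_fraction: float = 0.2  # pi: fraction of tumour samples shifted
    shift: float = 2.0  # mu, log-expression units
    noise_sd: float = 1.0  # sigma
    direction: str = "up"
    n_datasets: int = 4
    probe_overlap_range: tuple[float, float] = (0.4, 0.6)
    shared_de_fraction: float = 0.7
    n_genes: int = 2000
    n_signal_genes: int = 120
    targets_per_mirna: int = 15
    target_signal_fraction: float = 0.8
    n_gene_sets: int = 20
    n_true_gene_sets: int = 5
    gene_set_size: int = 40
    gene_set_signal_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal <= 1 or self.n_tumor <= 1:
            raise ValueError("need at least 2 samples per group")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if not (0.0 < self.de_fraction < 1.0):
            raise ValueError("de_fraction must lie in (0, 1)")
        if not (0.0 < self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction (pi) must lie in (0, 1]")
        if self.shift < 0:
            raise ValueError("shift (mu) must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd (sigma) must be positive")
        if self.direction not in ("up", "down", "mixed"):
            raise ValueError("direction must be 'up', 'down' or 'mixed'")
        lo, hi = self.probe_overlap_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("probe_overlap_range must satisfy 0 < low <= high <= 1")
        if not (0.0 <= self.shared_de_fraction <= 1.0):
            raise ValueError("shared_de_fraction must lie in [0, 1]")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_features))

    @property
    def n_shifted(self) -> int:
        return max(1, int(round(self.outlier_fraction * self.n_tumor)))


@dataclass
class SimulationTruth:
    """Planted ground truth for one generated dataset.

    ``shifted_samples`` maps each DE feature to the indices (within the
    tumour-sample columns) that received the shift. ``true_target_genes``
    and ``true_pathways`` are scenario-level: targets of the DE features
    shared across datasets, and the gene sets planted to be enriched in
    them (empty for a standalone dataset).
    """

    dataset_id: str
    de_features: frozenset[str]
    shifted_samples: dict[str, tuple[int, ...]] = field(repr=False)
    de_direction: dict[str, str] = field(repr=False, default_factory=dict)
    true_target_genes: frozenset[str] = frozenset()
    true_pathways: frozenset[str] = frozenset()


def _feature_name(i: int) -> str:
    return f"MIR{i:05d}"


def _gene_name(i: int) -> str:
    return f"GENE{i:05d}"


def _assign_directions(
    de_features: list[str], direction: str, rng: np.random.Generator
) -> dict[str, str]:
    if direction != "mixed":
        return {f: direction for f in de_features}
    order = list(rng.permutation(len(de_features)))
    n_up = (len(de_features) + 1) // 2  # odd counts: one extra up
    up = {de_features[i] for i in order[:n_up]}
    return {f: ("up" if f in up else "down") for f in de_features}


def generate_dataset(
    config: SimulationConfig,
    dataset_index: int = 0,
    *,
    feature_ids: list[str] | None = None,
    de_features: list[str] | None = None,
    rng: np.random.Generator | None = None,
    true_target_genes: frozenset[str] = frozenset(),
    true_pathways: frozenset[str] = frozenset(),
) -> tuple[ExpressionDataset, SimulationTruth]:
    """Generate one dataset and its planted truth.

    Standalone use draws the feature panel from a pool twice the panel
    size, so independently generated datasets share features by chance;
    :func:`generate_scenario` instead injects panels whose pairwise
    overlaps are controlled. Same config and index always yield identical
    output.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, dataset_index])
    if feature_ids is None:
        pool = [_feature_name(i) for i in range(2 * config.n_features)]
        feature_ids = sorted(rng.choice(pool, size=config.n_features, replace=False))
    if len(feature_ids) != config.n_features:
        raise ValueError("feature panel size does not match config.n_features")
    if de_features is None:
        de_features = sorted(
            rng.choice(feature_ids, size=config.n_de, replace=False)
        )
    de_set = set(de_features)
    if not de_set <= set(feature_ids):
        raise ValueError("DE features must belong to the feature panel")

    ds_id = f"D{dataset_index}"
    n1, n2 = config.n_normal, config.n_tumor
    sample_ids = [f"{ds_id}_N{i:03d}" for i in range(n1)] + [
        f"{ds_id}_T{j:03d}" for j in range(n2)
    ]
    group = [GROUP_NORMAL] * n1 + [GROUP_TUMOR] * n2

    values = rng.normal(0.0, config.noise_sd, size=(config.n_features, n1 + n2))
    directions = _assign_directions(sorted(de_set), config.direction, rng)
    shifted: dict[str, tuple[int, ...]] = {}
    index_of = {f: i for i, f in enumerate(feature_ids)}
    for f in sorted(de_set):
        idx = np.sort(rng.choice(n2, size=config.n_shifted, replace=False))
        sign = 1.0 if directions[f] == "up" else -1.0
        values[index_of[f], n1 + idx] += sign * config.shift
        shifted[f] = tuple(int(i) for i in idx)

    dataset = ExpressionDataset(
        dataset_id=ds_id,
        feature_ids=list(feature_ids),
        sample_ids=sample_ids,
        values=values,
        group=group,
    )
    truth = SimulationTruth(
        dataset_id=ds_id,
        de_features=frozenset(de_set),
        shifted_samples=shifted,
        de_direction=directions,
        true_target_genes=true_target_genes,
        true_pathways=true_pathways,
    )
    return dataset, truth


def _core_size(config: SimulationConfig, rng: np.random.Generator) -> int:
    lo, hi = config.probe_overlap_range
    frac = rng.uniform(lo, hi)
    size = int(round(frac * config.n_features))
    # rounding must not escape the requested range
    size = max(size, int(np.ceil(lo * config.n_features)))
    size = min(size, int(np.floor(hi * config.n_features)))
    if size < 1 or size > config.n_features:
        raise ValueError(
            f"infeasible probe_overlap_range {config.probe_overlap_range} "
            f"for n_features={config.n_features}"
        )
    return size


def generate_scenario(
    config: SimulationConfig,
) -> tuple[
    list[ExpressionDataset], list[SimulationTruth], TargetMap, GeneSetCollection
]:
    """Generate a full multi-dataset scenario with target and pathway truth.

    All ``n_datasets`` panels share a common core sized so every pairwise
    overlap |A ∩ B| / min(|A|, |B|) falls inside ``probe_overlap_range``;
    remaining panel slots are dataset-private features. DE features are a
    shared core subset (fraction ``shared_de_fraction``) plus private
    picks. The target map sends the shared DE-miRNAs preferentially into a
    signal gene pool; the planted gene sets are built mostly from that pool
    while decoy sets avoid it.
    """
    if config.n_datasets < 2:
        raise ValueError("a scenario requires n_datasets >= 2")
    rng = np.random.default_rng(config.seed)

    core_size = _core_size(config, rng)
    n_private = config.n_features - core_size
    core = [_feature_name(i) for i in range(core_size)]
    panels: list[list[str]] = []
    next_id = core_size
    for _ in range(config.n_datasets):
        private = [_feature_name(i) for i in range(next_id, next_id + n_private)]
        next_id += n_private
        panels.append(sorted(core + private))

    n_de = config.n_de
    n_shared_de = int(round(config.shared_de_fraction * n_de))
    if n_shared_de > core_size:
        raise ValueError(
            f"shared DE count {n_shared_de} exceeds the shared core size {core_size}; "
            "lower shared_de_fraction or raise the overlap range"
        )
    shared_de = sorted(rng.choice(core, size=n_shared_de, replace=False))

    # -- target map and gene sets ----------------------------------------
    genes = [_gene_name(i) for i in range(config.n_genes)]
    signal = sorted(rng.choice(genes, size=config.n_signal_genes, replace=False))
    background = sorted(set(genes) - set(signal))

    all_features = sorted(set().union(*panels))
    k_t = config.targets_per_mirna
    k_sig = int(round(config.target_signal_fraction * k_t))
    pairs: list[tuple[str, str]] = []
    shared_de_set = set(shared_de)
    for mir in all_features:
        if mir in shared_de_set:
            tg = list(rng.choice(signal, size=min(k_sig, len(signal)), replace=False))
            tg += list(rng.choice(background, size=k_t - len(tg), replace=False))
        else:
            tg = list(rng.choice(genes, size=k_t, replace=False))
        pairs.extend((mir, g) for g in tg)
    target_map = TargetMap.from_pairs(pairs)

    view = target_map.by_mirna
    true_target_genes = frozenset().union(*(view[m] for m in shared_de))

    n_sig_per_set = int(round(config.gene_set_signal_fraction * config.gene_set_size))
    sets: dict[str, frozenset[str]] = {}
    true_pathways: list[str] = []
    for i in range(config.n_gene_sets):
        name = f"GS{i:03d}"
        if i < config.n_true_gene_sets:
            members = list(
                rng.choice(signal, size=min(n_sig_per_set, len(signal)), replace=False)
            )
            members += list(
                rng.choice(
                    background, size=config.gene_set_size - len(members), replace=False
                )
            )
            true_pathways.append(name)
        else:
            members = list(
                rng.choice(background, size=config.gene_set_size, replace=False)
            )
        sets[name] = frozenset(members)
    collection = GeneSetCollection(sets=sets, universe=frozenset(genes), label="synthetic")
    true_pathway_set = frozenset(true_pathways)

    # -- per-dataset expression ------------------------------------------
    datasets: list[ExpressionDataset] = []
    truths: list[SimulationTruth] = []
    for d in range(config.n_datasets):
        panel = panels[d]
        candidates = sorted(set(panel) - shared_de_set)
        private_de = list(rng.choice(candidates, size=n_de - n_shared_de, replace=False))
        de = sorted(shared_de + private_de)
        child = np.random.default_rng([config.seed, 1000 + d])
        ds, truth = generate_dataset(
            config,
            d,
            feature_ids=panel,
            de_features=de,
            rng=child,
            true_target_genes=true_target_genes,
            true_pathways=true_pathway_set,
        )
        datasets.append(ds)
        truths.append(truth)
    return datasets, truths, target_map, collection


def generate_prediction_tables(
    target_map: TargetMap,
    n_predictors: int,
    noise: float,
    seed: int,
) -> list[TargetMap]:
    """Noisy per-tool versions of a reference target map.

    Each table drops every true pair independently with probability
    ``noise`` and adds ``round(noise * |pairs|)`` spurious pairs drawn from
    the map's miRNA and gene vocabularies. With ``noise=0`` every table
    equals the reference, so their intersection does too; with noise the
    intersection is a high-precision subset.
    """
    if n_predictors < 2:
        raise ValueError("at least 2 predictors are required")
    if not (0.0 <= noise < 1.0):
        raise ValueError("noise must lie in [0, 1)")
    mirnas = sorted(target_map.mirnas)
    genes = sorted(target_map.genes)
    true_pairs = sorted(target_map.pairs)
    n_spurious = int(round(noise * len(true_pairs)))
    tables: list[TargetMap] = []
    for p in range(n_predictors):
        rng = np.random.default_rng([seed, p])
        keep = rng.random(len(true_pairs)) >= noise
        pairs = {pair for pair, k in zip(true_pairs, keep) if k}
        added = 0
        while added < n_spurious:
            pair = (
                mirnas[int(rng.integers(len(mirnas)))],
                genes[int(rng.integers(len(genes)))],
            )
            if pair not in target_map.pairs and pair not in pairs:
                pairs.add(pair)
                added += 1
        tables.append(TargetMap(pairs=frozenset(pairs)))
    return tables


def panel_overlap(a, b) -> float:
    """Probe-panel overlap |A ∩ B| / min(|A|, |B|)."""
    A, B = set(a), set(b)
    return len(A & B) / min(len(A), len(B))


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["probe_overlap_range"] = list(config.probe_overlap_range)
    return d
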