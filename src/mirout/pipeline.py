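"""End-to-end orchestration: simulate/load -> score -> select -> consensus
-> targets -> enrichment.

The stage order mirrors the analysis workflow: per dataset, all statistics
score every feature and nominate their top quantile; the cross-method
consensus ranks the statistics and the winner's selections feed the
target-gene stage; per-dataset target sets are reduced to the cross-dataset
consensus genes, which are finally tested for gene-set over-representation.
Runs are deterministic under a fixed seed and every intermediate can be
written to disk so each stage is testable in isolation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io as mio
from .consensus import (
    ConsensusEvaluation,
    MethodRanking,
    cross_dataset_de_consensus,
    putative_outliers,
    rank_methods,
    select_top_quantile,
)
from .datasets import ExpressionDataset
from .enrichment import GeneSetCollection, enrich
from .simulate import SimulationConfig, SimulationTruth, config_to_dict, generate_scenario
from .stats import METHODS, score_all
from .targets import ConsensusGenes, TargetMap, gene_consensus, targets_of

logger = logging.getLogger("mirout.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Defaults follow the published analysis protocol: selection quantile
    ``q=0.05``, putative outliers need ``k_methods=3`` of the 6 statistics,
    cross-dataset consensus needs ``k_datasets=3`` datasets, and the
    enrichment cutoff is 0.001 (on FDR, or raw p for KEGG-style
    collections). Inputs are either an embedded :class:`SimulationConfig`
    or paths to expression/metadata/target/GMT files.
    """

    q: float = 0.05
    k_methods: int = 3
    k_datasets: int = 3
    methods: tuple[str, ...] = METHODS
    direction_mode: str = "both"
    threshold: float = 0.001
    threshold_on: str = "fdr"
    consensus_level: str = "gene"  # or "mirna"
    seed: int = 0
    simulation: SimulationConfig | None = None
    expression_paths: tuple[tuple[str, str], ...] = ()  # (matrix, metadata) pairs
    target_map_path: str | None = None
    fallback_prediction_paths: tuple[str, ...] = ()
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")
        if not self.methods:
            raise ValueError("at least one method is required")
        if self.k_methods > len(self.methods):
            raise ValueError(
                f"k_methods={self.k_methods} exceeds the number of methods "
                f"({len(self.methods)})"
            )
        if self.consensus_level not in ("gene", "mirna"):
            raise ValueError("consensus_level must be 'gene' or 'mirna'")
        if self.simulation is None and not self.expression_paths:
            raise ValueError("either a simulation config or expression paths are required")


@dataclass
class RunReport:
    """Summary of one pipeline run; JSON-serialisable via ``to_dict``."""

    seed: int
    config: dict
    selection_sizes: dict[str, dict[str, int]]
    accuracy: dict[str, dict[str, float]]
    ranking: MethodRanking
    consensus_de_features: tuple[str, ...]
    consensus_genes: ConsensusGenes | None
    enrichment_summary: dict
    mirnas_without_targets: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        counts = {}
        if self.consensus_genes is not None:
            counts = {
                str(k): v for k, v in self.consensus_genes.counts_by_multiplicity.items()
            }
        return {
            "seed": self.seed,
            "config": self.config,
            "selection_sizes": self.selection_sizes,
            "accuracy": self.accuracy,
            "ranking": {
                "median_accuracy": self.ranking.median,
                "sd_accuracy": self.ranking.sd,
                "best_method": self.ranking.best_method,
            },
            "consensus_de_features": sorted(self.consensus_de_features),
            "n_consensus_de_features": len(self.consensus_de_features),
            "consensus_genes": sorted(self.consensus_genes.genes)
            if self.consensus_genes
            else [],
            "n_consensus_genes": len(self.consensus_genes.genes)
            if self.consensus_genes
            else 0,
            "gene_multiplicity_counts": counts,
            "enrichment": self.enrichment_summary,
            "mirnas_without_targets": sorted(self.mirnas_without_targets),
        }


@dataclass
class PipelineResult:
    """Full in-memory result: the report plus every intermediate."""

    report: RunReport
    datasets: list[ExpressionDataset]
    truths: list[SimulationTruth] = field(default_factory=list)
    evaluations: list[ConsensusEvaluation] = field(default_factory=list)
    best_selections: dict[str, frozenset[str]] = field(default_factory=dict)
    enrichment_table: object | None = None


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        sim = config.simulation
        datasets, truths, target_map, collection = generate_scenario(sim)
        return datasets, truths, target_map, collection
    datasets = [
        mio.read_expression(m, meta) for m, meta in config.expression_paths
    ]
    truths: list[SimulationTruth] = []
    target_map = (
        mio.read_target_map(config.target_map_path) if config.target_map_path else None
    )
    if config.fallback_prediction_paths:
        from .targets import combine_target_maps, intersect_predictions

        tables = [mio.read_target_map(p) for p in config.fallback_prediction_paths]
        fallback = intersect_predictions(tables)
        target_map = (
            combine_target_maps(target_map, fallback) if target_map else fallback
        )
    collection = mio.read_gmt(config.gmt_path) if config.gmt_path else None
    return datasets, truths, target_map, collection


def _warn_private_features(datasets: list[ExpressionDataset]) -> None:
    if len(datasets) < 2:
        return
    for ds in datasets:
        others = set().union(
            *(set(o.feature_ids) for o in datasets if o.dataset_id != ds.dataset_id)
        )
        private = sorted(set(ds.feature_ids) - others)
        if private:
            logger.info(
                "dataset %s has %d features private to it (first: %s)",
                ds.dataset_id,
                len(private),
                private[:3],
            )


def run_full_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Execute every stage and return the report plus intermediates.

    With ``outdir`` set, all intermediates are written there in the
    plain-text formats of :mod:`mirout.io`; reruns with the same config and
    seed produce byte-identical files. Stage timings go to the logger only.
    """
    t0 = time.perf_counter()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name: str, start: float) -> float:
        now = time.perf_counter()
        logger.info("stage %-12s %.2fs", name, now - start)
        return now

    try:
        datasets, truths, target_map, collection = _load_inputs(config)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage 'load': {exc}") from exc
    t = _stage("load", t0)
    _warn_private_features(datasets)

    if out is not None:
        for ds in datasets:
            mio.write_expression(
                ds, out / f"{ds.dataset_id}_expression.tsv", out / f"{ds.dataset_id}_metadata.tsv"
            )
        for truth in truths:
            mio.write_truth(truth, out / f"{truth.dataset_id}_truth.json")
        if target_map is not None:
            mio.write_target_map(target_map, out / "target_map.tsv")
        if collection is not None:
            mio.write_gmt(collection, out / "gene_sets.gmt")

    # -- score + select ---------------------------------------------------
    evaluations: list[ConsensusEvaluation] = []
    selection_sizes: dict[str, dict[str, int]] = {}
    accuracy: dict[str, dict[str, float]] = {}
    best_pool: dict[str, dict[str, frozenset[str]]] = {}
    for ds in datasets:
        try:
            scores = score_all(ds, config.methods, config.direction_mode)
            selections = [select_top_quantile(s, config.q) for s in scores]
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'score' [{ds.dataset_id}]: {exc}") from exc
        if out is not None:
            mio.write_scores(scores, out / f"{ds.dataset_id}_scores.tsv")
        selection_sizes[ds.dataset_id] = {
            s.method: len(s.selected) for s in selections
        }
        best_pool[ds.dataset_id] = {s.method: s.selected_set for s in selections}
        try:
            ev = putative_outliers(selections, config.k_methods)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'consensus' [{ds.dataset_id}]: {exc}"
            ) from exc
        evaluations.append(ev)
        accuracy[ds.dataset_id] = dict(sorted(ev.accuracy.items()))
    t = _stage("score", t)

    ranking = rank_methods(evaluations)
    best = ranking.best_method
    best_selections = {ds_id: pool[best] for ds_id, pool in best_pool.items()}
    if out is not None:
        mio.write_accuracy_table(accuracy, out / "accuracy.tsv")
        mio.write_ranking(ranking, out / "ranking.json")
    t = _stage("rank", t)

    k_d = min(config.k_datasets, len(datasets))
    consensus_de = cross_dataset_de_consensus(best_selections, k_d)

    # -- targets ----------------------------------------------------------
    consensus_genes: ConsensusGenes | None = None
    missing: tuple[str, ...] = ()
    query: frozenset[str] = frozenset()
    if target_map is not None:
        try:
            if config.consensus_level == "gene":
                per_dataset: dict[str, frozenset[str]] = {}
                missing_all: set[str] = set()
                for ds_id, feats in best_selections.items():
                    genes, miss = targets_of(feats, target_map)
                    per_dataset[ds_id] = genes
                    missing_all.update(miss)
                consensus_genes = gene_consensus(per_dataset, k_d)
                query = consensus_genes.genes
                missing = tuple(sorted(missing_all))
            else:  # miRNA-level: consensus first, then targets
                query, miss = targets_of(consensus_de, target_map)
                missing = miss
                consensus_genes = gene_consensus(
                    {ds_id: query for ds_id in best_selections}, k_d
                )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'targets': {exc}") from exc
        if out is not None:
            mio.write_gene_list(query, out / "consensus_genes.txt")
            if consensus_genes is not None:
                rows = sorted(consensus_genes.multiplicity.items())
                with open(out / "gene_multiplicity.tsv", "w") as fh:
                    fh.write("gene_id\tmultiplicity\n")
                    for g, c in rows:
                        fh.write(f"{g}\t{c}\n")
    t = _stage("targets", t)

    # -- enrichment --------------------------------------------------------
    enrichment_summary: dict = {}
    table = None
    if collection is not None and query:
        try:
            table = enrich(
                query, collection, threshold=config.threshold, threshold_on=config.threshold_on
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'enrich': {exc}") from exc
        passing = table[table["passes_threshold"]]
        enrichment_summary = {
            "collection": collection.label,
            "n_sets": int(len(table)),
            "n_passing": int(len(passing)),
            "passing_sets": sorted(passing["set_name"].tolist()),
            "threshold": config.threshold,
            "threshold_on": config.threshold_on,
        }
        if out is not None:
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    t = _stage("enrich", t)

    cfg_echo = {
        "q": config.q,
        "k_methods": config.k_methods,
        "k_datasets": config.k_datasets,
        "methods": list(config.methods),
        "direction_mode": config.direction_mode,
        "threshold": config.threshold,
        "threshold_on": config.threshold_on,
        "consensus_level": config.consensus_level,
        "simulation": config_to_dict(config.simulation) if config.simulation else None,
    }
    report = RunReport(
        seed=config.seed,
        config=cfg_echo,
        selection_sizes=selection_sizes,
        accuracy=accuracy,
        ranking=ranking,
        consensus_de_features=tuple(sorted(consensus_de)),
        consensus_genes=consensus_genes,
        enrichment_summary=enrichment_summary,
        mirnas_without_targets=missing,
    )
    if out is not None:
        mio.write_json(report.to_dict(), out / "report.json")
    logger.info("pipeline done in %.2fs", time.perf_counter() - t0)
    return PipelineResult(
        report=report,
        datasets=datasets,
        truths=truths,
        evaluations=evaluations,
        best_selections=best_selections,
        enrichment_table=table,
    )
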