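"""Readers and writers for the pipeline's plain-text formats.

Formats: expression matrix TSV (first column ``feature_id``, remaining
columns samples), sample metadata TSV (``sample_id``, ``group``), target
map TSV (``mirna_id``, ``gene_id``), GMT gene-set collections, scores and
accuracy TSVs, and JSON for truth/ranking/report. Every reader/writer pair
round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import MethodRanking
from .datasets import ExpressionDataset, VALID_GROUPS
from .enrichment import GeneSetCollection
from .simulate import SimulationTruth
from .stats import MethodScores
from .targets import TargetMap


# -- expression -----------------------------------------------------------


def write_expression(dataset: ExpressionDataset, matrix_path, metadata_path) -> None:
    df = pd.DataFrame(
        dataset.values, index=dataset.feature_ids, columns=dataset.sample_ids
    )
    df.index.name = "feature_id"
    df.to_csv(matrix_path, sep="\t")
    meta = pd.DataFrame({"sample_id": dataset.sample_ids, "group": dataset.group})
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_expression(matrix_path, metadata_path, dataset_id: str | None = None) -> ExpressionDataset:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if list(meta.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(
            f"{metadata_path}: expected columns sample_id, group; got {list(meta.columns)}"
        )
    groups = dict(zip(meta["sample_id"], meta["group"]))
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise ValueError(f"{metadata_path}: no group label for sample(s) {missing}")
    bad = sorted({g for g in groups.values() if g not in VALID_GROUPS})
    if bad:
        raise ValueError(f"{metadata_path}: unknown group label(s) {bad}")
    if dataset_id is None:
        dataset_id = Path(matrix_path).stem
    return ExpressionDataset(
        dataset_id=dataset_id,
        feature_ids=[str(f) for f in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        group=[groups[s] for s in df.columns],
    )


# -- target maps ----------------------------------------------------------


def write_target_map(target_map: TargetMap, path) -> None:
    df = pd.DataFrame(sorted(target_map.pairs), columns=["mirna_id", "gene_id"])
    df.to_csv(path, sep="\t", index=False)


def read_target_map(path) -> TargetMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if cols[:2] != ["mirna_id", "gene_id"]:
        # headerless two-column files are accepted
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two tab-separated columns")
        df.columns = ["mirna_id", "gene_id"] + [str(c) for c in df.columns[2:]]
    if df[["mirna_id", "gene_id"]].isna().any().any():
        raise ValueError(f"{path}: missing miRNA or gene ID")
    return TargetMap.from_pairs(zip(df["mirna_id"], df["gene_id"]))


# -- GMT ------------------------------------------------------------------


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.label}\t{genes}\n")


def read_gmt(path, universe=None, label: str | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated gene IDs).

    ``universe`` defaults to the union of all member genes; pass the
    intended background explicitly for a defensible enrichment null.
    """
    sets: dict[str, frozenset[str]] = {}
    desc = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(
        sets=sets, universe=frozenset(universe), label=label or desc or "geneset"
    )


# -- scores / selections / accuracy --------------------------------------


def write_scores(scores_list: list[MethodScores], path) -> None:
    rows = []
    for ms in scores_list:
        for i, fid in enumerate(ms.feature_ids):
            rows.append(
                (
                    fid,
                    ms.method,
                    repr(float(ms.scores[i])),
                    ms.direction[i],
                    int(ms.degenerate[i]),
                )
            )
    df = pd.DataFrame(
        rows, columns=["feature_id", "method", "score", "direction", "degenerate"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_scores(path, dataset_id: str) -> list[MethodScores]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"feature_id": str, "method": str},
        float_precision="round_trip",
    )
    out = []
    for method, sub in df.groupby("method", sort=True):
        out.append(
            MethodScores(
                method=str(method),
                dataset_id=dataset_id,
                feature_ids=[str(f) for f in sub["feature_id"]],
                scores=sub["score"].to_numpy(dtype=float),
                direction=[str(d) for d in sub["direction"]],
                degenerate=sub["degenerate"].to_numpy(dtype=bool),
            )
        )
    return out


def write_accuracy_table(accuracies: dict[str, dict[str, float]], path) -> None:
    """``accuracies``: dataset_id -> method -> accuracy percent."""
    rows = [
        (ds, m, acc)
        for ds in sorted(accuracies)
        for m, acc in sorted(accuracies[ds].items())
    ]
    pd.DataFrame(rows, columns=["dataset_id", "method", "accuracy_percent"]).to_csv(
        path, sep="\t", index=False
    )


# -- JSON -----------------------------------------------------------------


def _json_default(o):
    if isinstance(o, (frozenset, set)):
        return sorted(o)
    if isinstance(o, tuple):
        return list(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def write_truth(truth: SimulationTruth, path) -> None:
    write_json(
        {
            "dataset_id": truth.dataset_id,
            "de_features": sorted(truth.de_features),
            "shifted_samples": {f: list(v) for f, v in truth.shifted_samples.items()},
            "de_direction": truth.de_direction,
            "true_target_genes": sorted(truth.true_target_genes),
            "true_pathways": sorted(truth.true_pathways),
        },
        path,
    )


def write_ranking(ranking: MethodRanking, path) -> None:
    write_json(
        {
            "median_accuracy": ranking.median,
            "sd_accuracy": ranking.sd,
            "best_method": ranking.best_method,
        },
        path,
    )


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gene_list(path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
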