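"""Core expression-data container.

An :class:`ExpressionDataset` holds one platform's feature x sample matrix of
log-scale expression values together with a binary sample grouping
(``normal`` vs ``tumor``). All downstream statistics operate on the two
group submatrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUP_NORMAL = "normal"
GROUP_TUMOR = "tumor"
VALID_GROUPS = (GROUP_NORMAL, GROUP_TUMOR)


@dataclass
class ExpressionDataset:
    """Feature x sample log-expression matrix with two-group labels.

    Parameters
    ----------
    dataset_id:
        Identifier shared by all artefacts derived from this dataset.
    feature_ids:
        Unique feature (probe / miRNA) identifiers, one per matrix row.
    sample_ids:
        Unique sample identifiers, one per matrix column.
    values:
        Real matrix of shape ``(len(feature_ids), len(sample_ids))``.
    group:
        Per-sample label, each ``"normal"`` or ``"tumor"``; at least two
        samples per group are required.
    """

    dataset_id: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        self.group = list(self.group)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (features x samples)")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature IDs must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample IDs must be unique")
        if len(self.group) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        bad = sorted({g for g in self.group if g not in VALID_GROUPS})
        if bad:
            raise ValueError(f"unknown group labels: {bad}; expected {VALID_GROUPS}")
        if self.n_normal < 2 or self.n_tumor < 2:
            raise ValueError("need at least 2 samples per group")

    # -- group views -------------------------------------------------------

    @property
    def normal_mask(self) -> np.ndarray:
        return np.asarray([g == GROUP_NORMAL for g in self.group])

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.asarray([g == GROUP_TUMOR for g in self.group])

    @property
    def n_normal(self) -> int:
        return sum(g == GROUP_NORMAL for g in self.group)

    @property
    def n_tumor(self) -> int:
        return sum(g == GROUP_TUMOR for g in self.group)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def normal_matrix(self) -> np.ndarray:
        """Submatrix of the normal-group samples (features x n_normal)."""
        return self.values[:, self.normal_mask]

    def tumor_matrix(self) -> np.ndarray:
        """Submatrix of the tumour-group samples (features x n_tumor)."""
        return self.values[:, self.tumor_mask]

    def tumor_sample_ids(self) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group) if g == GROUP_TUMOR]
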