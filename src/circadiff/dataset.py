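"""Expression dataset container and TSV I/O.

An :class:`ExpressionDataset` holds a genes x samples matrix of
log10(1 + normalized count) values and a sample-annotation table with one
row per matrix column (sample_id, group in {young, old}, donor, and the
timepoint in hours).  On disk it is a pair of TSVs: the matrix file
(``gene_id`` plus one column per sample) and the annotation file; columns
are reconciled by sample_id, so their order need not match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DatasetError", "ExpressionDataset", "load_expression", "write_expression"]

_ANNOTATION_COLUMNS = ("sample_id", "group", "donor", "timepoint_hr")
_GROUPS = ("young", "old")


class DatasetError(ValueError):
    """Malformed expression matrix / annotation pair."""


@dataclass
class ExpressionDataset:
    """Genes x samples log-scale expression with sample annotation."""

    gene_ids: list[str]
    values: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DatasetError(f"matrix must be 2-D, got shape {self.values.shape}")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise DatasetError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} annotated samples"
            )
        dup = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()]
        if len(dup):
            raise DatasetError(f"duplicate gene ids: {sorted(set(dup))}")
        missing = [c for c in _ANNOTATION_COLUMNS if c not in self.samples.columns]
        if missing:
            raise DatasetError(f"annotation is missing columns: {missing}")
        bad_groups = set(self.samples["group"]) - set(_GROUPS)
        if bad_groups:
            raise DatasetError(f"unknown groups in annotation: {sorted(bad_groups)}")
        dup_s = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
        if len(dup_s):
            raise DatasetError(f"duplicate sample ids: {sorted(set(dup_s))}")
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices belonging to a group."""
        return np.flatnonzero((self.samples["group"] == group).to_numpy())

    def group_times(self, group: str) -> np.ndarray:
        """Timepoints (hours) for a group's columns, in column order."""
        return self.samples.loc[
            self.samples["group"] == group, "timepoint_hr"
        ].to_numpy(dtype=float)

    def gene_values(self, gene_index: int, group: str) -> np.ndarray:
        return self.values[gene_index, self.group_columns(group)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.samples["sample_id"].tolist(),
        )


def load_expression(matrix_path, annotation_path) -> ExpressionDataset:
    """Load an expression matrix TSV plus annotation TSV, validating the pair.

    Matrix columns are joined to annotation rows by sample_id; every matrix
    column needs an annotation row and vice versa, and all expression cells
    must be numeric.  Errors name the offending samples/genes.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if matrix.columns[0] != "gene_id":
        raise DatasetError(
            f"first matrix column must be 'gene_id', got {matrix.columns[0]!r}"
        )
    annotation = pd.read_csv(annotation_path, sep="\t")
    missing = [c for c in _ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise DatasetError(f"annotation is missing columns: {missing}")

    matrix_samples = list(matrix.columns[1:])
    ann_samples = annotation["sample_id"].astype(str).tolist()
    unannotated = sorted(set(matrix_samples) - set(ann_samples))
    if unannotated:
        raise DatasetError(f"matrix samples missing from annotation: {unannotated}")
    orphaned = sorted(set(ann_samples) - set(matrix_samples))
    if orphaned:
        raise DatasetError(f"annotated samples missing from matrix: {orphaned}")

    # reconcile column order via the annotation's sample order
    data = matrix[ann_samples]
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~data.isna()
    if bad.to_numpy().any():
        genes = matrix.loc[bad.any(axis=1), "gene_id"].tolist()
        raise DatasetError(f"non-numeric expression values for genes: {genes}")
    if numeric.isna().to_numpy().any():
        genes = matrix.loc[numeric.isna().any(axis=1), "gene_id"].tolist()
        raise DatasetError(f"missing expression values for genes: {genes}")

    return ExpressionDataset(
        gene_ids=matrix["gene_id"].tolist(),
        values=numeric.to_numpy(dtype=float),
        samples=annotation,
    )


def write_expression(dataset: ExpressionDataset, matrix_path, annotation_path) -> None:
    """Write the dataset as matrix + annotation TSVs (12 significant digits)."""
    frame = dataset.to_frame().reset_index()
    frame.to_csv(matrix_path, sep="\t", index=False, float_format="%.12g")
    dataset.samples.to_csv(annotation_path, sep="\t", index=False, float_format="%.12g")
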