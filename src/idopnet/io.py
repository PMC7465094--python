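"""Expression matrices, risk labels and the expression index.

The expression index (EI) of a sample is the total expression of all
analyzed genes in that sample.  Because every gene is a part of this
whole, expression can be read as a function of EI across samples, which
is the substrate of the whole pipeline.  EI is always recomputed from
the current gene set — subsetting a dataset changes its EI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionDataset", "load_dataset", "order_by_ei", "module_expression"]


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with per-sample risk labels.

    Parameters
    ----------
    values : DataFrame, genes in rows, samples in columns, non-negative.
    risk : optional Series mapping sample id -> risk label (e.g. "high"/"low").
    """

    values: pd.DataFrame
    risk: pd.Series | None = None

    def __post_init__(self):
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix must be numeric")
        if (arr < 0).any():
            raise ValueError("negative expression values")
        if self.risk is not None:
            self.risk = self.risk.reindex(v.columns)
            if self.risk.isna().any():
                missing = list(self.risk.index[self.risk.isna()])
                raise ValueError(f"samples without risk label: {missing}")

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def ei(self) -> pd.Series:
        """Expression index: per-sample sum over the retained genes.

        Always recomputed from ``values``, never cached, so it can not
        go stale under subsetting.
        """
        return self.values.sum(axis=0)

    @property
    def groups(self) -> list[str]:
        if self.risk is None:
            return []
        return sorted(self.risk.unique())

    # ------------------------------------------------------------------
    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        gene_ids = [g for g in gene_ids if g in self.values.index]
        if not gene_ids:
            raise ValueError("gene subset shares no ids with the dataset")
        return ExpressionDataset(self.values.loc[gene_ids], self.risk)

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        risk = self.risk.loc[sample_ids] if self.risk is not None else None
        return ExpressionDataset(self.values[list(sample_ids)], risk)

    def group(self, label: str) -> "ExpressionDataset":
        """Samples belonging to one risk group.  Per-sample EI values
        are unchanged by the subset: EI sums over genes, not samples."""
        if self.risk is None:
            raise ValueError("dataset has no risk labels")
        ids = list(self.risk.index[self.risk == label])
        if not ids:
            raise ValueError(f"no samples in group {label!r}")
        return self.subset_samples(ids)

    def with_risk(self, risk: pd.Series) -> "ExpressionDataset":
        return ExpressionDataset(self.values, risk)

    def order_by_ei(self) -> "ExpressionDataset":
        """Sort samples by ascending EI; ties broken by sample id."""
        key = pd.DataFrame({"ei": self.ei, "sid": self.values.columns})
        order = key.sort_values(["ei", "sid"], kind="mergesort")["sid"]
        return self.subset_samples(list(order))

    def zero_genes(self) -> list[str]:
        """Genes with all-zero expression: they carry no curve and are
        excluded from model fitting."""
        return list(self.values.index[(self.values == 0).all(axis=1)])

    # ------------------------------------------------------------------
    def write(self, matrix_path, metadata_path=None, sep: str = "\t") -> None:
        self.values.to_csv(matrix_path, sep=sep, index_label="gene_id")
        if metadata_path is not None:
            if self.risk is None:
                raise ValueError("no risk labels to write")
            meta = pd.DataFrame(
                {"sample_id": self.risk.index, "risk": self.risk.values}
            )
            meta.to_csv(metadata_path, index=False)


# ----------------------------------------------------------------------
def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_dataset(matrix_path, metadata_path, gene_list_path=None) -> ExpressionDataset:
    """Load an expression matrix plus sample metadata.

    Orientation of the matrix (genes x samples vs samples x genes) is
    auto-detected by matching metadata sample ids against the column and
    row labels.  Samples missing from the metadata are dropped with a
    warning; a gene list restricts the dataset (and hence the EI) to the
    listed genes.
    """
    mat = _read_table(matrix_path)
    meta = pd.read_csv(metadata_path)
    if "sample_id" not in meta.columns or "risk" not in meta.columns:
        raise ValueError("metadata must have columns sample_id,risk")
    meta_ids = set(meta["sample_id"].astype(str))

    cols = set(map(str, mat.columns))
    rows = set(map(str, mat.index))
    if len(cols & meta_ids) >= len(rows & meta_ids):
        pass  # genes x samples as expected
    elif rows & meta_ids:
        mat = mat.T
    if not set(map(str, mat.columns)) & meta_ids:
        raise ValueError("no overlapping sample ids between matrix and metadata")

    risk = pd.Series(
        meta["risk"].values, index=meta["sample_id"].astype(str), name="risk"
    )
    keep = [c for c in mat.columns if str(c) in risk.index]
    dropped = [c for c in mat.columns if str(c) not in risk.index]
    if dropped:
        logger.warning("dropping %d samples without metadata: %s", len(dropped), dropped[:5])
    mat = mat[keep]
    ds = ExpressionDataset(mat, risk.loc[[str(c) for c in keep]])

    if gene_list_path is not None:
        genes = [
            ln.strip()
            for ln in Path(gene_list_path).read_text().splitlines()
            if ln.strip()
        ]
        ds = ds.subset_genes(genes)
    return ds


def order_by_ei(ds: ExpressionDataset) -> ExpressionDataset:
    return ds.order_by_ei()


def module_expression(ds: ExpressionDataset, labels) -> ExpressionDataset:
    """Aggregate genes to module-level rows by summation.

    ``labels`` maps gene id -> module label.  The sum (not the mean)
    preserves the part-whole identity: summing the module rows of a
    sample recovers its EI exactly.
    """
    labels = dict(labels)
    unknown = set(labels) - set(ds.values.index)
    if unknown:
        raise ValueError(f"partition covers genes absent from dataset: {sorted(unknown)[:5]}")
    missing = set(ds.values.index) - set(labels)
    if missing:
        raise ValueError(f"genes without module assignment: {sorted(missing)[:5]}")
    mod = ds.values.groupby(pd.Series(labels).reindex(ds.values.index)).sum()
    mod.index = [f"M{m}" if not str(m).startswith("M") else str(m) for m in mod.index]
    return ExpressionDataset(mod, ds.risk)
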