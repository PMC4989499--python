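"""Core in-memory containers for gene-by-cell expression data.

Matrices are oriented genes-as-rows, cells-as-columns everywhere in this
package. Each cell carries exactly one collection-time label drawn from a
declared ordered set of time levels; the label order is the time-course
order used by every downstream module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "RescaledMatrix"]


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Non-negative expression values (counts, TPM or normalized counts).

    Parameters
    ----------
    values
        Gene-by-cell (or gene-by-sample) DataFrame; index is gene IDs,
        columns are cell IDs.
    time
        Per-cell time label, an ordered categorical aligned with the
        columns of ``values``. The category order is the collection-time
        order of the experiment.
    unit
        One of ``"counts"``, ``"tpm"``, ``"normalized"``.
    """

    values: pd.DataFrame
    time: pd.Series
    unit: str = "counts"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "cell IDs")
        if self.unit not in ("counts", "tpm", "normalized"):
            raise ValueError(f"unknown unit {self.unit!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        self.time = pd.Series(self.time)
        missing = self.values.columns.difference(self.time.index)
        if len(missing):
            raise ValueError(f"cells without a time label: {list(missing[:5])}")
        self.time = self.time.reindex(self.values.columns)
        if not isinstance(self.time.dtype, pd.CategoricalDtype):
            levels = list(pd.unique(self.time))
            self.time = self.time.astype(
                pd.CategoricalDtype(categories=levels, ordered=True)
            )
        elif not self.time.cat.ordered:
            self.time = self.time.cat.as_ordered()
        if self.time.isna().any():
            bad = self.time.index[self.time.isna()].tolist()
            raise ValueError(f"cells with time label outside declared set: {bad[:5]}")

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def time_levels(self) -> list:
        """Declared collection times, in time-course order (observed only)."""
        observed = [
            lv for lv in self.time.cat.categories if (self.time == lv).any()
        ]
        return observed

    def cells_at(self, level) -> np.ndarray:
        """Column indices of the cells collected at ``level``."""
        return np.flatnonzero((self.time == level).to_numpy())

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, cell_ids], self.time.loc[cell_ids], self.unit
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[gene_ids], self.time, self.unit
        )


@dataclass
class RescaledMatrix:
    """Per-gene standardized expression (mean 0, unit sample variance).

    Keeps the per-gene mean and standard deviation that produced the
    rescaling so the transform is auditable and invertible, plus the list
    of zero-variance genes that had to be dropped.
    """

    values: pd.DataFrame
    time: pd.Series
    gene_means: pd.Series
    gene_sds: pd.Series
    dropped_genes: list = field(default_factory=list)
    log_transformed: bool = False
    variance_convention: str = "sample"  # n-1 denominator

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cells_at(self, level) -> np.ndarray:
        return np.flatnonzero((self.time == level).to_numpy())

    @property
    def time_levels(self) -> list:
        observed = [
            lv for lv in self.time.cat.categories if (self.time == lv).any()
        ]
        return observed
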