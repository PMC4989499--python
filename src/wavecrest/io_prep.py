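"""Reading/writing expression matrices and the standard preprocessing steps.

Covers dense TSV/CSV and MatrixMarket input, per-cell QC on detected-gene
counts, median-by-ratio (median-of-ratios) size-factor normalization,
low-median gene filtering, per-gene standardization, and the FACS-derived
Differentiation Score used in knockdown screens.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, RescaledMatrix

__all__ = [
    "load_matrix",
    "save_matrix",
    "qc_filter_cells",
    "median_by_ratio_normalize",
    "filter_low_median_genes",
    "rescale_genes",
    "differentiation_score",
]


def _read_metadata(meta_path, time_order=None) -> pd.Series:
    meta = pd.read_csv(meta_path)
    if not {"cell_id", "time_label"} <= set(meta.columns):
        raise ValueError("metadata must have columns cell_id, time_label")
    if meta["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in metadata")
    labels = meta.set_index("cell_id")["time_label"].astype(str)
    if time_order is None:
        time_order = list(pd.unique(labels))
    bad = set(labels) - set(map(str, time_order))
    if bad:
        raise ValueError(f"time labels outside declared ordered set: {sorted(bad)}")
    return labels.astype(pd.CategoricalDtype([str(t) for t in time_order], ordered=True))


def load_matrix(
    path,
    format: str = "tsv",
    meta_path=None,
    *,
    unit: str = "counts",
    time_order=None,
    transposed: bool = False,
) -> ExpressionMatrix:
    """Load a gene-by-cell matrix plus its cell metadata.

    Dense ``tsv``/``csv``: first column gene IDs, header row of cell IDs.
    ``mtx``: MatrixMarket triplets with sidecar ``<stem>.genes.txt`` and
    ``<stem>.cells.txt`` one-ID-per-line files.

    Cells are restricted to (and ordered by) the matrix columns; every
    matrix cell must appear in the metadata, which maps cell IDs to a time
    label validated against the declared ordered set (``time_order``; by
    default the order of first appearance in the metadata file).
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx":
        genes_path = path.with_suffix(".genes.txt")
        cells_path = path.with_suffix(".cells.txt")
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FileNotFoundError(f"missing MatrixMarket sidecar file {p}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = genes_path.read_text().split()
        cells = cells_path.read_text().split()
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=cells)
    else:
        raise ValueError(f"unknown format {format!r}")
    if transposed:
        df = df.T
    if meta_path is None:
        raise ValueError("meta_path is required")
    labels = _read_metadata(meta_path, time_order)
    orphans = df.columns.difference(labels.index)
    if len(orphans):
        raise ValueError(
            f"cells present in matrix but absent from metadata: {list(orphans[:5])}"
        )
    return ExpressionMatrix(df, labels.reindex(df.columns), unit=unit)


def save_matrix(m: ExpressionMatrix, path, format: str = "tsv", meta_path=None) -> None:
    """Write a matrix (and optionally its metadata) in a loadable format."""
    path = pathlib.Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        m.values.to_csv(path, sep=sep)
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values.to_numpy()))
        path.with_suffix(".genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        path.with_suffix(".cells.txt").write_text("\n".join(m.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    if meta_path is not None:
        pd.DataFrame(
            {"cell_id": m.cell_ids, "time_label": m.time.to_numpy()}
        ).to_csv(meta_path, index=False)


def qc_filter_cells(
    m: ExpressionMatrix, min_genes: int = 5000, tpm_threshold: float = 1.0
) -> tuple[ExpressionMatrix, list]:
    """Remove cells detecting fewer than ``min_genes`` genes at TPM above
    ``tpm_threshold``.

    A cell is retained iff its number of genes with TPM strictly greater
    than ``tpm_threshold`` is at least ``min_genes``. Returns the filtered
    matrix and the removed cell IDs.
    """
    if m.unit != "tpm":
        raise ValueError("QC on detected-gene counts requires TPM values")
    detected = (m.values.to_numpy() > tpm_threshold).sum(axis=0)
    keep = detected >= min_genes
    removed = list(m.cell_ids[~keep])
    return m.subset_cells(m.cell_ids[keep]), removed


def median_by_ratio_normalize(
    m: ExpressionMatrix, *, min_positive_fraction: float = 1.0
) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios normalization (the DESeq-style size factor).

    Size factor of cell ``j`` is the median over reference genes of
    ``values[g, j] / geometric_mean_g``, where the geometric mean is over
    cells with positive counts and the reference set is the genes positive
    in at least ``min_positive_fraction`` of cells (1.0 = classical rule:
    positive in every cell). Normalized values divide each column by its
    size factor.
    """
    X = m.values.to_numpy(dtype=float)
    pos_frac = (X > 0).mean(axis=1)
    ref = pos_frac >= min_positive_fraction
    if not ref.any():
        raise ValueError(
            "no gene is positive in the required fraction of cells; relax the "
            "reference-gene rule via min_positive_fraction < 1"
        )
    R = X[ref]
    # geometric mean over all cells; rows of R are strictly positive when
    # min_positive_fraction == 1, otherwise restrict to positive entries
    with np.errstate(divide="ignore"):
        logs = np.where(R > 0, np.log(R), np.nan)
    geo = np.exp(np.nanmean(logs, axis=1))
    ratios = R / geo[:, None]
    size_factors = np.nanmedian(np.where(R > 0, ratios, np.nan), axis=0)
    if not np.all(np.isfinite(size_factors)) or (size_factors <= 0).any():
        raise ValueError("non-positive or undefined size factor for some cell")
    norm = pd.DataFrame(X / size_factors, index=m.gene_ids, columns=m.cell_ids)
    sf = pd.Series(size_factors, index=m.cell_ids, name="size_factor")
    return ExpressionMatrix(norm, m.time, unit="normalized"), sf


def filter_low_median_genes(
    m: ExpressionMatrix, min_median: float = 10.0
) -> tuple[ExpressionMatrix, list]:
    """Drop genes whose median expression across cells is below ``min_median``.

    The rule is strict: a gene at exactly ``min_median`` is retained.
    Returns the filtered matrix and the dropped gene IDs.
    """
    med = np.median(m.values.to_numpy(), axis=1)
    keep = med >= min_median
    dropped = list(m.gene_ids[~keep])
    return m.subset_genes(m.gene_ids[keep]), dropped


def rescale_genes(m: ExpressionMatrix, log_transform: bool = True) -> RescaledMatrix:
    """Standardize each gene to mean 0 and unit sample variance across cells.

    With ``log_transform`` the values are log2(x + 1) before
    standardization. Sample variance uses the n-1 denominator. Genes with
    zero variance carry no ordering information and are dropped; they are
    listed in ``dropped_genes``.
    """
    if m.n_cells < 2:
        raise ValueError("rescaling requires at least 2 cells")
    X = m.values.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    means = X.mean(axis=1)
    sds = X.std(axis=1, ddof=1)
    keep = sds > 0
    dropped = list(m.gene_ids[~keep])
    Z = (X[keep] - means[keep, None]) / sds[keep, None]
    return RescaledMatrix(
        values=pd.DataFrame(Z, index=m.gene_ids[keep], columns=m.cell_ids),
        time=m.time,
        gene_means=pd.Series(means[keep], index=m.gene_ids[keep]),
        gene_sds=pd.Series(sds[keep], index=m.gene_ids[keep]),
        dropped_genes=dropped,
        log_transformed=log_transform,
    )


def differentiation_score(
    pct_cxcr4: float,
    pct_egfp: float,
    control_pct_cxcr4: float,
    control_pct_egfp: float,
) -> float:
    """Differentiation Score of a knockdown condition.

    The ratio (% CXCR4+ cells) / (% T-reporter-EGFP+ cells), normalized by
    the same ratio in the non-targeting control so the control scores
    exactly 1. All four percentages must lie in (0, 100].
    """
    for name, v in (
        ("pct_cxcr4", pct_cxcr4),
        ("pct_egfp", pct_egfp),
        ("control_pct_cxcr4", control_pct_cxcr4),
        ("control_pct_egfp", control_pct_egfp),
    ):
        if not (0 < v <= 100):
            raise ValueError(f"{name} must be in (0, 100], got {v}")
    return (pct_cxcr4 / pct_egfp) / (control_pct_cxcr4 / control_pct_egfp)
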