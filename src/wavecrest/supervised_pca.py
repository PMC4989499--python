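"""Bulk-supervised PCA: fit component axes on bulk RNA-seq, project cells.

PCA on single-cell data directly can be dominated by technical noise, so
the component axes are learned from matched bulk RNA-seq instead: genes
are standardized across bulk samples, the loading matrix W is taken from
the bulk decomposition, and each single cell j (standardized per gene
across cells) is placed at score[j, n] = sum_g W[g, n] * Xtilde[g, j].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, RescaledMatrix
from .io_prep import rescale_genes

__all__ = ["PCModel", "fit_bulk_pca", "project_cells", "export_loading_weights"]


@dataclass
class PCModel:
    """Bulk-derived per-gene standardization plus the loading matrix W.

    ``loadings`` is genes x components with orthonormal columns; the sign
    of each component is fixed so its largest-magnitude loading is
    positive, making outputs reproducible across linear-algebra backends.
    """

    loadings: pd.DataFrame  # genes x components
    bulk_means: pd.Series
    bulk_sds: pd.Series
    explained_variance: np.ndarray
    bulk_scores: pd.DataFrame  # samples x components, for self-consistency checks
    sign_flipped: np.ndarray  # per component, True if the raw SVD sign was flipped

    @property
    def genes(self) -> pd.Index:
        return self.loadings.index

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_bulk_pca(
    bulk: ExpressionMatrix, n_components: int, *, log_transform: bool = True
) -> PCModel:
    """PCA of the per-gene standardized bulk matrix.

    Genes are rescaled to mean 0, unit sample variance across bulk samples
    (constant genes dropped) before the decomposition; at most
    min(#samples - 1, #genes) components are admissible.
    """
    if bulk.n_cells < 2:
        raise ValueError("need at least 2 bulk samples")
    rescaled = rescale_genes(bulk, log_transform=log_transform)
    Z = rescaled.values.to_numpy()  # genes x samples
    max_rank = min(bulk.n_cells - 1, Z.shape[0])
    if not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components={n_components} outside admissible range 1..{max_rank}"
        )
    # SVD of the samples-x-genes matrix; right singular vectors are loadings
    M = Z.T
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    W = Vt[:n_components].T  # genes x components
    flipped = np.zeros(n_components, dtype=bool)
    for k in range(n_components):
        i = np.argmax(np.abs(W[:, k]))
        if W[i, k] < 0:
            W[:, k] = -W[:, k]
            flipped[k] = True
    scores = M @ W
    comps = [f"PC{k + 1}" for k in range(n_components)]
    return PCModel(
        loadings=pd.DataFrame(W, index=rescaled.gene_ids, columns=comps),
        bulk_means=rescaled.gene_means,
        bulk_sds=rescaled.gene_sds,
        explained_variance=(S[:n_components] ** 2) / (M.shape[0] - 1),
        bulk_scores=pd.DataFrame(scores, index=bulk.cell_ids, columns=comps),
        sign_flipped=flipped,
    )


def project_cells(
    model: PCModel, cells: RescaledMatrix
) -> tuple[pd.DataFrame, list]:
    """Project per-gene standardized cells onto the bulk loading axes.

    Only genes shared between the model and the cells contribute;
    score[j, n] = sum over shared genes g of W[g, n] * Xtilde[g, j].
    Returns (cell-by-component scores, gene IDs dropped from either side).
    """
    shared = model.genes.intersection(cells.gene_ids)
    if len(shared) == 0:
        raise ValueError("no genes shared between bulk model and cells")
    dropped = sorted(
        set(model.genes).symmetric_difference(set(cells.gene_ids))
    )
    W = model.loadings.loc[shared].to_numpy()
    X = cells.values.loc[shared].to_numpy()  # genes x cells
    scores = X.T @ W
    return (
        pd.DataFrame(scores, index=cells.cell_ids, columns=model.loadings.columns),
        dropped,
    )


def export_loading_weights(model: PCModel, component: int) -> pd.Series:
    """Absolute loadings |W[g, n]| of one component, as per-gene weights
    for downstream gene-set enrichment tools (1-based component index)."""
    if not (1 <= component <= model.n_components):
        raise IndexError(
            f"component {component} out of range 1..{model.n_components}"
        )
    col = f"PC{component}"
    return model.loadings[col].abs().rename(f"abs_loading_{col}")
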