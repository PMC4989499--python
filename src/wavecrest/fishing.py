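"""Fishing: permutation screening of candidate genes for smooth trends.

Given a recovered cell order (or a contiguous slice of it, e.g. the cells
of one collection time), each candidate gene's rescaled expression is
fitted with a polynomial against rank position and summarized by its MSE
(small MSE = smooth trend). Significance comes from a permutation null:
repeatedly draw a gene uniformly from the universe under consideration,
permute its cell order, and record the refitted MSE; the p-value of a
candidate is the fraction of null MSEs at or below its observed MSE.
Direction (up/down) is the sign of a separate linear fit's slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._regression import linear_slope, mse_matrix, polyfit_order
from .containers import RescaledMatrix
from .ordering import CellOrder, TrendFit

__all__ = ["FishingResult", "fit_gene_mse", "permutation_pvalues", "rank_candidates"]


@dataclass
class FishingResult:
    """Per-candidate fishing record."""

    gene: str
    mse: float
    p_literal: float  # (# null MSE <= observed MSE) / n_perm; may be 0
    p_corrected: float  # (k + 1) / (n_perm + 1)
    slope_sign: int
    direction: str  # "up" or "down"
    zero_slope_flag: bool = False
    rank: int | None = None  # 1-based, within direction


def _slice_indices(order) -> np.ndarray:
    if isinstance(order, CellOrder):
        return order.order
    return np.asarray(order, dtype=int)


def fit_gene_mse(
    order, data: RescaledMatrix, gene: str, degree: int = 3
) -> TrendFit:
    """Polynomial fit of one gene along an order slice.

    The MSE comes from the degree-d fit; the slope sign from a separate
    degree-1 fit on the same points.
    """
    idx = _slice_indices(order)
    if gene not in data.gene_ids:
        raise KeyError(f"gene {gene!r} absent from data")
    if idx.size < degree + 2:
        raise ValueError(f"order slice of {idx.size} cells is shorter than degree+2")
    y = data.values.loc[gene].to_numpy(dtype=float)[idx]
    coef, mse = polyfit_order(y, degree)
    slope = linear_slope(y)
    # a symmetric profile has slope 0 up to rounding; call it zero
    tol = 1e-12 * max(1.0, float(np.abs(y).max()))
    sign = 0 if abs(slope) < tol else int(np.sign(slope))
    return TrendFit(gene, degree, coef, mse, sign)


def permutation_pvalues(
    order,
    data: RescaledMatrix,
    candidates,
    universe=None,
    degree: int = 3,
    n_perm: int = 100_000,
    seed: int = 0,
    *,
    shared_null: bool = True,
    allow_small_n_perm: bool = False,
    _chunk: int = 512,
) -> list[FishingResult]:
    """Permutation p-values for candidate genes along an order slice.

    Builds a null MSE sample of size ``n_perm`` (draw a gene uniformly
    from the universe — by default every gene in ``data`` — permute its
    cell order uniformly, refit) shared across candidates; with
    ``shared_null=False`` an independent null of the same size is drawn
    per candidate. For observed MSE m, the literal p-value is
    ``#{null <= m} / n_perm`` (which can be exactly 0); the standard
    ``(k+1)/(n_perm+1)`` correction is reported alongside. Deterministic
    given the seed.
    """
    idx = _slice_indices(order)
    candidates = list(candidates)
    universe = list(universe) if universe is not None else list(data.gene_ids)
    if not universe:
        raise ValueError("permutation universe is empty")
    missing = [g for g in candidates if g not in data.gene_ids]
    if missing:
        raise KeyError(f"candidate genes absent from data: {missing[:5]}")
    if n_perm < 100 and not allow_small_n_perm:
        raise ValueError(
            "n_perm < 100 gives unusably coarse p-values; pass "
            "allow_small_n_perm=True to override"
        )
    rng = np.random.default_rng(seed)
    n = idx.size
    U = data.values.loc[universe].to_numpy(dtype=float)[:, idx]  # universe x cells

    def draw_null(r: np.random.Generator) -> np.ndarray:
        null = np.empty(n_perm)
        done = 0
        while done < n_perm:
            k = min(_chunk, n_perm - done)
            gene_idx = r.integers(len(universe), size=k)
            block = np.empty((n, k))
            for i, gi in enumerate(gene_idx):
                block[:, i] = U[gi, r.permutation(n)]
            null[done : done + k] = mse_matrix(block, degree)
            done += k
        return null

    shared = draw_null(rng) if shared_null else None

    results = []
    for gene in candidates:
        fit = fit_gene_mse(idx, data, gene, degree)
        null = shared if shared_null else draw_null(rng)
        k = int((null <= fit.mse).sum())
        direction = "down" if fit.slope_sign < 0 else "up"
        results.append(
            FishingResult(
                gene=gene,
                mse=fit.mse,
                p_literal=k / n_perm,
                p_corrected=(k + 1) / (n_perm + 1),
                slope_sign=fit.slope_sign,
                direction=direction,
                zero_slope_flag=fit.slope_sign == 0,
            )
        )
    return results


def rank_candidates(
    results: list[FishingResult], top_k: int = 25
) -> tuple[list[FishingResult], list[FishingResult]]:
    """Split results by direction and rank by trend quality.

    Within each direction, genes are sorted ascending by observed MSE,
    then by literal p-value, then by gene ID; ranks are 1-based. Returns
    the top ``top_k`` of each direction (up list, down list).
    """
    if not results:
        raise ValueError("no fishing results to rank")
    out = []
    for direction in ("up", "down"):
        group = [r for r in results if r.direction == direction]
        group.sort(key=lambda r: (r.mse, r.p_literal, r.gene))
        for i, r in enumerate(group, start=1):
            r.rank = i
        out.append(group[:top_k])
    return out[0], out[1]
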