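"""Marker-guided cell ordering under the collection-time block constraint.

Cells sampled at successive collection times are reordered so that a set
of marker genes traces smooth profiles along the order, quantified as the
aggregated mean squared error (MSE) of per-gene polynomial regressions
against rank position. The order is built greedily by extended nearest
insertion (ENI) — cells are inserted one at a time into the admissible
slot of minimal aggregated MSE — and then refined by 2-opt local search.
The hard constraint throughout: cells from different collection times may
not interleave, so the order is a sequence of contiguous time blocks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._regression import mse_matrix
from .containers import RescaledMatrix

__all__ = [
    "CellOrder",
    "TrendFit",
    "aggregated_mse",
    "eni_order",
    "two_opt_refine",
    "recover_order",
    "exhaustive_oracle",
    "count_admissible_orders",
]


@dataclass(frozen=True)
class TrendFit:
    """Polynomial fit of one gene along a cell order."""

    gene: str
    degree: int
    coefficients: np.ndarray  # increasing power order
    mse: float
    slope_sign: int  # sign of the separate degree-1 fit: +1, -1 or 0

    def __post_init__(self):
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.mse < 0:
            raise ValueError("MSE must be >= 0")


@dataclass
class CellOrder:
    """A permutation of cell (column) indices partitioned into contiguous
    time blocks, one per collection time, in collection-time order."""

    order: np.ndarray
    block_spans: list  # [(start, stop)] half-open, one per time level
    time_levels: list

    def __post_init__(self):
        self.order = np.asarray(self.order, dtype=int)
        n = self.order.size
        if not np.array_equal(np.sort(self.order), np.arange(n)):
            raise ValueError("order must be a permutation of all cell indices")
        if len(self.block_spans) != len(self.time_levels):
            raise ValueError("one block span per time level required")
        pos = 0
        for start, stop in self.block_spans:
            if start != pos or stop < start:
                raise ValueError("block spans must be contiguous and ordered")
            pos = stop
        if pos != n:
            raise ValueError("block spans must cover the whole order")

    def __len__(self) -> int:
        return self.order.size

    def block(self, level) -> np.ndarray:
        """Ordered cell indices of the block collected at ``level``."""
        i = self.time_levels.index(level)
        start, stop = self.block_spans[i]
        return self.order[start:stop]

    @classmethod
    def from_data(cls, data: RescaledMatrix, order) -> "CellOrder":
        """Build (and validate) a CellOrder from an index sequence, deriving
        block spans from the data's time labels."""
        order = np.asarray(order, dtype=int)
        levels = data.time_levels
        codes = data.time.cat.codes.to_numpy()[order]
        if np.any(np.diff(codes) < 0):
            raise ValueError("cells from different collection times are mixed")
        spans, pos = [], 0
        for lv in levels:
            size = int((data.time == lv).sum())
            spans.append((pos, pos + size))
            pos += size
        return cls(order, spans, list(levels))

    def to_frame(self, data: RescaledMatrix) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(len(self)),
                "cell_id": data.cell_ids[self.order],
                "time_label": data.time.to_numpy()[self.order],
            }
        )


def _marker_matrix(data: RescaledMatrix, genes) -> np.ndarray:
    genes = list(genes)
    if not genes:
        raise ValueError("marker gene set is empty")
    missing = [g for g in genes if g not in data.gene_ids]
    if missing:
        raise KeyError(f"marker genes absent from data: {missing[:5]}")
    # cells x genes, in native column order
    return data.values.loc[genes].to_numpy(dtype=float).T


def aggregated_mse(
    order: CellOrder | np.ndarray, data: RescaledMatrix, genes, degree: int = 3
) -> float:
    """Sum over marker genes of the polynomial-regression MSE along the order.

    Each gene's rescaled expression is fitted against rank positions mapped
    to equally spaced points in [0, 1]; the objective is the sum of the
    per-gene mean squared residuals.
    """
    idx = order.order if isinstance(order, CellOrder) else np.asarray(order, int)
    Y = _marker_matrix(data, genes)[idx]
    return float(mse_matrix(Y, degree).sum())


def eni_order(
    data: RescaledMatrix, genes, degree: int = 3, seed: int = 0
) -> CellOrder:
    """Construct a cell order by constrained extended nearest insertion.

    Starts from one randomly chosen cell per collection time (in time
    order); the remaining cells are drawn in random sequence and each is
    inserted into the slot — any position inside its own time block,
    including the block's two edges — that minimizes the aggregated MSE,
    ties resolved to the earliest slot. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    levels = data.time_levels
    if len(levels) < 2:
        raise ValueError("need at least 2 collection time points")
    Y = _marker_matrix(data, genes)  # cells x genes

    block_cells = []
    for lv in levels:
        cells = data.cells_at(lv)
        if cells.size == 0:
            raise ValueError(f"time point {lv!r} has no cells")
        block_cells.append(cells)

    level_of = data.time.cat.codes.to_numpy()
    observed_code = {lv: data.time.cat.categories.get_loc(lv) for lv in levels}
    code_to_block = {observed_code[lv]: b for b, lv in enumerate(levels)}

    seeds = [int(rng.choice(cells)) for cells in block_cells]
    order = list(seeds)
    sizes = [1] * len(levels)

    remaining = np.array(
        [c for c in range(data.n_cells) if c not in set(seeds)], dtype=int
    )
    rng.shuffle(remaining)

    for c in remaining:
        b = code_to_block[level_of[c]]
        start = sum(sizes[:b])
        best_mse, best_pos = math.inf, None
        # early in construction there are fewer points than degree+2;
        # cap the degree so the fit stays overdetermined
        d_eff = max(1, min(degree, len(order) + 1 - 2))
        for pos in range(start, start + sizes[b] + 1):
            cand = order[:pos] + [c] + order[pos:]
            mse = float(mse_matrix(Y[np.asarray(cand)], d_eff).sum())
            if mse < best_mse - 0.0:  # strict: ties keep the earliest slot
                best_mse, best_pos = mse, pos
        order.insert(best_pos, c)
        sizes[b] += 1

    spans, pos = [], 0
    for s in sizes:
        spans.append((pos, pos + s))
        pos += s
    return CellOrder(np.array(order), spans, list(levels))


def two_opt_refine(
    order: CellOrder,
    data: RescaledMatrix,
    genes,
    degree: int = 3,
    n_iter: int = 20000,
    seed: int = 0,
    *,
    move: str = "reversal",
    max_consecutive_rejects: int = 2000,
    return_trace: bool = False,
):
    """Refine an order by 2-opt local search within time blocks.

    Proposes ``n_iter`` random moves — segment reversals (default) or pair
    swaps — with both endpoints in the same time block, accepting a move
    iff the aggregated MSE strictly decreases; stops early after
    ``max_consecutive_rejects`` consecutive rejections. The output MSE is
    never above the input MSE and the time-block constraint is preserved.
    """
    if move not in ("reversal", "swap"):
        raise ValueError("move must be 'reversal' or 'swap'")
    rng = np.random.default_rng(seed)
    Y = _marker_matrix(data, genes)
    cur = order.order.copy()
    cur_mse = float(mse_matrix(Y[cur], degree).sum())
    trace = [cur_mse]
    eligible = [
        (start, stop) for start, stop in order.block_spans if stop - start >= 2
    ]
    if eligible and n_iter > 0:
        rejects = 0
        for _ in range(n_iter):
            start, stop = eligible[rng.integers(len(eligible))]
            i, j = rng.choice(np.arange(start, stop), size=2, replace=False)
            if i > j:
                i, j = j, i
            cand = cur.copy()
            if move == "reversal":
                cand[i : j + 1] = cand[i : j + 1][::-1]
            else:
                cand[i], cand[j] = cand[j], cand[i]
            mse = float(mse_matrix(Y[cand], degree).sum())
            if mse < cur_mse:
                cur, cur_mse = cand, mse
                trace.append(cur_mse)
                rejects = 0
            else:
                rejects += 1
                if rejects >= max_consecutive_rejects:
                    break
    refined = CellOrder(cur, list(order.block_spans), list(order.time_levels))
    if return_trace:
        return refined, trace
    return refined


def recover_order(
    data: RescaledMatrix,
    genes,
    degree: int = 3,
    seed: int = 0,
    n_restarts: int = 5,
    n_iter: int = 20000,
    *,
    move: str = "reversal",
) -> CellOrder:
    """Multi-start order recovery: ENI construction plus 2-opt refinement.

    The greedy ENI construction is randomized (seed cells and insertion
    sequence), so a single run can land in a poor basin; this runs
    ``n_restarts`` independent constructions, refines each by 2-opt, and
    returns the order with the lowest aggregated MSE. Deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(2**31, size=max(1, n_restarts))
    best_order, best_mse = None, math.inf
    for s in child_seeds:
        o = eni_order(data, genes, degree=degree, seed=int(s))
        o = two_opt_refine(
            o, data, genes, degree=degree, n_iter=n_iter, seed=int(s), move=move
        )
        mse = aggregated_mse(o, data, genes, degree)
        if mse < best_mse:
            best_order, best_mse = o, mse
    return best_order


def count_admissible_orders(data: RescaledMatrix) -> int:
    """Number of orders respecting the time-block constraint."""
    return math.prod(
        math.factorial(int((data.time == lv).sum())) for lv in data.time_levels
    )


def exhaustive_oracle(
    data: RescaledMatrix, genes, degree: int = 3, max_orders: int = 1_000_000
) -> tuple[CellOrder, float]:
    """Globally optimal order by brute-force enumeration (test-scale only).

    Enumerates every admissible order (product of within-block
    permutations) and returns one argmin order with its aggregated MSE.
    """
    total = count_admissible_orders(data)
    if total > max_orders:
        raise ValueError(f"{total} admissible orders exceeds max_orders={max_orders}")
    Y = _marker_matrix(data, genes)
    levels = data.time_levels
    blocks = [data.cells_at(lv) for lv in levels]
    best_mse, best = math.inf, None
    for perm_tuple in itertools.product(
        *(itertools.permutations(b.tolist()) for b in blocks)
    ):
        cand = np.fromiter(itertools.chain.from_iterable(perm_tuple), dtype=int)
        mse = float(mse_matrix(Y[cand], degree).sum())
        if mse < best_mse:
            best_mse, best = mse, cand
    spans, pos = [], 0
    for b in blocks:
        spans.append((pos, pos + b.size))
        pos += b.size
    return CellOrder(best, spans, list(levels)), best_mse
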