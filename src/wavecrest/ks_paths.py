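"""Directional KS tests between adjacent collection times, composed into
per-gene expression paths.

A gene's behaviour over an ordered time course is summarized as a path of
per-transition calls (Up / Down / EE, one per adjacent pair of time
points): a two-sample Kolmogorov-Smirnov test compares the gene's
expression distributions in consecutive conditions, the call direction is
the sign of the dominant one-sided KS statistic, and a gene is
differentially expressed iff any transition is not EE. This is a
thresholded, test-based path caller; it deliberately does not model
posterior path probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = ["PathCall", "signed_ks", "classify_paths"]

#: sign convention: positive statistic = later condition stochastically larger (Up)
SIGN_CONVENTION = "positive = increase over time"


@dataclass
class PathCall:
    """Per-gene path of per-transition calls across the time course."""

    gene: str
    directions: list  # "Up" / "Down" / "EE", one per adjacent time pair
    statistics: np.ndarray  # signed KS statistics, in [-1, 1]
    pvalues: np.ndarray  # (adjusted, if requested) per-transition p-values

    @property
    def path(self) -> str:
        return "-".join(self.directions)

    @property
    def is_de(self) -> bool:
        return any(d != "EE" for d in self.directions)


def signed_ks(x, y) -> tuple[float, float]:
    """Signed two-sample KS statistic and asymptotic p-value.

    Magnitude is the usual two-sample KS distance between ``x`` (earlier
    condition) and ``y`` (later condition); the sign is that of the
    dominant one-sided statistic, positive when ``y`` is stochastically
    larger (Up). Antisymmetric in its arguments; 0 when the one-sided
    statistics tie exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each condition needs at least 3 cells")
    grid = np.concatenate([x, y])
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    d_plus = float(np.max(fx - fy))  # mass of x sits lower -> y larger -> Up
    d_minus = float(np.max(fy - fx))
    d = max(d_plus, d_minus, 0.0)
    if d_plus > d_minus:
        stat = d
    elif d_minus > d_plus:
        stat = -d
    else:
        stat = 0.0
    p = float(stats.ks_2samp(x, y, method="asymp").pvalue)
    return stat, min(p, 1.0)


def classify_paths(
    data: ExpressionMatrix, alpha: float = 0.05, fdr: bool = True
) -> list[PathCall]:
    """Call per-gene expression paths across adjacent collection times.

    For every gene and adjacent time pair, a signed KS test is run; the
    transition is Up/Down if its p-value (Benjamini-Hochberg adjusted
    across genes within the transition when ``fdr`` is on) is at most
    ``alpha``, with direction from the statistic's sign, else EE. Output
    is sorted by gene ID.
    """
    levels = data.time_levels
    if len(levels) < 2:
        raise ValueError("need at least 2 time points")
    groups = []
    for lv in levels:
        cells = data.cells_at(lv)
        if cells.size < 3:
            raise ValueError(f"time point {lv!r} has fewer than 3 cells")
        groups.append(data.values.to_numpy(dtype=float)[:, cells])
    n_genes = data.n_genes
    n_trans = len(levels) - 1
    stat = np.zeros((n_genes, n_trans))
    pval = np.ones((n_genes, n_trans))
    for t in range(n_trans):
        for g in range(n_genes):
            stat[g, t], pval[g, t] = signed_ks(groups[t][g], groups[t + 1][g])
        if fdr:
            pval[:, t] = multipletests(pval[:, t], method="fdr_bh")[1]
    calls = []
    for g in np.argsort(data.gene_ids):
        dirs = []
        for t in range(n_trans):
            if pval[g, t] <= alpha and stat[g, t] != 0:
                dirs.append("Up" if stat[g, t] > 0 else "Down")
            else:
                dirs.append("EE")
        calls.append(
            PathCall(str(data.gene_ids[g]), dirs, stat[g].copy(), pval[g].copy())
        )
    return calls


def paths_to_frame(calls: list[PathCall], levels) -> pd.DataFrame:
    """Tabulate path calls: one (stat, p, call) triple per transition."""
    rows = []
    for c in calls:
        row = {"gene_id": c.gene}
        for t, d in enumerate(c.directions):
            tag = f"{levels[t]}_to_{levels[t + 1]}"
            row[f"stat_{tag}"] = c.statistics[t]
            row[f"p_{tag}"] = c.pvalues[t]
            row[f"call_{tag}"] = d
        row["overall_DE"] = c.is_de
        rows.append(row)
    return pd.DataFrame(rows)
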