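"""Benchmark experiments for the package's statistical properties.

Each function sets up a self-contained simulated experiment — ordering
optimality against exhaustive enumeration, latent-order recovery, fishing
calibration and power, KS path error rates, projection self-consistency —
and returns the measured quantities. Problem sizes are desk-scale by
design; see docs/methods.md for what these simulations do and do not show.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, kstest

from .containers import ExpressionMatrix, RescaledMatrix
from .fishing import permutation_pvalues, rank_candidates
from .io_prep import filter_low_median_genes, median_by_ratio_normalize, rescale_genes
from .ks_paths import classify_paths
from .ordering import (
    CellOrder,
    aggregated_mse,
    exhaustive_oracle,
    recover_order,
)
from .simulate import SimConfig, simulate_null_genes, simulate_time_course
from .supervised_pca import fit_bulk_pca, project_cells

__all__ = [
    "ordering_optimality_rate",
    "order_recovery_taus",
    "fishing_null_pvalues",
    "fishing_power_counts",
    "kspath_error_rates",
    "pca_self_consistency_errors",
    "normalization_equivariance_errors",
    "mse_oracle_max_diff",
]


def _random_rescaled(rng, block_sizes, n_genes):
    labels = []
    for b, size in enumerate(block_sizes):
        labels += [f"T{b}"] * size
    n = len(labels)
    time = pd.Series(
        pd.Categorical(labels, categories=sorted(set(labels)), ordered=True),
        index=[f"c{j}" for j in range(n)],
    )
    genes = [f"g{i}" for i in range(n_genes)]
    return RescaledMatrix(
        values=pd.DataFrame(rng.normal(size=(n_genes, n)), index=genes,
                            columns=time.index),
        time=time,
        gene_means=pd.Series(0.0, index=genes),
        gene_sds=pd.Series(1.0, index=genes),
    )


def ordering_optimality_rate(
    n_instances: int = 50,
    block_sizes=(4, 4),
    n_genes: int = 3,
    degree: int = 2,
    seed: int = 0,
) -> float:
    """Fraction of random instances where multi-start ENI + 2-opt reaches
    the exhaustive oracle's global-minimum aggregated MSE (within 1e-9)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_instances):
        data = _random_rescaled(rng, block_sizes, n_genes)
        genes = list(data.gene_ids)
        _, oracle_mse = exhaustive_oracle(data, genes, degree=degree)
        best = recover_order(
            data, genes, degree=degree, seed=seed + i, n_restarts=5, n_iter=3000
        )
        hits += aggregated_mse(best, data, genes, degree) <= oracle_mse + 1e-9
    return hits / n_instances


def _pipeline_markers(rescaled, n_up=3, n_down=3, n_peak=2):
    up = [g for g in rescaled.gene_ids if g.endswith("_up")][:n_up]
    down = [g for g in rescaled.gene_ids if g.endswith("_down")][:n_down]
    peak = [g for g in rescaled.gene_ids if g.endswith("_peak")][:n_peak]
    return up + down + peak


def order_recovery_taus(n_seeds: int = 20, seed: int = 0, degree: int = 3) -> list:
    """Per-seed within-block |Kendall tau| (size-weighted mean over blocks)
    between the recovered and the latent order on the default course."""
    taus = []
    for s in range(n_seeds):
        cfg = SimConfig(seed=seed + s)
        matrix, truth = simulate_time_course(cfg)
        norm, _ = median_by_ratio_normalize(matrix, min_positive_fraction=0.9)
        filt, _ = filter_low_median_genes(norm)
        rescaled = rescale_genes(filt)
        markers = _pipeline_markers(rescaled)
        order = recover_order(rescaled, markers, degree=degree, seed=seed + s)
        pt = truth.pseudotime.reindex(rescaled.cell_ids).to_numpy()
        block_taus, weights = [], []
        for lv in order.time_levels:
            block = order.block(lv)
            tau, _ = kendalltau(np.arange(block.size), pt[block])
            block_taus.append(abs(tau))
            weights.append(block.size)
        taus.append(float(np.average(block_taus, weights=weights)))
    return taus


def fishing_null_pvalues(
    n_null: int = 500, n_perm: int = 2000, seed: int = 0
) -> dict:
    """Corrected p-values of null (flat) genes fished along a fixed order,
    with their KS distance from U(0,1) and the fraction at or below 0.05."""
    cfg = SimConfig(seed=seed)
    null = simulate_null_genes(cfg, n_null)
    rescaled = rescale_genes(null)
    idx = np.arange(rescaled.n_cells)
    results = permutation_pvalues(
        idx, rescaled, list(rescaled.gene_ids), n_perm=n_perm, seed=seed
    )
    p = np.array([r.p_corrected for r in results])
    return {
        "pvalues": p,
        "ks_distance": float(kstest(p, "uniform").statistic),
        "frac_le_alpha": float((p <= 0.05).mean()),
        "alpha_bound": 0.05 + 3 * float(np.sqrt(0.05 * 0.95 / p.size)),
    }


def fishing_power_counts(
    n_seeds: int = 20,
    n_planted: int = 10,
    n_null: int = 500,
    n_perm: int = 2000,
    seed: int = 0,
) -> list:
    """Per-seed count of planted up-trend genes recovered in the top-25 up
    list when fished among nulls along the latent within-block order."""
    counts = []
    for s in range(n_seeds):
        cfg = SimConfig(
            seed=seed + s, n_up=n_planted, n_down=0, n_peak=0, n_flat=n_null
        )
        matrix, truth = simulate_time_course(cfg)
        rescaled = rescale_genes(matrix)
        pt = truth.pseudotime.reindex(rescaled.cell_ids).to_numpy()
        order = []
        for lv in rescaled.time_levels:
            cells = rescaled.cells_at(lv)
            order += list(cells[np.argsort(pt[cells])])
        results = permutation_pvalues(
            np.array(order), rescaled, list(rescaled.gene_ids),
            n_perm=n_perm, seed=seed + s,
        )
        up, _ = rank_candidates(results, top_k=25)
        counts.append(sum(1 for r in up if r.gene.endswith("_up")))
    return counts


def kspath_error_rates(
    n_seeds: int = 20,
    n_null: int = 100,
    n_shift: int = 20,
    cells_per_time: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Null per-transition call rate and planted-shift sensitivity.

    Null genes come from the flat generator; shifted genes take the same
    null draws plus a 2-standard-deviation step at one randomly chosen
    transition.
    """
    null_rates, sensitivities = [], []
    for s in range(n_seeds):
        cfg = SimConfig(
            seed=seed + s, n_timepoints=4, cells_per_time=cells_per_time
        )
        matrix = simulate_null_genes(cfg, n_null + n_shift)
        vals = matrix.values.to_numpy().copy()
        rng = np.random.default_rng(seed + s + 10_000)
        codes = matrix.time.cat.codes.to_numpy()
        shift_at = rng.integers(0, cfg.n_timepoints - 1, size=n_shift)
        for i in range(n_shift):
            g = n_null + i
            sd = vals[g].std(ddof=1)
            vals[g, codes > shift_at[i]] += 2.0 * sd
        shifted = matrix.values.copy()
        shifted.iloc[:, :] = vals
        m = type(matrix)(shifted, matrix.time, unit="normalized")
        calls = {c.gene: c for c in classify_paths(m, alpha=alpha)}
        genes = list(matrix.gene_ids)
        null_calls = [
            d for g in genes[:n_null] for d in calls[g].directions if d != "EE"
        ]
        n_null_tests = n_null * (cfg.n_timepoints - 1)
        null_rates.append(len(null_calls) / n_null_tests)
        hit = sum(
            1
            for i in range(n_shift)
            if calls[genes[n_null + i]].directions[shift_at[i]] == "Up"
        )
        sensitivities.append(hit / n_shift)
    return {
        "null_call_rates": null_rates,
        "sensitivities": sensitivities,
        "alpha": alpha,
        "null_bound": alpha
        + 3 * float(np.sqrt(alpha * (1 - alpha) / (n_null * 3))),
    }


def pca_self_consistency_errors(seed: int = 0, n_components: int = 3) -> dict:
    """Bulk-projection round-trip error and the deviation of project_cells
    from a literal double-loop evaluation of the projection sum."""
    rng = np.random.default_rng(seed)
    n_genes, n_samples = 60, 6
    vals = rng.gamma(2.0, 50.0, size=(n_genes, n_samples)) + 1.0
    time = pd.Series(
        pd.Categorical([f"T{t}" for t in range(n_samples)], ordered=True),
        index=[f"s{t}" for t in range(n_samples)],
    )
    bulk = ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                     columns=time.index),
        time, unit="normalized",
    )
    model = fit_bulk_pca(bulk, n_components)
    rescaled = rescale_genes(bulk)
    proj, _ = project_cells(model, rescaled)
    round_trip = float(
        np.abs(proj.to_numpy() - model.bulk_scores.to_numpy()).max()
    )
    W = model.loadings.to_numpy()
    X = rescaled.values.to_numpy()
    expected = np.zeros((X.shape[1], n_components))
    for j in range(X.shape[1]):
        for n in range(n_components):
            for g in range(X.shape[0]):
                expected[j, n] += W[g, n] * X[g, j]
    double_loop = float(np.abs(proj.to_numpy() - expected).max())
    return {"round_trip_error": round_trip, "double_loop_error": double_loop}


def normalization_equivariance_errors(seed: int = 0) -> dict:
    """Size-factor equivariance under a planted per-cell multiplier, and
    the maximal deviation from 1 on an identical-column matrix."""
    rng = np.random.default_rng(seed)
    n_genes, n_cells = 50, 12
    vals = rng.gamma(2.0, 10.0, size=(n_genes, n_cells)) + 0.1
    mult = rng.uniform(0.5, 2.0, size=n_cells)
    time = pd.Series(
        pd.Categorical(["T0"] * n_cells, ordered=True),
        index=[f"c{j}" for j in range(n_cells)],
    )

    def make(v):
        return ExpressionMatrix(
            pd.DataFrame(v, index=[f"g{i}" for i in range(n_genes)],
                         columns=time.index),
            time,
        )

    _, sf_base = median_by_ratio_normalize(make(vals))
    _, sf_scaled = median_by_ratio_normalize(make(vals * mult))
    # the geometric-mean reference rescales with the data, so size factors
    # track the planted multipliers exactly up to one global constant
    ratio = sf_scaled.to_numpy() / sf_base.to_numpy()
    ratio = ratio / np.exp(np.mean(np.log(ratio)))
    target = mult / np.exp(np.mean(np.log(mult)))
    equivariance = float(np.abs(ratio - target).max())
    col = vals[:, :1]
    _, sf_ident = median_by_ratio_normalize(make(np.tile(col, n_cells)))
    identical = float(np.abs(sf_ident.to_numpy() - 1.0).max())
    return {"equivariance_error": equivariance, "identical_column_error": identical}


def mse_oracle_max_diff(n_instances: int = 100, seed: int = 0) -> float:
    """Max |aggregated MSE - literal normal-equations oracle| over random
    instances (also exercises the single-gene fit path)."""
    from .fishing import fit_gene_mse

    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        n = int(rng.integers(8, 40))
        degree = int(rng.integers(1, 4))
        n_genes = int(rng.integers(1, 6))
        data = _random_rescaled(rng, (n // 2, n - n // 2), n_genes)
        genes = list(data.gene_ids)
        order = CellOrder.from_data(data, np.arange(n))
        got = aggregated_mse(order, data, genes, degree)
        x = np.linspace(0.0, 1.0, n)
        X = np.column_stack([x**k for k in range(degree + 1)])
        XtX_inv = np.linalg.inv(X.T @ X)
        expected = 0.0
        for g in genes:
            y = data.values.loc[g].to_numpy()
            beta = XtX_inv @ (X.T @ y)
            expected += float((y - X @ beta) @ (y - X @ beta) / n)
        worst = max(worst, abs(got - expected))
        single = fit_gene_mse(np.arange(n), data, genes[0], degree)
        y = data.values.loc[genes[0]].to_numpy()
        beta = XtX_inv @ (X.T @ y)
        worst = max(
            worst, abs(single.mse - float((y - X @ beta) @ (y - X @ beta) / n))
        )
    return worst
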