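"""Synthetic time-course scRNA-seq with known ground truth.

Emulates the sampling design of a differentiation time course: each cell
has a latent pseudotime drawn from its collection time's window on [0, 1]
(windows of consecutive time points overlap, emulating cell-state
asynchrony at a fixed clock time), per-gene mean expression follows a
smooth profile of pseudotime on the log2 scale, counts are overdispersed
(gamma-Poisson) around the mean, and technical dropouts zero entries with
probability decreasing in the mean. Paired bulk samples are within-time
averages of independently simulated cells. Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_time_course",
    "simulate_null_genes",
    "make_paired_fixture",
]

PROFILE_CLASSES = ("up", "down", "peak", "flat")


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Defaults describe a desk-scale differentiation course: 4 collection
    times x 40 cells, 600 genes of which 30 carry trends. Trend genes
    swing ``effect_size`` log2 units across the course — the scale of
    canonical differentiation markers, which move between silent and
    highly expressed. ``dispersion`` is the gamma-Poisson overdispersion
    (variance = m + dispersion * m^2; 0 = noise-free deterministic means).
    Dropout probability for an entry with mean m is
    ``dropout_scale * exp(-dropout_decay * m)``.
    """

    n_timepoints: int = 4
    cells_per_time: int = 40
    n_up: int = 10
    n_down: int = 10
    n_peak: int = 10
    n_flat: int = 570
    effect_size: float = 6.0  # log2 units across the whole course
    base_log2_mean: float = 7.5
    base_log2_sd: float = 1.0
    dispersion: float = 0.05
    dropout_scale: float = 0.3
    dropout_decay: float = 0.15  # per unit of mean expression
    window_overlap: float = 0.25  # fraction by which adjacent windows overlap
    seed: int = 0

    def __post_init__(self):
        if self.n_timepoints < 2 or self.cells_per_time < 1:
            raise ValueError("need >= 2 time points with >= 1 cell each")
        if min(self.n_up, self.n_down, self.n_peak, self.n_flat) < 0:
            raise ValueError("gene-class counts must be non-negative")
        if self.dispersion < 0 or self.dropout_decay < 0:
            raise ValueError("rate parameters must be >= 0")
        if not (0 <= self.dropout_scale <= 1):
            raise ValueError("dropout_scale must be in [0, 1]")
        if not (0 <= self.window_overlap < 1):
            raise ValueError("window_overlap must be in [0, 1)")

    @property
    def time_labels(self) -> list:
        return [f"T{t}" for t in range(self.n_timepoints)]


@dataclass
class GroundTruth:
    """Latent state behind a simulated matrix."""

    pseudotime: pd.Series  # per cell, in [0, 1]
    gene_classes: pd.Series  # per gene, one of PROFILE_CLASSES
    gene_effects: pd.Series  # log2 amplitude per gene (0 for flat)
    gene_base_log2: pd.Series


def _windows(cfg: SimConfig) -> list:
    """Per-time pseudotime windows; centers strictly increase, adjacent
    windows overlap by cfg.window_overlap of their width."""
    T = cfg.n_timepoints
    half = (1.0 + cfg.window_overlap) / (2.0 * T)
    return [
        (
            max(0.0, (t + 0.5) / T - half),
            min(1.0, (t + 0.5) / T + half),
        )
        for t in range(T)
    ]


def _profile(klass: str, pt: np.ndarray) -> np.ndarray:
    """Centered profile shape on [0,1]; multiplied by the log2 effect size."""
    if klass == "up":
        return pt - 0.5
    if klass == "down":
        return 0.5 - pt
    if klass == "peak":
        return np.exp(-((pt - 0.5) ** 2) / (2 * 0.15**2)) - 0.5
    if klass == "flat":
        return np.zeros_like(pt)
    raise ValueError(f"unknown profile class {klass!r}")


def _gene_catalogue(cfg: SimConfig, rng: np.random.Generator):
    classes = (
        ["up"] * cfg.n_up
        + ["down"] * cfg.n_down
        + ["peak"] * cfg.n_peak
        + ["flat"] * cfg.n_flat
    )
    n = len(classes)
    names = [f"G{i:04d}_{c}" for i, c in enumerate(classes)]
    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n)
    effects = np.where(np.array(classes) == "flat", 0.0, cfg.effect_size)
    return names, classes, base, effects


def _draw_counts(
    mean: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.dispersion == 0:
        vals = mean.copy()
    else:
        lam = rng.gamma(1.0 / cfg.dispersion, mean * cfg.dispersion)
        vals = rng.poisson(lam).astype(float)
    if cfg.dropout_scale > 0:
        p_drop = cfg.dropout_scale * np.exp(-cfg.dropout_decay * mean)
        vals = np.where(rng.random(mean.shape) < p_drop, 0.0, vals)
    return vals


def simulate_time_course(cfg: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a gene-by-cell count matrix with its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    windows = _windows(cfg)
    labels, pts = [], []
    for t, (lo, hi) in enumerate(windows):
        pts.append(rng.uniform(lo, hi, size=cfg.cells_per_time))
        labels += [cfg.time_labels[t]] * cfg.cells_per_time
    pt = np.concatenate(pts)
    cell_ids = [f"C{i:04d}" for i in range(pt.size)]

    names, classes, base, effects = _gene_catalogue(cfg, rng)
    log2_mean = np.empty((len(names), pt.size))
    for g, klass in enumerate(classes):
        log2_mean[g] = base[g] + effects[g] * _profile(klass, pt)
    mean = np.exp2(log2_mean)
    values = _draw_counts(mean, cfg, rng)

    time = pd.Series(
        pd.Categorical(labels, categories=cfg.time_labels, ordered=True),
        index=cell_ids,
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=names, columns=cell_ids), time, unit="counts"
    )
    truth = GroundTruth(
        pseudotime=pd.Series(pt, index=cell_ids, name="pseudotime"),
        gene_classes=pd.Series(classes, index=names, name="class"),
        gene_effects=pd.Series(effects, index=names, name="effect"),
        gene_base_log2=pd.Series(base, index=names, name="base_log2"),
    )
    return matrix, truth


def simulate_null_genes(cfg: SimConfig, n_genes: int) -> ExpressionMatrix:
    """Matrix of flat-profile genes only, for type-I-error calibration."""
    flat_cfg = replace(cfg, n_up=0, n_down=0, n_peak=0, n_flat=n_genes)
    matrix, _ = simulate_time_course(flat_cfg)
    return matrix


def make_paired_fixture(
    cfg: SimConfig, n_bulk_per_time: int = 3, bulk_noise_sd: float = 0.05
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Matched bulk + single-cell fixture sharing one gene catalogue.

    Bulk sample r at time t is the per-gene mean of an independently
    simulated batch of cells from t's pseudotime window, times lognormal
    measurement noise. Returns (bulk, single-cell, single-cell truth).
    """
    sc_matrix, truth = simulate_time_course(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    windows = _windows(cfg)
    names = list(sc_matrix.gene_ids)
    classes = truth.gene_classes.to_numpy()
    base = truth.gene_base_log2.to_numpy()
    effects = truth.gene_effects.to_numpy()

    cols, labels = {}, []
    for t, (lo, hi) in enumerate(windows):
        for r in range(n_bulk_per_time):
            pt = rng.uniform(lo, hi, size=cfg.cells_per_time)
            log2_mean = np.empty((len(names), pt.size))
            for g, klass in enumerate(classes):
                log2_mean[g] = base[g] + effects[g] * _profile(klass, pt)
            cells = _draw_counts(np.exp2(log2_mean), cfg, rng)
            noise = np.exp(rng.normal(0.0, bulk_noise_sd, size=len(names)))
            name = f"{cfg.time_labels[t]}_rep{r + 1}"
            cols[name] = cells.mean(axis=1) * noise
            labels.append(cfg.time_labels[t])
    bulk_df = pd.DataFrame(cols, index=names)
    bulk_time = pd.Series(
        pd.Categorical(labels, categories=cfg.time_labels, ordered=True),
        index=bulk_df.columns,
    )
    bulk = ExpressionMatrix(bulk_df, bulk_time, unit="counts")
    return bulk, sc_matrix, truth
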