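# Methods

## Cell ordering model

The ordering stage assumes that along the true differentiation trajectory
a small set of marker genes varies smoothly, and that collection times are
coarsely informative: a cell collected at 24 h is never placed after a
cell collected at 36 h, but within a collection time any order is
admissible. An order is therefore a permutation of cells partitioned into
contiguous time blocks, and the objective is the aggregated MSE: for each
marker gene, standardized expression is regressed on rank position by
ordinary least squares with a polynomial basis, and the per-gene mean
squared residuals are summed. Smoothness, not monotonicity, is rewarded:
peaked markers are handled by the same objective.

Two deliberate conventions:

- **Regression abscissa.** Rank positions are mapped to equally spaced
  points on [0, 1]. The order itself carries no spacing information, so
  equal spacing is the only defensible choice; it also makes the design
  matrix depend solely on (n, degree), which lets the implementation cache
  one orthonormal basis per size and evaluate a candidate order with a
  single thin matrix product (residual sum of squares = ‖y‖² − ‖Qᵀy‖²).
- **Polynomial degree.** Default 3, configurable 1–5. Marker profiles in a
  several-day course fall, peak, or rise; a cubic is the lowest degree
  accommodating all three shapes. Degree is capped at n − 2 during the
  earliest ENI insertions so the fit stays overdetermined.

### Search

ENI seeds the order with one random cell per time point (in time order),
then inserts the remaining cells in random sequence, each into the
admissible slot — every position within its own time block, including the
block edges — minimizing the aggregated MSE, ties to the earliest slot.
2-opt refinement proposes random segment reversals with both endpoints in
one block (a swap mode exists behind a flag) and accepts only strict
improvements, stopping after 20,000 proposals or 2,000 consecutive
rejections. Acceptance-by-strict-decrease makes the MSE trace strictly
decreasing, so the search cannot cycle.

Both stages are randomized, and on small instances a single run reaches
the enumerated global optimum only ~55–70% of the time. The pipeline entry
point `recover_order` therefore runs 5 independent restarts
(construction + refinement) and keeps the lowest-MSE order, which raises
the hit rate above 95% on 2-block × 4-cell instances while leaving each
primitive's contract unchanged. All randomness flows from
`numpy.random.default_rng(seed)`; identical seeds give bit-identical
orders.

An exhaustive oracle (`exhaustive_oracle`) enumerates all admissible
orders (product of within-block permutations, refused above 10⁶ orders)
and is used only as an independent optimality reference in tests.

Orders are identified only up to reversal symmetry — reversing the whole
order maps positions x → 1 − x, under which the polynomial family is
closed — so recovery is always scored with |Kendall tau|.

## Fishing

Along a recovered order (or one time block of it), each candidate gene is
summarized by the MSE of its polynomial fit; small MSE means a smooth
trend. The null distribution is built by repeatedly drawing a gene
uniformly from the universe under consideration, permuting its cell order
uniformly, and refitting — so the null captures both the universe's MSE
composition and the destruction of order association. The p-value is the
fraction of null MSEs at or below the observed MSE. This literal estimator
can return exactly 0, so the standard (k+1)/(n+1) corrected p-value is
reported alongside; the two differ by at most 1/n_perm. By default one
null pool of 100,000 draws is shared by all candidates (a per-candidate
mode exists); the default universe is every gene in the filtered matrix.

Direction is the sign of a separate linear fit's slope; slopes within
1e-12 (relative to the data scale) of zero are classified "up" with an
explicit flag — an arbitrary but deterministic rule for a measure-zero
case. Ranking within each direction is by ascending MSE, with the literal
p-value and then the gene ID as tie-breakers.

## Bulk-supervised PCA

PCA fitted directly on single-cell matrices tends to align with technical
noise, so component axes are learned from matched bulk RNA-seq: genes are
standardized across bulk samples (log2(x+1) first, by default), the
loading matrix W comes from an SVD of the samples × genes matrix, and each
standardized single cell j is scored as Σ_g W_gⁿ X̃_gʲ over the gene
intersection. Cells are standardized with their own per-gene statistics,
not the bulk's, mirroring the separate definitions of the two rescaled
matrices. Sign ambiguity is fixed by making each component's
largest-magnitude loading positive. At most min(#samples − 1, #genes)
components are admissible. Absolute loadings are exportable as per-gene
weights for downstream enrichment tools (the enrichment itself is out of
scope). Genes absent from either side are dropped and reported, never
imputed.

## KS path calls

For each gene and each adjacent pair of collection times, a two-sample
Kolmogorov–Smirnov test compares the expression distributions. The signed
statistic carries the magnitude of the usual KS distance and the sign of
the dominant one-sided statistic — positive when the later condition is
stochastically larger (Up) — and is exactly antisymmetric in its
arguments; a tie between the one-sided statistics yields 0. P-values are
the asymptotic two-sample KS p-values, Benjamini–Hochberg adjusted across
genes within each transition by default. A transition is Up/Down if its
(adjusted) p ≤ α, else EE; a gene is differentially expressed iff any
transition is non-EE. This is a thresholded, test-based path caller: it
deliberately does not model posterior probabilities over whole paths, and
dropout zeros are left in the compared samples (a flag can exclude them).

## Preprocessing

- QC: cells with fewer than 5000 genes at TPM > 1 are removed (boundary
  inclusive: exactly 5000 detected genes is retained).
- Normalization: median-of-ratios size factors, reference genes = genes
  positive in every cell (classical rule; relaxable to a positive-fraction
  threshold for sparse data). Size factors are defined up to one global
  constant because the per-gene geometric-mean reference rescales with the
  data; the exact invariant is that factor ratios track per-cell
  multipliers.
- Gene filter: genes with median normalized expression below 10 are
  dropped (a gene at exactly 10 is retained).
- Standardization: per-gene mean 0, unit sample variance (n − 1
  denominator, which makes the row (1, 2, 3) map exactly to (−1, 0, 1));
  log2(x+1) first by default, since marker profiles are conventionally
  examined on that scale — a flag disables it because the ordering could
  equally run on the raw normalized scale. Zero-variance genes are dropped
  and listed rather than zero-filled, since a constant row contributes
  nothing to the MSE objective but would inflate gene counts.

## Synthetic data

The generator emulates an asynchronous differentiation course. Each cell's
latent pseudotime is uniform on its collection time's window on [0, 1];
adjacent windows overlap by 25% of their width, so clock time bounds but
does not determine progression state. Per-gene mean expression follows a
profile on the log2 scale — linear up, linear down, Gaussian peak
(σ = 0.15), or flat — with amplitude `effect_size`; counts are
gamma-Poisson with variance m + φm² (φ = `dispersion`; φ = 0 yields
noise-free deterministic means, useful for degenerate-case tests); dropout
zeroes an entry with probability `dropout_scale · exp(−dropout_decay · m)`.
Bulk samples are per-gene means of independently simulated cell batches
times lognormal measurement noise (σ = 0.05), sharing the gene catalogue
with the single-cell matrix.

Default conditions: 4 time points × 40 cells, 600 genes (10 up, 10 down,
10 peaked, 570 flat). The noise defaults describe the *marker-gene
regime* — the well-expressed genes that survive the median ≥ 10 filter and
that one would actually order on: baseline log2 mean 7.5 ± 1 (~180
normalized counts), trend amplitude 6 log2 units (canonical
differentiation markers swing between near-silence and high expression),
dispersion 0.05, and dropout concentrated on lowly expressed entries
(scale 0.3, decay 0.15 per count unit, i.e. negligible above ~30 counts).
In this regime the latent order is recoverable to within-block
|Kendall tau| ≈ 0.8; at substantially higher dispersion or with heavy
dropout on the markers themselves, the aggregated-MSE optimum itself drifts
from the latent order (verified by comparing recovered orders against
truth-sorted orders), so passing recovery tests speak to this regime and
not to ordering on dropout-dominated, lowly expressed genes. Other known
gaps to real data: no library-size variation between cells (size factors
are ≈ 1 by construction, which is why normalization is tested separately
with planted multipliers), no batch or capture-position effects, no
gene–gene correlation beyond the shared pseudotime, and independent
dropout rather than zero-inflation correlated within cells.

## Problem sizes and numerics

Benchmark experiments (`wavecrest._evaluation`, reused by
`scripts/acceptance.py` and the end-to-end tests) run at desk scale:
50 instances of 2 blocks × 4 cells for optimality-vs-enumeration, 20 seeds
of the default 4 × 40 course for recovery, 500 null genes × 2000
permutations for calibration, 20 seeds of 4 × 50 cells for KS error rates.
Least squares is solved via QR (cached orthonormal bases) or
`numpy.linalg.lstsq`; agreement with literal normal equations is at the
1e-15 level, asserted at 1e-9. Tiny negative residual norms from rounding
on exact fits are clamped to zero. Ties in ENI insertion resolve to the
earliest slot; candidate enumeration order in the exhaustive oracle is
lexicographic, and the first argmin wins.

## Limitations

- The ordering is directional and linear: no branching structure is
  inferred, and a marker set mixing two lineages will produce a compromise
  order.
- Marker choice is supervised; the method does not discover markers.
- The permutation p-value inherits the universe's composition: if the
  universe itself is enriched for trending genes, p-values are
  conservative.
- The KS path caller treats transitions independently and reports
  test-based calls, not path posteriors.
- FACS-derived Differentiation Scores are computed from user-supplied
  percentages; the package does not model the underlying cytometry.
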