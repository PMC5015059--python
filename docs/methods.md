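# Methods

## The expressing-cell-count statistic

For gene *g* in a genes × cells FPKM matrix, `N(g)` is the number of
cells with FPKM strictly greater than the positivity threshold
(default 3 FPKM). The strict inequality matters at the boundary: a cell
at exactly 3 FPKM is not positive. `N` is kept on the raw integer scale —
it is not normalised by the number of cells — so fits are per dataset;
cross-dataset statements are made on flag fractions, not raw `N`.

Only genes whose maximum FPKM over cells lies in the moderate window are
analysed for heterogeneity. The window is interpreted as
`max_fpkm ∈ (window_low, window_high]`, default `(3, 30]`: the lower
bound is strict for consistency with positivity, and the upper boundary
is inclusive because exclusion is defined by exceeding 30 FPKM in at
least one cell. Both bounds are configurable; the upper-boundary
convention is a package choice and is documented here because genes at
exactly 30 FPKM switch strata under the alternative reading.

## The two-component mixture and H/L/U flags

Pooled over all windowed genes (both biotypes together — the per-biotype
fit exists behind `per_biotype_fit=True` but is not the default, since
the two-population structure is a property of the joint `N`
distribution), the `N` values are fitted with a two-component univariate
Gaussian mixture by EM.

Numerical choices:

* **Initialisation.** Weights (0.5, 0.5) and standard deviations
  (0.5, 0.5). Means default to the 25th/75th percentiles of the data —
  a deterministic start, so reruns are byte-identical; `init="random"`
  draws two distinct data values instead (seeded) for multi-restart
  checks. The reference EM routine this mirrors draws its means
  stochastically; the quartile default trades that fidelity for
  reproducibility.
* **E/M steps** use log-space densities with `logsumexp`; the
  log-likelihood is recorded every iteration and is non-decreasing (a
  property the tests assert on every run).
* **Convergence**: relative |Δ log-likelihood| < 1e−8, at most 1000
  iterations (typical fits converge in < 10).
* **Degeneracy guards**: fewer than 10 points or fewer than 2 distinct
  values is an error; a component variance falling below 1e−6 or an
  effective component count below 1 raises a non-convergence error
  rather than returning a spike solution.
* **Identifiability**: components are relabelled so μ₁ ≤ μ₂; component 1
  (few expressing cells) is the high-heterogeneity population.

A gene with `N = n` gets the posterior
`P(high | n) = λ₁φ(n;μ₁,σ₁) / [λ₁φ(n;μ₁,σ₁) + λ₂φ(n;μ₂,σ₂)]` and flag
**H** if the posterior exceeds 0.99, **L** if its complement does
(`1 − p > 0.99`, evaluated in exactly that form so the two boundaries
are symmetric in floating point), **U** otherwise. Fraction summaries
report H/L/U per biotype among the *windowed* genes; note that a
fraction "of all expressed genes" (including the >30 FPKM stratum in
the denominator) is a different, larger-denominator convention.

## Coefficient of variation and Welch comparisons

CV is computed across **all** cells, zeros included, as sample SD
(n−1 denominator) over mean. Including zeros is deliberate: dropout is
part of the heterogeneity signal, and excluding zero cells would make
CV a deterministic function of the positive cells only. The n−1
convention gives the exact identity CV = √C for a gene expressed in one
of C cells at any level, which the tests exploit; `ddof=0` is available.

Expressed genes (max > 3 FPKM) are stratified into moderate
(max ≤ 30) and high (max > 30) strata, and the four biotype × stratum
groups are compared with two-sided Welch t-tests (unequal variances,
Welch–Satterthwaite degrees of freedom; implementation delegates to
scipy, tests pin it to textbook arithmetic and an independent R
evaluation). No multiple-testing correction is applied to the 6 pairwise
p-values; they are reported raw. Box-plot summaries use 1.5×IQR
whiskers clamped to the most extreme point inside the fence.

## Quantification conventions

Gene length is the union-exon length: bases covered by ≥1 exon of ≥1
isoform, counted once. FPKM = reads × 10⁹ / (union length × library
size). Internally all intervals are 0-based half-open; GTF's 1-based
inclusive coordinates are converted at the parsing boundary only.

Biotype rules: RefSeq prefixes NM_/XM_/NP_/XP_ → coding; NR_/XR_ or a
lincRNA annotation → noncoding; genes carrying both kinds of transcript
resolve to coding; everything else is excluded rather than guessed.
A noncoding-evidenced gene whose union exons overlap, on the same
strand, the union exons of a coding-evidenced gene is reclassified
coding (possible read-through), with the partner gene recorded in the
audit string — the annotation itself does not say how read-through
should be detected, and same-strand exonic overlap is the conservative
operationalisation chosen here. The comparison set keeps only genes
with union length strictly greater than 200 nt.

For a gene overlapped by an opposite-strand gene in non-strand-specific
libraries, expression is an interval: the under-estimate uses reads in
the target-exclusive exonic region, the over-estimate adds all reads in
the shared exonic region. Both divide by the full target union length,
so "under" is a true lower bound under the fixed gene model (the
alternative — dividing the exclusive count by the exclusive length — is
not a bound in either direction). Read-to-region assignment is the
caller's job; the package computes and exports the region geometry
(BED) and turns (exclusive, ambiguous) counts into bounds. Only exonic
intersections count as ambiguous; intronic overlap does not.

## Longest ORF and its chance model

An ORF is ATG…in-frame-stop on the sense strand, length counted through
the stop codon inclusive (so lengths are multiples of 3, minimum 6; the
stop-excluded convention is available via `orf_length(...,
include_stop=False)`). Codons containing N never match ATG or a stop.
Ties go to the smallest start. The chance model draws replicate
sequences i.i.d. from a base composition (default: the observed
mononucleotide frequencies) and reports the add-one-corrected empirical
p-value `(1 + #{replicates ≥ observed}) / (reps + 1)`; a
dinucleotide-preserving Altschul–Erickson shuffle of a reference
sequence is the alternative null for composition-sensitive questions.

## What the generator emulates — and what it does not

`SimulationSpec` plants, per gene: a biotype, a stratum (moderate
window vs >30 FPKM; fraction `frac_high_expr`), a heterogeneity class
for moderate genes (high with probability `p_high_lnc` = 0.74 /
`p_high_mrna` = 0.35 by default), an expressing-cell count `N` from the
class distribution, the identity of the positive cells (uniform without
replacement), and positive-cell magnitudes from a log-normal truncated
to the stratum's FPKM range; all other cells are exact zeros (optionally
sub-threshold uniform(0, 3) noise, which stresses the strict threshold
without changing any `N`). Defaults: 96 cells, 2000 genes per biotype,
high-heterogeneity class `N ~ Normal(6, 3)` and low-heterogeneity
`N ~ Normal(55, 12)` (rounded, clamped to [1, n_cells]) — a
well-separated regime in which the Gaussian-mixture model is correctly
specified; a negative-binomial `N` mode exists to probe robustness to
skew. High-stratum genes get biotype-shifted `N` distributions
(lncRNA Normal(35, 8), mRNA Normal(75, 10)) reflecting that abundant
genes drop out less, which gives the four CV groups the expected
ordering. A spec whose class distribution would land outside
[1, n_cells] in more than half of draws is rejected.

What this does **not** emulate: empirical single-cell count noise
(no Poisson/NB sampling of the magnitudes), amplification artefacts,
cell-size or library-size variation, correlated gene modules, or any
coupling between expression level and dropout beyond the stratum shift.
Passing recovery tests therefore demonstrates that the pipeline's
inference is correct *under its own model assumptions* — not that real
datasets satisfy those assumptions.

## Problem sizes

The test suite and acceptance script run the full pipeline at 96 cells ×
4000 genes, mixture recovery at n = 2000 over 20 seeds, EM-vs-grid
checks at n = 40, the ORF scan oracle on 1000 sequences up to 5 kb, and
1000-replicate null calibrations — sizes at which every check completes
in seconds while estimates (binomial SE of a fraction at n = 2000 is
about 1 percentage point) sit well inside the asserted tolerances.

## Known limitations

* The mixture is Gaussian on a bounded integer statistic; with extreme
  class means near 1 or n_cells the normal tails are truncated by
  clamping and the fit is mis-specified (the negbin mode exposes this).
* Biotype rules cover RefSeq prefixes plus the lincRNA label only; other
  annotation vocabularies fall into "excluded".
* The under/over bounds assume exactly one overlapping antisense gene;
  nested multi-gene loci need the partition computed against the union
  of partners.
* The CLI reads whole matrices into memory; at single-cell atlas scale
  (10⁵+ cells) a chunked backend would be needed.
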