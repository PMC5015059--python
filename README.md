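# hetflag

Classify per-gene cell-to-cell expression heterogeneity in single-cell
RNA-seq, and compare it between long non-coding RNAs (lncRNAs) and mRNAs.

## The problem

lncRNAs show low *population-level* expression compared to mRNAs. One
explanation is that a lncRNA is not weakly expressed in every cell, but
strongly expressed in only a few cells of an otherwise homogeneous
population. Bulk RNA-seq cannot distinguish these cases; single-cell
RNA-seq can. `hetflag` implements the statistical machinery to make that
distinction systematically, per gene, across a genes × cells FPKM matrix.

## The statistic and the model

For each gene, count the number of cells *N* in which it is expressed —
FPKM strictly greater than a positivity threshold (default **3 FPKM**).
Restricted to genes whose maximum expression across cells lies in a
moderate window (default **3–30 FPKM**; lower bound strict, upper
inclusive — genes above 30 FPKM in any cell are set aside), the pooled
distribution of *N* over all genes is bimodal. `hetflag` fits it with a
two-component univariate Gaussian mixture by EM:

    p(n) = λ₁ φ(n; μ₁, σ₁) + λ₂ φ(n; μ₂, σ₂),   μ₁ ≤ μ₂

starting from λ = (0.5, 0.5) and σ = (0.5, 0.5), with means initialised
at the 25th/75th percentiles of the data (deterministic default) or at
random data points (`--init random`). Component 1, the smaller-mean
component, is the **high-heterogeneity** population: genes expressed in
few cells. Each gene is then flagged by its posterior probability of
component membership at cutoff 0.99 (strict):

* **H** — high heterogeneity (posterior of component 1 > 0.99),
* **L** — low heterogeneity (posterior of component 2 > 0.99),
* **U** — uncertain otherwise.

Around this core the package provides: union-exon gene lengths and FPKM
(reads × 10⁹ / (length × library size)) from a GTF; RefSeq-prefix biotype
rules (NM_/XM_/NP_/XP_ → coding, NR_/XR_/lincRNA → noncoding, with a
same-strand exonic-overlap read-through reclassification and a strict
>200 nt length filter); per-gene coefficient-of-variation comparisons
across biotype × expression strata with Welch's t-tests; under/over FPKM
bounds for genes overlapped by an opposite-strand gene in unstranded
data; a longest-ORF scanner with a Monte-Carlo chance model; and a
synthetic-data generator with planted ground truth that makes all of the
above testable end to end.

## Worked example

Simulate a 96-cell dataset (400 genes per biotype, a quarter of them in
the >30 FPKM stratum, planted high-heterogeneity fractions 0.74 for
lncRNAs and 0.35 for mRNAs) and run the whole pipeline:

```sh
hetflag run --config config.yaml
```

with `config.yaml`:

```yaml
simulate: {n_lnc: 400, n_mrna: 400, frac_high_expr: 0.25}
out: demo
seed: 11
```

`demo/summary.txt` then reads:

```
H/L/U fractions per biotype:
     coding: H 38.9%  L 60.4%  U 0.6%  (low-or-uncertain 61.1%, n=316)
  noncoding: H 75.0%  L 24.7%  U 0.3%  (low-or-uncertain 25.0%, n=292)

CV group comparisons (Welch, two-sided):
  mRNA-high vs lncRNA-high: t=-18.8 p=2.69e-42
  ...
  mRNA-moderate vs lncRNA-moderate: t=-7.3 p=9.02e-13
```

75.0% of the analyzable lncRNAs but only 38.9% of the mRNAs are flagged
H — the planted 0.74/0.35 fractions recovered from the matrix alone —
and within each expression stratum lncRNA CVs significantly exceed mRNA
CVs. `demo/model.txt` shows the fitted mixture (here μ ≈ (5.9, 55.8)
cells, recovering the generator's two N populations), and
`demo/records.tsv` holds the per-gene N, posterior and flag:

```
gene_id     biotype    n_expressing  max_fpkm  posterior_high  flag
lnc_00001   noncoding  46            27.0315   2.12946e-41     L
lnc_00002   noncoding  4             19.9058   0.999984        H
```

Each stage is also available directly (`hetflag simulate / annotate /
fpkm / classify / cv / bounds / orf`); see `hetflag <cmd> --help`.

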