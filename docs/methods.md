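# Methods

## Module discovery

The discovery pipeline treats a large, uniformly processed cohort as a
"gold standard" whose correlation structure defines the modules.

**Correlation.** All correlations in the package are Spearman. Ranks are
assigned per gene with average-rank tie handling; the correlation matrix
is the Pearson correlation of standardized rank rows, computed as a
blocked matrix product (`block_size` rows at a time) so the G × G result
is the only genome-scale allocation; a 20k-gene matrix needs ~3.2 GB and
no per-pair intermediates. Genes with zero rank variance (constant
profiles) cannot be correlated: their rows are zeroed, their diagonal is
set to 0, and they are reported in `zero_variance`. An optional prefilter
(`prefilter_quantile`) drops the bottom quantile of genes by mean
expression before this stage, since genes with low absolute expression
correlate poorly with everything and only add junk modules.

**Sparsification.** Per row, the k = ⌈keep_fraction·(G−1)⌉ highest signed
correlations are retained and everything else is zeroed. Design choices:

- Signed ρ, not |ρ|: a gene's neighbourhood is the genes it rises with;
  anticorrelated genes are deliberately excluded from it.
- Ceiling rounding, so every gene keeps at least one neighbour.
- Ties at the k-th value break by lexicographic gene id, making the result
  deterministic.
- The matrix is *not* re-symmetrized. Each row is that gene's
  neighbourhood profile — the object that is clustered — and per-row
  thresholding is the point of the construction.
- Zero-variance genes keep all-zero rows (diagonal 0), which routes them
  to the reserved unclustered module downstream.

**Clustering.** Genes are clustered on d(i,j) = 1 − r(rowᵢ, rowⱼ), the
correlation distance between sparsified neighbourhood rows, with average
linkage, and the dendrogram is cut at height h (default 0.8 on the [0, 2]
correlation-distance scale). Both the distance and the linkage are
configurable; these defaults are the conventional co-expression choices
compatible with that cut height. Labels are renumbered 1..M by decreasing
size (ties by the lexicographically smallest member), with 0 reserved for
unclustered/degenerate genes. Modules below `min_report_size` (default 25
genes) stay in the assignment but are excluded from module-level reports:
on realistic inputs the sub-25-gene tail is dominated by noise
agglomerates.

**Rejected baseline.** `baseline_modules` clusters raw (logged) expression
rows directly — Euclidean distance by default, i.e. what naive
`dist` + `hclust` defaults give — cut to a matched module count. It exists
only to keep the motivating comparison under regression test: it mixes
expression level into the distance and recovers planted modules far worse
(ARI ≈ 0.5 vs ≈ 1.0 under the default synthetic design). A
correlation-distance variant is available via `metric="correlation"`.

## Collapsed module scores

A module's collapsed score starts from all members and alternates
(1) score = per-sample median of retained members' centered values,
(2) retained = members with Spearman ρ(gene, score) strictly > `r_keep`
(default 0.6), until the retained set repeats. Numerical contract:

- The fixed point is exact retained-set equality, not a tolerance.
- Retained sets can oscillate in principle, so all visited sets are
  remembered; revisiting one terminates with `converged=False`.
- The initial retained set is all members.
- If an iteration would empty the retained set, the score falls back to
  the plain median over all members with `converged=False`. This keeps the
  transfer use case total: modules that do not cohere in a foreign dataset
  still get a (flagged) score.
- The procedure is invariant to sample order and to member order; with
  `max_iter=50` every planted-module scenario in the test suite converges
  in ≤ 3 iterations.

The gene × module Spearman table (`gene_module_correlation`) supports
spotting genes that track several modules; each gene's own module and its
ρ to it are dedicated columns.

## Module transfer and probe filtering

Transfer restricts each module to genes the foreign platform measures
(coverage is reported; < 20% warns, zero errors), median-centers the
foreign data, re-collapses, and reports each member gene's ρ to its own
collapsed score plus per-module averages. When a reference cohort is
supplied, its per-module averages are recomputed **on the gene subset
shared with the foreign platform**, so the side-by-side comparison is like
for like; a consequence is that self-transfer reproduces the reference
values exactly.

Probe intensity is operationalized as the mean linear-scale value across
samples (it is the practical predictor of poor probe coherence on arrays).
`filter_probes` removes probes below the cutoff — default 50, a
platform-level optimum meant to be checked against the returned
intensity-versus-ρ diagnostic table rather than trusted blindly — and
warns if a cutoff removes more than 90% of probes. No automated cutoff
search is attempted.

## Barcodes, subtypes, and cross-dataset analyses

**Discretization.** Score rows are standardized with a robust z,
(x − median)/(1.4826·MAD), so levels are invariant to affine rescaling of
a row; HI if z ≥ z_hi, LO if z ≤ −z_hi, else MID. Zero-MAD rows are all
MID and flagged. The default z_hi = 0.5 is a display threshold: it splits
a roughly Gaussian score row into ≈ 31/38/31% LO/MID/HI, which is what one
wants in a barcode heatmap. **Subtype calling is different**: the
unique-HI rule ("the sample's one HI module names its subtype") needs
confident HI calls, and since ~31% of any Gaussian row sits above z = 0.5,
that threshold would tag spurious HI modules in most samples. The shipped
rule example and the tests therefore call subtypes at z_hi = 2.0, where
the spurious-HI rate per module is a fraction of a percent. Both numbers
are exposed as parameters.

**Median split** partitions samples at a module score's median with ties
going to the low group (deterministic); constant rows put every sample in
the low group with a warning. The groups are emitted for external survival
tooling; no survival model is fitted here.

**NMF subtyping** shifts the score matrix to non-negative by subtracting
its global minimum and factorizes samples × modules at rank k with 20
random restarts (seed-controlled), keeping the lowest reconstruction
error; a sample's cluster is the argmax of its factor row. Concordance
against reference labels uses optimal one-to-one Hungarian matching, which
bounds any fixed label mapping from below.

**Average rank** ranks genes ascending within each sample (average ties)
and averages across samples — a non-parametric aggregate invariant to any
monotone within-sample transform, suitable for combining fold-changes
across heterogeneous datasets.

**Core members** of a concept (e.g. cell cycle) across C module sets are
the genes belonging to the mapped module in ≥ T sets; T is explicit
because the right stringency depends on how many datasets genuinely carry
the concept. **Module conservation** across datasets is scored by the
pairwise Jaccard index of module gene sets, clustered with average linkage
on 1 − Jaccard (cut 0.8). This is a deliberate, self-contained stand-in
for external cluster-of-clusters consensus tooling; the Jaccard matrix is
part of the result so users can feed it to such tools themselves.

## Synthetic data

The generator emulates exactly the structure the discovery stages assume.
Per module j with nⱼ genes, a latent factor Fⱼ ~ N(0, 1) per sample (or a
correlated multivariate normal when `factor_corr` plants module–module
correlation); gene g gets log2 value bg + ag·Fⱼ + ε, ε ~ N(0, σ), with
base means bg ~ U(6, 10) (linear means ≫ 50), loadings ag ~ U(0.8, 1.2),
and σ_lo = 0.35 — giving within-module gene–gene Spearman ≈ 0.85–0.92, a
well-measured cohort. Background genes are independent N(0, 1) noise
around their base mean; low-expression genes have base means U(0.5, 2)
and σ = 1, the low-abundance/high-relative-noise tail. Values are
exponentiated to a linear TPM-like scale, so logging recovers the latent
model and every rank-based stage sees the planted monotone structure.
Defaults: modules 40/30/30, 60 samples, 40 background, 10 low-expression
genes; all draws flow from one `numpy` generator seeded by `seed`, making
cohorts bit-reproducible.

Degradation modes: `ffpe_noise` multiplies values by 2^N(0, σ_hi)
(default σ_hi = 1.2), the heavy log-normal noise of degraded RNA;
`microarray_lowintensity` inflates a designated probe subset's noise and
rescales each probe so its mean linear intensity equals a target (20 by
default) — below the 50 cutoff by construction.

What the generator does **not** model: library-size and GC biases, batch
effects, discrete counts at low abundance, single-cell dropout beyond the
noise tiers, non-linear gene–gene dependence, and hierarchically nested
modules. Passing recovery tests therefore show the pipeline is correct and
well-behaved under its own assumptions (block-correlated, monotone,
log-normal data), not that real cohorts will yield modules of any
particular quality.

Planted-module recovery is scored by the adjusted Rand index computed on
planted genes only (truth id > 0): background and low-expression genes are
generated as unassigned noise, and the ≥ 25-gene reporting floor already
excludes the small junk modules they form.

## Other numerical and I/O choices

- TPM-like linear data is logged as log2(x + pseudo), pseudo = 1 by
  default (configurable); Spearman stages are unaffected by the choice,
  which matters only for centered fold-change displays.
- Median centering is the default (means are also stored and mean
  centering is available); duplicate gene ids on read collapse to the
  highest-average row, favouring the better-measured probe/transcript.
- TSV I/O writes floats at 17 significant digits and parses them with
  correctly-rounded conversion, so write → read is bit-exact.
- Workbook export paints centered values on a blue–white–red ramp over
  ±2 log2 fold-change (0 = white) with a per-module colour column; cell
  values are stored as numbers, serialized by the spreadsheet layer at 16
  significant digits (the XLSX numeric-text convention), which is the
  round-trip precision of that format. Oversize matrices are
  gene-downsampled to a cell budget with a warning.
- GMT output is strictly tab-delimited, ≥ 3 fields per line, one geneset
  per module at or above the reporting floor.
- CLI runs write a `provenance.yaml` (resolved parameters, no timestamps)
  next to their outputs; identical config + seed reproduces every output
  file byte for byte.

## Known limitations

- The cut height, keep fraction, and r_keep defaults are sensible for
  TCGA-scale cohorts but interact: small cohorts (< ~50 samples) produce
  noisier correlations and may need a lower keep fraction or higher cut.
- The sparsified matrix is dense G × G; ~20k genes is workstation
  feasible, far beyond that is not the target regime.
- One gene, one module: genes genuinely shared by programs surface only
  post hoc through the gene × module correlation table.
- No eigengene/PCA summarization, no soft membership, no batch
  correction, no survival statistics — deliberately out of scope.
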