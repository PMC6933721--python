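# Methods

This note documents the statistical models, the synthetic study the tests
run on, the numerical choices, and the limitations of `epihub`.

## Methylation preprocessing

Beta values (the methylation fraction at a CpG) are heteroscedastic near 0
and 1; statistics are therefore run on M-values, M = log2(β / (1 − β)).
Betas are clipped to [ε, 1 − ε] with **ε = 1e−6** before the transform so
fully (un)methylated probes map to large finite M (≈ ±19.93) instead of
±∞, preserving strict monotonicity.

Missingness filtering drops probes with more than 20% missing samples
first, then samples with more than 20% missing values *on the surviving
probes*. The order matters on edge cases (a sample can be rescued by the
removal of a badly missing probe) and is fixed: probes first.

k-nearest-probe imputation replaces each missing cell (i, s) by the mean
over the **k = 10** nearest probes that are observed in sample s. Probe
distance is the Euclidean distance over samples observed in both probes
(pairwise-complete); ties break by row order, so the procedure is
deterministic, and observed entries are never touched. A probe missing
everywhere is an error (impossible after the missingness filter).

Blacklist removal drops probes on chrX/chrY or flagged as SNP-overlapping
or cross-hybridising. Promoter restriction keeps the Illumina region
classes {TSS1500, TSS200, 5′UTR, 1stExon}; these two filters commute.

## Expression preprocessing

Probe-level matrices are de-duplicated (first member of each known
replicate group survives), quantile-normalised (each sample's order
statistics replaced by the across-sample mean of order statistics; ties
share their mean rank value; the operation is idempotent), and collapsed
to genes by the per-gene median over probes. Probes annotated to zero or
to multiple genes are discarded before the collapse. Background
correction of raw array intensities is out of scope: input is assumed to
be log2 scale already, and the synthetic generator emits normalised
gene-level data directly, so quantile normalisation is a structural no-op
on the synthetic pipeline.

## Differential expression

Per gene, an ordinary two-group fit gives the log2 fold-change
Δ = mean(GDM) − mean(control) and pooled residual variance s² on
d = n₁ + n₂ − 2 degrees of freedom. Under the hierarchical model
σ²_g ~ scaled-inverse-χ²(d₀, s₀²), the posterior variance is
s̃² = (d₀s₀² + d·s²)/(d₀ + d) and t̃ = Δ / (s̃·√(1/n₁ + 1/n₂)) follows a t
distribution with d₀ + d degrees of freedom. (d₀, s₀²) are estimated by
moment matching on e_g = log s²_g − ψ(d/2) + log(d/2): the excess of
Var(e) over ψ′(d/2) determines d₀ through the trigamma equation
ψ′(d₀/2) = Var(e) − ψ′(d/2), solved by monotone bisection on a log grid
to |Δ| < 1e−8. Genes with s² = 0 are excluded from the moment fit. When
the excess is non-positive the prior is degenerate: d₀ = +∞, s̃² = s₀² =
mean(s²), and the reference distribution is normal. The implementation is
cross-checked against the Bioconductor `limma` package on a fixture in the
test suite.

The DEG call is **raw p < 0.05** with no multiple-testing correction —
that is the screen this pipeline implements; q-values are reported only in
the enrichment stage. Direction labels are `up_in_GDM` (Δ > 0) and
`up_in_control`.

## Enrichment

Over-representation p-values are the hypergeometric upper tail
p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n), accumulated in log space (gammaln +
logsumexp) for numerical safety; the test suite verifies agreement with
exact rational enumeration to 1e−12 on every configuration with N ≤ 30.
The universe is the post-collapse expression gene set — the genes the
screen could have selected — since ORA is only interpretable against the
tested universe. Benjamini–Hochberg q-values are computed within each
category (BP/CC/MF/pathway); selection uses raw p < 0.05 to match the
screen's declared threshold.

## Pathway network

KGML documents are reduced to undirected simple graphs: gene entries
expand to all listed aliases, group entries to the union of their members,
and each relation contributes the Cartesian product of the two expansions
(self-loops dropped). Relation orientation and subtype are discarded from
the topology — the downstream centralities are undirected — but subtype
and source pathway are kept as edge attributes, and merging accumulates
provenance. All relation subtypes produce edges by default (the
alternative, subtype filtering, is exposed by filtering the parsed graph);
compound-mediated and maplink relations are out of scope. The degree
histogram is reported with the least-squares slope of log10 frequency vs
log10 degree as a descriptive heavy-tail summary.

## Driver screen and hub selection

Matched samples are the intersection of expression and methylation sample
ids in expression order. For each network gene and each of its promoter
CpGs, the Pearson correlation r across matched samples is tested with
t = r√((n−2)/(1−r²)) on n − 2 df, **two-sided**, and pairs with r < 0 and
p < 0.05 are retained. A one-sided variant would halve these p-values; the
two-sided-with-sign-constraint form is used because it is the conservative
reading, and the screen's effective false-positive rate per pair is α/2
(verified by the null-calibration test).

The mixed network has driver genes, their retained CpGs, the pathway edges
among driver genes, and one edge per retained (gene, CpG) pair. CpG nodes
connect only to their annotated gene. Centralities are computed on the
full mixed graph and reported for gene nodes:

* degree — incident edge count;
* closeness — the **harmonic** form Σ 1/d(u,v) with 1/∞ = 0, which stays
  well defined on the disconnected graphs this construction produces
  (classical closeness is not);
* betweenness — Brandes accumulation, unnormalised, over unordered pairs.

Hubs are the intersection of the three top-k lists (default **k = 10**).
Ranks are dense, and value ties at the k-th rank are all included, making
the selection invariant to row order. Because "top 10" and "top 10%" are
both defensible cutoffs for this kind of analysis, a fractional mode
(`frac=0.10`) is implemented alongside the absolute default; the package
does not guess between them beyond the default.

## Classifier

Features are the selected hub genes' expression values, z-scaled with
means and SDs learned on the training samples only. The kernel is linear —
the p ≈ n regime of a 27-sample, 10-feature problem gives nonlinear
kernels nothing to work with — and the cost parameter is picked from
{0.01, 0.1, 1, 10} by stratified, seeded ten-fold cross-validated
accuracy (ties favour the smaller C). GDM is the positive class
throughout. The random cohort split draws per-class training counts
uniformly without replacement (default 15 GDM + 12 control for training,
leaving 15 + 13 for validation). AUC is the rank (Mann–Whitney) statistic
with half credit for ties, verified against exhaustive pairwise
concordance; ROC points sweep all distinct decision scores. Stability is
the histogram, over seeded repetitions, of predicted-GDM counts among 50%
subsamples of known normals. Covariate comparison between predicted groups
uses the pooled two-sample t-test from `cohort_stats`.

## Cohort summary statistics

Continuous baseline characteristics use the **pooled** (Student) t-test —
from raw vectors or directly from published mean (SD) / n summaries, the
two routes agreeing to 1e−10 by construction — because the pooled form
reproduces the printed p-values of the emulated cohort's characteristics
table (maternal age p ≈ 0.764, gestational age p ≈ 0.558); Welch's test
is available as an option. Categorical characteristics use the Pearson
chi-square with the Yates continuity correction on 2×2 tables (which
reproduces the printed infant-sex p = 1 exactly: the correction absorbs
the half-count imbalance of a 20/21 vs 21/20 split). The published BMI,
gravidity and ethnicity p-values of that table are not reproducible from
the printed numbers by any standard test (the BMI entry duplicates the
maternal-age p exactly and is most plausibly a transcription artifact);
they are not asserted anywhere.

## The synthetic study

The generator's defaults are the emulated study's shape: 41/41 methylation
samples; 30/25 expression samples whose ids are a strict subset of the
methylation ids (so sample matching is nontrivial); 1200 genes; 30
pathways; 300 genes up-regulated in GDM and 165 in controls with |log2FC|
drawn from [0.5, 2.0]; 20 driver genes, 10 of them hubs; promoter CpG
counts from a truncated geometric distribution (truncated at 30 to keep
fixtures small) calibrated so that 82.5% of CpG-bearing genes carry fewer
than 20 CpGs, with 7.1% of genes carrying none; target driver coupling
r = −0.6; 2% missing beta entries; 5% of non-driver probes flagged
(sex-chromosome, SNP or cross-hybridisation) and ~10% extra non-promoter
probes, so every preprocessing filter has work to do.

Model details and deliberate choices:

* Expression: gene baseline ~ N(8, 1.5) on the log2 scale plus N(0, 0.7)
  sample noise. Data are generated directly on the normalised scale —
  array-intensity normalisation is a property of raw data and is not
  emulated.
* Hub drivers double as case-up DEGs with a fixed shift of 1.5 × the noise
  SD (≈ 1.05 log2FC), so the planted diagnostic signal lives in the genes
  the pipeline is supposed to find; with no DEGs planted (null
  configurations) hubs carry no effect, keeping the null clean.
* Driver CpGs: M = m₀ − (expr − baseline) + N(0, σ_m), with σ_m solved
  from the target correlation given the per-gene expression SD (including
  the group-shift variance); betas are the logistic back-transform.
  Driver CpGs are always promoter-class, autosomal and unflagged — the
  ground truth must survive preprocessing for recovery to be measurable.
* Non-driver CpGs: equal-weight Beta(2, 8) / Beta(8, 2) mixture, the
  component drawn per probe — the canonical bimodality of 450K data — so
  the beta→M transform is exercised across its range.
* Missing entries are injected into the methylation matrix only; the
  expression branch has no imputation step, matching the modelled
  workflow in which expression arrives complete after vendor processing.
* The pathway network grows by preferential attachment seeded on a clique
  of the hub drivers (each newcomer attaches 2 edges
  degree-proportionally), which guarantees the hubs end up with the
  highest degrees and the degree histogram is heavy-tailed. Edges are
  assigned to pathways at random; the first pathway additionally encodes
  one relation through a multi-alias entry and one through a group entry,
  so the parser's expansion rules are exercised on every round trip. The
  generator returns the exact union edge set, and parsing its own KGML
  must reproduce that set edge-for-edge.
* The external cohort (6 GDM / 177 normal) reuses the internal gene
  baselines and fold-changes with fresh noise; unlike the matched internal
  cohort, its GDM cases carry +3 years of age and +2 kg/m² of BMI, the
  known risk-factor structure of an unmatched population.
* Internal sample metadata (age ≈ N(33.3, 4.75), BMI ≈ N(26.5, 5.6)) is
  drawn identically for both groups, emulating a matched cohort in which
  baseline tests should be null.

All randomness derives from `SynthConfig.seed` through fixed stream keys
(cohort / network / external), so identical configs are byte-identical
across processes.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: array chemistry and background noise, batch
effects, cell-type composition, probe-level expression structure,
correlated methylation between neighbouring CpGs, linkage between
pathways and differential expression (planted DEGs are placed uniformly,
so pathway enrichment on synthetic data is a null exercise), and any
biological identity of the gene symbols.

## Problem sizes and runtime

The default study (1200 genes, ~13k probes, 82/55 samples, 30 pathways)
runs end to end in a few seconds. The statistical test suite uses 20
generator seeds for the calibration and recovery properties — null DEG
rate, null screen retention, planted DEG/driver/hub recovery, CV accuracy,
permutation-null accuracy — which is enough to estimate each rate well
inside the asserted tolerances while keeping the suite around five
minutes. Oracle-equivalence suites run on exhaustive small domains
(every hypergeometric configuration with N ≤ 30; graphs up to 25 nodes;
score vectors up to 50 samples) where brute-force enumeration is exact.

## Known limitations

* The driver screen tests each (gene, CpG) pair marginally; CpGs of the
  same gene share the expression vector, so per-gene retained-CpG counts
  are correlated and the pair-level α/2 rate is not a gene-level error
  rate.
* The moderated-t implementation covers the two-group design only — no
  covariates, array weights, or trend/robust variants.
* The kNN imputation is O(probes × probes) in distance evaluations
  (blocked matrix algebra in practice); for full-scale 450K matrices a
  chunked or approximate neighbour search would be preferable.
* Hub selection by top-k intersection can return fewer than k genes (or
  none); the pipeline reports the intersection as-is rather than padding
  it.
* JSON model serialisation round-trips linear kernels only.
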