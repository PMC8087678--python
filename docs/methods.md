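# Methods

## Scope and model

`cgiplast` classifies CpG-island (CGI) promoter genes per cancer type into
disjoint regulatory classes and quantifies their cross-cancer behaviour.
The decision pipeline is:

1. **Promoter curation.** Each TSS is windowed −250 bp to +500 bp
   (strand-relative, TSS base included, so 751 bp unless clipped at the
   chromosome start). Methylation probes are assigned by their single CpG
   coordinate. Windows with no probe are dropped; windows covered by an
   *identical* probe set are merged (their averaged β would be
   indistinguishable), taking the coordinate union and concatenating TSS and
   gene ids. Promoters on chrY/chrM are excluded, and only promoters with
   ≥ 1 bp CGI overlap are kept. Promoter methylation is the per-sample
   arithmetic mean of its probes' β values (missing probes dropped from the
   mean; an entry is missing only when all probes are).
2. **PRC2 annotation.** A promoter is PRC2⁺ when it overlaps both a
   chromatin-state segment in the H3K27me3 set {10 bivalent/poised TSS,
   11 flanking bivalent, 13 repressed Polycomb} and an EZH2 *or* SUZ12 peak
   (interchangeable evidence); PRC2⁻ when it overlaps neither any such
   segment nor any peak; otherwise ambiguous. A gene is PRC2⁺ if any CGI
   promoter is PRC2⁺, PRC2⁻ only if all are PRC2⁻; mixed/ambiguous genes
   join neither class. PRC2⁺ genes additionally pass a normal-expression
   gate — median FPKM < 4 over the cancer type's nonmalignant samples —
   because ESC-derived PRC2 annotation only carries over to tissues where
   the gene remains near-silent. The gate is applied per cancer type and
   scopes the whole PRC2⁺ set (both the hypermethylated and the upregulated
   branch); a global gate is available via the threshold configuration.
3. **Class calls.** Upregulated: expression filter passed AND adjusted
   p < 0.05 AND log2FC > 1. Hypermethylated promoter: β < 0.2 in strictly
   more than 90 % of nonmalignant samples AND β > 0.3 in strictly more than
   15 % of tumors; a hypermethylated *gene* needs ≥ 1 qualifying promoter
   and the absence of significant upregulation (log2FC < 1 OR adjusted
   p > 0.05), which makes HYPER and UP mutually exclusive by construction.
   All comparisons are strict, so values sitting exactly on a cutoff fail.
   The "p > 0.05" exclusion uses the adjusted p, consistent with the
   upregulation rule; genes that were not testable (failed the expression
   filter) count as not significantly upregulated, which is what the
   decision tree requires — the exclusion only removes demonstrated
   upregulation.

Downstream statistics operate on the per-(gene, cancer type) label table:
plastic genes (UP in one type, HYPER in another, within the same PRC2
class), cancer-type-restricted genes (mean-FPKM ratio ≥ 2 against all other
tumors with a 0.01 pseudo-floor, plus a one-vs-rest NB test at BH p < 0.05;
the significance step can be disabled), PCA distance ratios, LAD fractions,
signal profiles, and the enrichment statistics described below.

## The negative-binomial test

The two-group test is deliberately self-contained (no dispersion shrinkage,
no trend fitting, no independent filtering, no GLM covariates):

* size factors by median-of-ratios against the per-gene geometric-mean
  reference (genes with any zero excluded from the reference), scaled to
  median 1 — size factors are defined only up to a constant, and this
  convention makes normalized counts exactly invariant to rescaling one
  sample's library;
* per-gene dispersion α̂ by method of moments on normalized counts within
  each group, pooled with (n_k − 1) weights and floored at 1e−8;
* log2FC = log2(m_B + 0.5) − log2(m_A + 0.5) on normalized group means;
* delta-method SE from var(m_k) = (m_k + α̂ m_k²)/n_k;
* the Wald statistic is referred to a t distribution with n_A + n_B − 2
  degrees of freedom. With moment-estimated dispersions at n = 10 per
  group a normal reference is visibly anticonservative (empirical type-I
  ≈ 0.06–0.075 at α = 0.05); the t reference accounts for the dispersion
  estimation df and restores calibration (≈ 0.05);
* Benjamini–Hochberg over expression-filter-passing genes only, per cancer
  type.

The engine sits behind a plain table interface so a DESeq2/edgeR result can
be substituted; the test suite cross-checks it against DESeq2 (pydeseq2) on
planted data as an independent oracle.

## Enrichment statistics

* **Gene sets:** one-sided binomial z between the two upregulated classes,
  p₀ = (k_bg + 0.5)/(n_bg + 1) (the continuity guard prevents a degenerate
  null when a set misses the background), run in both directions.
  Filtering follows the unadjusted p < 0.05 convention; BH-adjusted values
  are reported alongside.
* **Motifs:** motif *occurrences* (per-TF interval sets) are an input; a
  region has a motif when ≥ 1 occurrence overlaps it, and enrichment of
  foreground vs background regions is the hypergeometric upper tail
  P(X ≥ k) with N = |fg| + |bg|, K motif-bearing regions, n = |fg|. This
  replaces de-novo motif discovery, which is out of scope: the statistic on
  predicted sites is the part of the analysis this package owns. TFs must
  clear median tumor FPKM > 10 and p < 0.01.
* **Peak overlap:** exact two-sided Fisher test; the reported odds ratio is
  the sample odds ratio with Haldane (+0.5) correction when a cell is zero.
* **Enhancer links:** mean distinct linked peaks per gene and the distinct
  region set linked to a gene list, from a (peak, gene) link table.

## The synthetic cohort

The generator emulates the *structure* of a multi-cancer study: a toy
two-chromosome genome with one gene every 8 kb, 1–3 clustered TSSs per gene
(sharing a probe set, hence merged) and a 25 % chance of a distal second
promoter with its own probes; 2–6 probes per promoter; CGIs covering the
probed region (a small fraction of genes is left CGI-free); chromatin
states and EZH2/SUZ12 peaks planted exactly on PRC2⁺ genes (an ambiguous
sliver gets states without peaks); LAD membership at 0.40 / 0.15 / 0.05 for
hypermethylated / upregulated-PRC2⁺ / other genes; Poisson enhancer links
(means 2.9 PRC2⁺, 1.9 PRC2⁻); motif occurrences planted in the enhancers of
designated target genes over a 5 % background rate; and gene sets enriched
for each upregulated class.

Expression is NB(μ, α) with lognormal library-size factors. Baseline FPKM
is uniform 0.5–2.5 for PRC2⁺ genes (clearing the FPKM < 4 gate) and
log-uniform 2–32 for PRC2⁻ genes. Because a 2000-gene toy genome cannot sum
to the 10⁹ FPKM·length budget of a real transcriptome, a block of highly
expressed *filler* genes (no promoter annotation) absorbs the remaining
library mass; without it, realized FPKM would be inflated ~30-fold and the
absolute thresholds (FPKM 1/4/10) would lose their meaning. Planted effects:
upregulated genes multiply tumor μ by 4 (PRC2⁺) or 2.5 (PRC2⁻) in one
target type; hypermethylated genes draw probe β from Beta(20, 6)
(mean ≈ 0.77) in 40 % of tumors — Beta(2, 30) (mean ≈ 0.06) otherwise — and
have tumor expression reduced 30 %, exercising the "not significantly up"
clause; plastic genes are UP in one type and HYPER in another; restricted
flags mark a subset of the single-type UP plantings. The first cancer
type's tumors additionally share a correlated expression program on a
random 10 % of genes (mean-zero in log space), so PCA separation is not an
artifact of the planted fold-changes alone, plus a latent TF program
coupling a high-expression driver gene to 30 target genes for the
expression-quintile analysis.

All randomness flows from a single integer seed (annotation and cohort use
derived streams); identical configurations produce byte-identical fixture
trees. Default sizes — 3 cancer types, 2000 genes, 40 tumors and 10 normals
per type — keep a full end-to-end run in a few seconds while leaving each
class with ~250 planted (gene, type) pairs, enough for stable
sensitivity/precision estimates.

What the generator does *not* emulate: real sequence context, probe
cross-reactivity, tumor purity and copy number, batch effects, dispersion
trends over the mean, correlated methylation beyond the gene level, and
realistic gene-length/expression covariation. Passing tests therefore
demonstrate that the decision rules and statistics do what they claim under
their stated model, not that the thresholds are optimal for real TCGA data.

## Numerical choices and edge cases

* Coordinates are 0-based half-open throughout; BED is consumed verbatim,
  TSV tables carry 1-based positions converted on read. Overlap means ≥ 1
  shared bp, strand ignored (states, peaks, CGIs, LADs are unstranded).
  Uncovered bedGraph bases read as signal 0.
* Whether the −250/+500 window includes the TSS base is a convention
  (included here, length 751); no downstream rule depends on ±1 bp.
* PCA uses log2(FPKM + 1), per-gene centering, SVD, first 2 components
  (configurable); the inter/intra ratio is +∞ when the intra-type distance
  is zero (within floating-point tolerance). Distance ratios are reported
  on tumor samples only.
* Signal profiles are TSS-centered and strand-oriented (minus-strand
  profiles mirrored); bins at a clipped chromosome edge are averaged over
  the full bin width (zero-fill), which preserves the mass identity
  `sum(bin values) * bin width = windowed integral`. Heatmap ordering uses
  the per-promoter mean signal, descending. Moving-window trends are
  centered rolling means with edge shrinkage.
* Merging promoters requires *identical* probe sets; promoters with merely
  overlapping sets stay distinct (their β vectors differ). Subset-merging
  is deliberately not performed.
* Cancer types with fewer than 5 nonmalignant samples are skipped with a
  warning.
* The expression-quintile stratified test is a one-sided Welch t between
  the top and bottom q (default 0.2) strata.

## Known limitations

* The NB engine has no dispersion shrinkage, so it is less powerful than
  DESeq2 at very small n and very low counts; the planted effect sizes here
  (fold-change ≥ 2.5 at 40 vs 10 samples) are comfortably inside its power
  envelope.
* Gene-level aggregation rules (any-promoter for hypermethylation,
  any-positive/all-negative for PRC2 class) are documented decisions where
  several readings are defensible; both are configurable at the promoter
  table level.
* The motif analysis measures occurrence enrichment only; it cannot
  discover motifs, weight occurrence strength, or control for sequence
  composition between foreground and background regions.
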