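# cgiplast

Pan-cancer classification of CpG-island (CGI) promoter regulation.

More than half of human promoters overlap CpG islands. A subset of these is
occupied by Polycomb Repressive Complex 2 (PRC2) in embryonic stem cells —
bivalent, poised, lowly expressed — and this PRC2⁺-CGI class is famously
prone to DNA hypermethylation and silencing in tumors. The same class is
also prone to the opposite fate: strong, cancer-type-specific
transcriptional upregulation, often driven by transcription-factor binding
in linked distal enhancers. `cgiplast` implements the analysis framework
that separates these fates. Per cancer type it calls three disjoint gene
classes,

* **hypermethylated PRC2⁺-CGI** — promoter β < 0.2 in > 90 % of nonmalignant
  samples and β > 0.3 in > 15 % of tumors, without significant upregulation
  (log2FC < 1 or adjusted p > 0.05);
* **upregulated PRC2⁺-CGI** — adjusted p < 0.05 and log2FC(tumor vs
  nonmalignant) > 1 for a gene whose CGI promoter carries a
  bivalent/repressed chromatin state (states 10/11/13 of the 15-state model)
  plus an EZH2 or SUZ12 peak, gated on near-silence in normal tissue
  (median FPKM < 4);
* **upregulated PRC2⁻-CGI** — the same expression rule for CGI genes with no
  PRC2 evidence at any promoter;

and then computes the downstream statistics: regulatory **plasticity**
(genes upregulated in one cancer type and hypermethylated in another),
cancer-type-**restricted** genes (≥ 2-fold higher in one type's tumors than
in all others), PCA inter/intra-type distance ratios, lamina-associated
domain (LAD) fractions, TSS-centered signal profiles, reciprocal
foreground/background gene-set enrichment (binomial z), motif enrichment in
linked enhancers (one-sided hypergeometric with a TF-expression gate),
Fisher peak-overlap tests and enhancer-links-per-gene summaries.

It is aimed at computational epigenomics groups who want the decision rules
as tested, reusable code. Because the full TCGA/Roadmap inputs are not
shippable, the package includes a first-class synthetic-cohort generator
that emits every input shape the pipeline consumes (TSS tables, CGI /
chromatin-state / peak / LAD BEDs, probe manifests, count and β matrices,
enhancer-gene links, motif BEDs, GMTs) with planted ground truth, so every
stage is validated end to end.

## The core statistics

Differential expression is a self-contained negative-binomial two-group
test: median-of-ratios size factors s_j, per-gene dispersion α̂ by method of
moments on normalized counts (var = μ + αμ²), log2FC from pseudo-counted
normalized group means, a delta-method standard error and a Wald statistic
referred to a t distribution with n₁+n₂−2 df, followed by
Benjamini–Hochberg correction over expression-filtered genes (count > 0 in
> 80 % of both groups, FPKM > 1 in > half of tumors). An externally computed
DE table with the same columns can be substituted.

Gene-set enrichment between the two upregulated classes uses a binomial
test approximated by a z-test with the background rate continuity-guarded,
z = (k/n − p₀)/√(p₀(1−p₀)/n), p₀ = (k_bg + ½)/(n_bg + 1), run reciprocally
with foreground and background swapped. Motif enrichment in enhancer
regions is an upper-tail hypergeometric on motif-bearing region counts,
reported only for TFs with median tumor FPKM > 10 and p < 0.01.

## Worked example

Generate a synthetic three-cancer-type cohort (2000 genes, 40 tumors and
10 normals per type) and run the full pipeline on the written files:

```sh
cgiplast simulate --out demo/fixture --seed 1
# wrote 21 files to demo/fixture (config hash 0b22a42f270cafb6)

cat > demo/run.yaml <<EOF
seed: 1
input_dir: demo/fixture
out_dir: demo/results
EOF
cgiplast run --config demo/run.yaml
```

which prints the per-cancer-type class counts

```
CT01: HYPER_PRC2=102, NONE=1711, UP_PRC2=78, UP_PRC2NEG=69
CT02: HYPER_PRC2=82, NONE=1719, UP_PRC2=92, UP_PRC2NEG=67
CT03: HYPER_PRC2=74, NONE=1733, UP_PRC2=90, UP_PRC2NEG=63
```

and writes `demo/results/` with the promoter table, per-type DE tables,
class calls, enrichment tables, a log, the effective configuration and
`summary.json`. Because the fixture carries a truth table, the summary also
reports recovery of the planted classes — with the default conditions the
calls are essentially exact:

```
HYPER_PRC2   sensitivity 0.992  precision 1.00   (tp=258, fn=2)
UP_PRC2      sensitivity 1.000  precision 1.00   (tp=260)
UP_PRC2NEG   sensitivity 0.995  precision 1.00   (tp=199, fn=1)
```

The downstream statistics recover the planted structure: LAD fractions of
0.354 / 0.181 / 0.043 for the hypermethylated-PRC2⁺ / upregulated-PRC2⁺ /
upregulated-PRC2⁻ promoters (planted gene-level rates 0.40 / 0.15 / 0.05),
and 2.96 vs 1.89 enhancer links per PRC2⁺ vs PRC2⁻ gene (planted Poisson
means 2.9 / 1.9). The same run is available without the CLI via
`cgiplast.simulate_all` + `cgiplast.analyze`.

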