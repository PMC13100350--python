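# Methods

## Model and procedure

`regratio` quantifies, per gene, the relative weight of transcriptional
versus post-transcriptional regulation from two peak-level inputs:

1. **Transcriptional density (TD)** — significant chromatin-accessibility
   peaks (ATAC-seq) counted in an *expanded gene boundary* and divided by
   gene length in kb. The expanded boundary stretches 5,000 bp upstream of
   the TSS and 500 bp past the 3′ end, capturing proximal promoters and
   nearby enhancers/silencers as well as the gene body.
2. **Post-transcriptional density (PTD)** — significant RNA–protein
   occupancy peaks (POP-seq) counted within the gene body, divided by the
   same length.
3. **Regulation ratio** — RR = PTD/TD. Because both densities share the
   length denominator, RR = pop_count/atac_count exactly; it is computed
   only for genes with ≥ 1 peak of each kind, and categories are assigned
   on the integer counts (pop > atac → post-transcriptional, equal →
   balanced, pop < atac → transcriptional), so RR = 1 is never lost to
   floating-point rounding.

Key modelling assumptions: a peak is an all-or-nothing regulatory event
(signal strength within a peak is ignored); peak *density* rather than raw
count is the comparable quantity between genes; any ≥ 1 bp overlap places a
peak "within" a window (peak callers routinely emit peaks straddling
boundaries, so containment would bias against boundary events); and a peak
overlapping the expanded boundaries of several genes counts for all of
them — double counting inflates totals but treats neighbouring genes
symmetrically.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `upstream_bp` | 5,000 | promoter-side extension of the expanded boundary (bp) |
| `downstream_bp` | 500 | 3′-side extension (bp) |
| `stranded` | true | mirror the margins for − strand genes |
| `alpha` | 0.05 | FDR threshold for significant peaks (strict `<`) |
| `min_overlap_bp` | 1 | minimum peak∩window intersection to count |

"Upstream" is interpreted strand-awarely (upstream of the TSS), the
standard promoter-capture reading; `--unstranded-window` reproduces the
strand-blind alternative since the choice is not forced by the definition
of the boundary. Genes without strand annotation are treated as + strand
with a logged warning.

Significance filtering takes two routes: narrowPeak input carries
caller-computed q-values (`use_q`); Piranha-style BED input carries raw
p-values, which are Benjamini–Hochberg adjusted across the whole file
(`bh_on_p`) — BH being the field-standard FDR procedure when the upstream
caller does not provide one. Correction is per file, not genome-wide across
assays. Exactly one peak file per assay is expected (replicates are
presumed pooled before peak calling); a concatenation helper exists but
never merges intervals.

## Statistics

* **Mann–Whitney U** — U counts pairs with the first sample above the
  second, ties ½. For pooled n ≤ 16 the p-value is exact by full
  enumeration of group assignments (correct under ties, where the classical
  exact distribution is not); above that, the tie-corrected normal
  approximation. Two-sided by default; sidedness is a caller choice.
* **Kruskal–Wallis** — tie-corrected H, chi-square p with k−1 df. The
  all-values-identical degenerate case reports H = 0 with an undefined
  (NaN) p rather than a fabricated one.
* **Cliff's delta** — (wins − losses)/(nm); satisfies δ = 2U/(nm) − 1 under
  the same tie convention.
* **Bonferroni** — min(1, m·p); the three pairwise category tests use m = 3
  (m = number of tests actually run when a category is empty).
* **Biotype enrichment** — per category, transcript-type shares are
  computed over *transcripts* (a gene contributes one count per annotated
  transcript); labels at ≤ 1% abundance are dropped; each retained
  (label, category) forms a 2×2 transcript-count table against the
  background (all transcripts of the annotation by default) tested with
  Fisher's exact test. A rank test cannot produce an odds ratio, so the
  contingency construction is the one consistent with reporting ORs; this
  choice is recorded in the output metadata. Zero cells get the
  Haldane–Anscombe 0.5 correction for the OR (flagged); the p-value is
  computed on the uncorrected table.
* **Density correlation** — Pearson r of log₁₀ TD vs log₁₀ PTD over passing
  genes (both strictly positive by the filter); r² is the reported
  quantity since axis sign conventions in plotting do not change it.

## Cross-sample agreement

Genes passing the filter in every sample are intersected by gene id (no
liftover). Each common gene's category vector is classified as *full*
agreement, *exactly-one-pair* agreement (that pair matches and the
remaining sample differs — the only pairwise definition under which the
classes partition the gene set), or *none*. With two samples the pair class
collapses into full agreement. With ≥ 4 samples a residual `multi_pair`
class (two disjoint agreeing pairs) becomes reachable and is reported
separately.

## Synthetic data: what it emulates, and what it does not

The generator draws gene lengths log-normal (default median 10 kb), places
genes uniformly on synthetic chromosomes, assigns each gene a regulatory
regime (default mix 41% transcriptional / 9.9% balanced / 49.1%
post-transcriptional), and draws significant peak counts Poisson with
per-kb rates per regime — the simplest model under which the per-kb
normalization is exactly the rate estimator and RR recovers the rate ratio.
Defaults give the post-transcriptional regime a 2:1 occupancy:accessibility
rate ratio with ≥ 5 expected accessibility peaks at the median length.
Balanced genes reuse a single shared count for both assays so exact RR = 1
occurs at any rate. A per-gene *activity* multiplier (log-normal, sd 0.6
in log₁₀), shared between assays, couples the two densities across genes;
the value was set so the log-density coupling is of the same order as
observed in real joint assays (R² ≈ 0.5–0.6) and it cancels from every
expected RR. Non-significant decoy peaks (per gene, and 200 intergenic)
exercise the FDR filter; ATAC decoys carry q ≥ 0.1, POP decoys raw
p ≥ 0.2, well clear of the BH boundary. Covariates are log-normal around
regime medians taken as study conditions (FPKM 34/6.75/310, isoforms 5/2/7,
protein 1.0/1.05/1.2 for transcriptional/balanced/post).

What the generator does **not** emulate: peak-width and signal-strength
distributions, chromatin domain structure, overlapping/nested gene
architecture beyond random collisions, correlated replicate noise, and any
sequence content. Passing tests therefore demonstrate that the pipeline's
arithmetic, filtering, classification and statistics behave as specified
under controlled regimes — not that real cell lines will show any
particular category split.

Problem sizes used in the checked runs — 2,000 genes per dataset, 2,000
null replicates, 50,000 agreement vectors — were chosen as the smallest
sizes at which the targeted effects are statistically unambiguous.

## Numerical choices and degenerate inputs

* Coordinates are uniformly 0-based half-open; GTF (1-based closed) is
  converted on load. Abutting intervals ([1000,2000) vs [2000,2100)) do not
  overlap.
* RR is formed as an exact rational before float conversion; categories
  come from integer comparison.
* log₂RR = log₂(pop) − log₂(atac), finite for every passing gene.
* The .rnk export sorts descending by score with lexicographic gene-id
  tie-break, making output order total and reproducible.
* Degenerate peak rows (start ≥ end) are rejected and counted, not
  silently dropped; missing significance fields fail fast naming the first
  offending record.
* Empty categories degrade covariate comparisons to the populated pair with
  a warning; empty common-gene sets are errors.

## Known limitations

* RR carries no direction or magnitude of individual regulatory events;
  it is a density contrast only.
* The metric is gene-level; isoform-resolved regulation is out of scope.
* Equal peak weighting ignores peak strength and width.
* The balanced class is a measure-zero knife-edge on counts; its size is
  sensitive to sequencing depth in real data (shallow assays produce small
  counts and hence more exact ties).
* Cross-sample agreement requires shared gene identifiers; no coordinate
  liftover is attempted.
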