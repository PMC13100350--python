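# regratio

Gene-level **regulation ratios** from chromatin-accessibility and
RNA–protein-occupancy peak calls.

A gene's expression is shaped both at the DNA (transcriptional) level —
visible as accessible chromatin around the gene — and at the RNA
(post-transcriptional) level — visible as protein-bound sites on its
transcripts. `regratio` takes *already-called* peaks from the two assays
(ATAC-seq narrowPeak for accessibility, POP-seq BED for RNA–protein
occupancy), assigns them to genes, and quantifies which regulatory layer
dominates each gene.

For a gene of length *L* (kb) with *A* significant accessibility peaks in
its **expanded boundary** (5,000 bp upstream of the TSS through 500 bp past
the 3′ end, strand-aware) and *P* significant occupancy peaks in the gene
body, the two densities and their ratio are

    TD  = A / L        (transcriptional density, peaks/kb)
    PTD = P / L        (post-transcriptional density, peaks/kb)
    RR  = PTD / TD = P / A

Since length cancels, RR is a pure count ratio, computed only for genes with
at least one peak of each kind (the gene filter):

* **RR > 1** — predominantly post-transcriptionally regulated
* **RR = 1** — balanced regulation (decided on the integer counts, exactly)
* **RR < 1** — predominantly transcriptionally regulated

Downstream, the package compares covariates (gene length, isoform count,
FPKM, protein expression) across the three categories with Kruskal–Wallis
and Bonferroni-corrected Mann–Whitney *U* tests plus Cliff's delta, tests
transcript-biotype enrichment per category with Fisher's exact test (odds
ratios over transcript-count 2×2 tables), measures classification agreement
across samples or cell lines, and exports log₂(RR) pre-ranked gene lists
(.rnk) for external GSEA. A synthetic-data module generates complete,
self-contained fixture sets (GTF + peak files + covariate tables) with
known regime structure.

Intended users: regulatory-genomics analysts with peak-level output from
MACS3 (ATAC-seq) and Piranha (POP-seq or CLIP-style assays) who want a
per-gene, assay-integrated summary of regulatory strategy.

## Worked example

```python
import regratio as rr

cfg = rr.SyntheticConfig(n_genes=500, seed=42)
paths = rr.simulate(cfg, "demo")

genes = rr.load_gene_annotation(paths["gtf"], fpkm_table=paths["fpkm"])
atac = rr.filter_significant(rr.load_narrowpeak(paths["atac"]), method="use_q")
pop = rr.filter_significant(rr.load_bed(paths["pop"], pvalue_col=7), method="bh_on_p")

profiles = rr.build_profiles(genes, atac, pop)
summary = rr.summarize_profiles(profiles)
print(f"passing filter: {summary['n_passing']}/{summary['n_genes']}")
for cat, pct in summary["category_pct"].items():
    print(f"  {cat:20s} {pct:5.1f}%")

corr = rr.density_correlation(profiles)
print(f"density correlation R^2 = {corr['r_squared']:.3f} (n={corr['n']})")

gene_map = {g.gene_id: g for g in genes}
comp = rr.compare_covariate(profiles, "fpkm", genes=gene_map)
print(f"FPKM across categories: Kruskal-Wallis p = {comp.kw_p:.3g}")
print("medians:", {c: round(m, 1) for c, m in comp.medians.items()})
```

prints

```
passing filter: 412/500
  transcriptional       38.3%
  balanced              15.5%
  post_transcriptional  46.1%
density correlation R^2 = 0.441 (n=412)
FPKM across categories: Kruskal-Wallis p = 2.58e-40
medians: {'transcriptional': 37.9, 'balanced': 12.5, 'post_transcriptional': 285.3}
```

412 of 500 genes carry at least one significant peak of each kind; the
category split reflects the generator's regime mix, the two log densities
correlate across genes (shared per-gene regulatory activity), and transcript
abundance separates sharply by category — post-transcriptionally dominated
genes are the most highly expressed, balanced genes the least.

The same pipeline from a shell:

```bash
regratio simulate --n-genes 500 --seed 42 --outdir demo
regratio compute --gtf demo/genes.gtf --atac demo/atac.narrowPeak \
    --pop demo/pop.bed --out out/profiles.tsv
regratio compare --profiles out/profiles.tsv --covariate fpkm \
    --covariate-table demo/fpkm.tsv --out out/fpkm_stats.tsv
regratio enrich --profiles out/profiles.tsv --gtf demo/genes.gtf --out out/enrich.tsv
regratio rnk --profiles out/profiles.tsv --out out/scores.rnk
```

Every command writes a `manifest.json` (parameters, input digests, seed)
next to its output; identical inputs reproduce identical outputs.

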