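"""Self-contained synthetic fixtures: annotation, peaks, covariates.

Emulates the statistical structure of a joint chromatin-accessibility /
RNA-protein-occupancy experiment so the whole pipeline is testable without
external data. Each gene is assigned a regulatory regime (transcriptional,
balanced, post-transcriptional); significant peak counts are Poisson with
per-kb rates chosen per regime, so the per-kb density normalization is
exactly the rate estimator and the expected count ratio equals the regime's
rate ratio. "Balanced" genes reuse one shared draw for both assays so exact
RR = 1 cases exist at any rate. Non-significant decoy peaks (genic and
intergenic) are added so the significance filter has work to do.

Defaults mirror the observed study conditions: regime mix 41/9.9/49.1
(transcriptional/balanced/post-transcriptional), log-normal gene lengths
with a 10 kb median, FPKM medians 34/6.75/310, isoform medians 5/2/7,
protein medians 1.0/1.05/1.2, and a two-fold post-transcriptional rate
advantage (lambda_pop/lambda_atac = 2) in the post regime.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .annotation_io import GeneRecord, body_window, expand_window
from .regulation_metrics import BALANCED, CATEGORIES, POST_TRANSCRIPTIONAL, TRANSCRIPTIONAL

DEFAULT_SEED = 1729

_DEFAULT_BIOTYPES = {
    "protein_coding": 0.45,
    "retained_intron": 0.20,
    "processed_transcript": 0.14,
    "nonsense_mediated_decay": 0.12,
    "lncRNA": 0.05,
    "miRNA": 0.02,
    "processed_pseudogene": 0.02,
}


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    n_chroms: int = 8
    chrom_length_bp: int = 25_000_000
    length_log10_mean: float = 4.0  # median gene length 10 kb
    length_log10_sd: float = 0.45
    length_min_bp: int = 200
    regime_fractions: dict = field(
        default_factory=lambda: {
            TRANSCRIPTIONAL: 0.410,
            BALANCED: 0.099,
            POST_TRANSCRIPTIONAL: 0.491,
        }
    )
    # significant-peak Poisson rates, peaks per kb of gene length
    lambda_atac: dict = field(
        default_factory=lambda: {
            TRANSCRIPTIONAL: 1.0,
            BALANCED: 0.5,
            POST_TRANSCRIPTIONAL: 0.5,
        }
    )
    lambda_pop: dict = field(
        default_factory=lambda: {
            TRANSCRIPTIONAL: 0.25,
            BALANCED: 0.5,
            POST_TRANSCRIPTIONAL: 1.0,
        }
    )
    sig_fraction: float = 0.8  # fraction of generated peaks that are significant
    #: per-gene regulatory-activity multiplier (log-normal, median 1) applied
    #: to both assays' rates: couples the two densities across genes without
    #: changing their expected ratio
    activity_log10_sd: float = 0.6
    n_intergenic_decoys: int = 200
    # per-regime covariate medians (log-normal sampling around them)
    isoform_medians: dict = field(
        default_factory=lambda: {
            TRANSCRIPTIONAL: 5,
            BALANCED: 2,
            POST_TRANSCRIPTIONAL: 7,
        }
    )
    fpkm_medians: dict = field(
        default_factory=lambda: {
            TRANSCRIPTIONAL: 34.0,
            BALANCED: 6.75,
            POST_TRANSCRIPTIONAL: 310.0,
        }
    )
    protein_medians: dict = field(
        default_factory=lambda: {
            TRANSCRIPTIONAL: 1.0,
            BALANCED: 1.05,
            POST_TRANSCRIPTIONAL: 1.2,
        }
    )
    isoform_log10_sd: float = 0.25
    fpkm_log10_sd: float = 0.5
    protein_log10_sd: float = 0.08
    biotype_probs: dict = field(default_factory=lambda: dict(_DEFAULT_BIOTYPES))
    missing_fraction: float = 0.0  # covariate rows dropped at random
    atac_peak_width: int = 200
    pop_peak_width: int = 50
    upstream_bp: int = 5000
    downstream_bp: int = 500
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        total = sum(self.regime_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("regime_fractions must sum to 1")
        for rates in (self.lambda_atac, self.lambda_pop):
            if any(v < 0 for v in rates.values()):
                raise ValueError("peak rates must be nonnegative")
        if not 0 < self.sig_fraction <= 1:
            raise ValueError("sig_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _rng(config: SyntheticConfig, rng: Optional[np.random.Generator]):
    return rng if rng is not None else np.random.default_rng(config.seed)


# ---------------------------------------------------------------------------
# Annotation


def generate_annotation(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[GeneRecord], dict[str, str]]:
    """Draw genes and their regulatory regimes.

    Lengths are log-normal (base 10), positions uniform per chromosome,
    strands random. The number of transcripts per gene follows the regime's
    isoform model; biotype labels are drawn i.i.d. from ``biotype_probs``.
    Returns (genes, gene_id -> regime).
    """
    rng = _rng(config, rng)
    regimes_order = list(CATEGORIES)
    fracs = np.array([config.regime_fractions.get(r, 0.0) for r in regimes_order])
    regime_idx = rng.choice(len(regimes_order), size=config.n_genes, p=fracs)

    lengths = np.round(
        10.0 ** rng.normal(config.length_log10_mean, config.length_log10_sd, config.n_genes)
    ).astype(int)
    lengths = np.clip(lengths, config.length_min_bp, config.chrom_length_bp // 10)
    chroms = rng.integers(0, config.n_chroms, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)

    labels = list(config.biotype_probs)
    label_p = np.array([config.biotype_probs[lb] for lb in labels])
    label_p = label_p / label_p.sum()

    genes: list[GeneRecord] = []
    regimes: dict[str, str] = {}
    for i in range(config.n_genes):
        regime = regimes_order[regime_idx[i]]
        length = int(lengths[i])
        start = int(rng.integers(0, config.chrom_length_bp - length))
        n_tx = max(
            1,
            int(round(10.0 ** rng.normal(
                np.log10(config.isoform_medians[regime]), config.isoform_log10_sd
            ))),
        )
        biotypes = tuple(labels[j] for j in rng.choice(len(labels), size=n_tx, p=label_p))
        gene_id = f"SYNG{i:05d}"
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                chrom=f"chr{chroms[i] + 1}",
                start=start,
                end=start + length,
                strand=str(strands[i]),
                biotypes=biotypes,
                isoform_count=n_tx,
            )
        )
        regimes[gene_id] = regime
    return genes, regimes


def write_gtf(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write genes and their transcripts as Ensembl-dialect GTF (1-based)."""
    with open(path, "w") as fh:
        fh.write("#!genome-build synthetic\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for t, biotype in enumerate(g.biotypes, start=1):
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.T{t}"; '
                    f'transcript_biotype "{biotype}";'
                )
                fh.write(
                    f"{g.chrom}\tsynthetic\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )


# ---------------------------------------------------------------------------
# Peaks


def _place_peak(rng, win_start: int, win_end: int, width: int) -> tuple[int, int]:
    width = min(width, win_end - win_start)
    start = int(rng.integers(win_start, win_end - width + 1))
    return start, start + width


def generate_peaks(
    config: SyntheticConfig,
    genes: Sequence[GeneRecord],
    regimes: Mapping[str, str],
    source: str,
    rng: Optional[np.random.Generator] = None,
    balanced_counts: Optional[Mapping[str, int]] = None,
    activities: Optional[Mapping[str, float]] = None,
) -> list[tuple]:
    """Generate peak rows for one assay, sorted by coordinate.

    Significant-peak counts are Poisson(lambda * length_kb) per gene; ATAC
    peaks land uniformly in the expanded window, POP peaks in the gene body.
    Balanced-regime genes take their significant count from
    ``balanced_counts`` when provided (shared between assays so exact RR = 1
    arises); ``activities`` supplies the per-gene rate multiplier shared
    between assays (1.0 when absent). Decoy (non-significant) peaks are
    added per gene at rate
    lambda*(1-sig_fraction)/sig_fraction plus ``n_intergenic_decoys``
    placed anywhere.

    Returns narrowPeak 10-tuples for atac, BED6+p 7-tuples for pop.
    """
    rng = _rng(config, rng)
    rates = config.lambda_atac if source == "atac" else config.lambda_pop
    rows = []
    counter = 0

    def sig_quality():
        if source == "atac":
            q = 10.0 ** (-rng.uniform(1.32, 6.0))  # q < 0.048
            p = q * rng.uniform(0.05, 0.8)
        else:
            p = 10.0 ** (-rng.uniform(4.0, 8.0))
            q = None
        return p, q

    def decoy_quality():
        if source == "atac":
            q = rng.uniform(0.1, 0.9)
            p = q * rng.uniform(0.3, 0.95)
        else:
            p = rng.uniform(0.2, 0.99)
            q = None
        return p, q

    width = config.atac_peak_width if source == "atac" else config.pop_peak_width
    for g in genes:
        regime = regimes[g.gene_id]
        activity = 1.0 if activities is None else activities[g.gene_id]
        lam = rates[regime] * activity * g.length_bp / 1000.0
        if source == "atac":
            win = expand_window(g, config.upstream_bp, config.downstream_bp,
                                chrom_length=config.chrom_length_bp)
        else:
            win = body_window(g)
        if regime == BALANCED and balanced_counts is not None:
            n_sig = balanced_counts[g.gene_id]
        else:
            n_sig = int(rng.poisson(lam)) if lam > 0 else 0
        lam_decoy = lam * (1 - config.sig_fraction) / config.sig_fraction
        n_decoy = int(rng.poisson(lam_decoy)) if lam_decoy > 0 else 0
        for is_sig, n in ((True, n_sig), (False, n_decoy)):
            for _ in range(n):
                start, end = _place_peak(rng, win.start, win.end, width)
                p, q = sig_quality() if is_sig else decoy_quality()
                counter += 1
                rows.append(_peak_row(source, g.chrom, start, end, counter, p, q, rng))

    for _ in range(config.n_intergenic_decoys):
        chrom = f"chr{int(rng.integers(0, config.n_chroms)) + 1}"
        start, end = _place_peak(rng, 0, config.chrom_length_bp, width)
        p, q = decoy_quality()
        counter += 1
        rows.append(_peak_row(source, chrom, start, end, counter, p, q, rng))

    rows.sort(key=lambda r: (r[0], int(r[1]), r[3]))
    return rows


def _peak_row(source, chrom, start, end, idx, p, q, rng):
    if source == "atac":
        return (
            chrom, str(start), str(end), f"atac_peak_{idx}",
            str(int(rng.integers(100, 1000))), ".",
            f"{rng.uniform(1.0, 20.0):.5f}",
            f"{-np.log10(p):.5f}", f"{-np.log10(q):.5f}",
            str((end - start) // 2),
        )
    return (
        chrom, str(start), str(end), f"pop_peak_{idx}",
        str(int(rng.integers(100, 1000))), ".", f"{p:.6g}",
    )


def write_peak_rows(rows: Sequence[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Covariates


def generate_covariates(
    config: SyntheticConfig,
    genes: Sequence[GeneRecord],
    regimes: Mapping[str, str],
    rng: Optional[np.random.Generator] = None,
) -> dict[str, list[tuple[str, str]]]:
    """Per-gene covariate tables as (gene_id, value) rows.

    Isoform counts restate the annotation's transcript counts (the tables
    must agree). FPKM and protein expression are log-normal around the
    regime medians. ``missing_fraction`` of rows is dropped at random per
    table.
    """
    rng = _rng(config, rng)
    tables: dict[str, list[tuple[str, str]]] = {"isoform_count": [], "fpkm": [], "protein_expr": []}
    for g in genes:
        regime = regimes[g.gene_id]
        fpkm = 10.0 ** rng.normal(np.log10(config.fpkm_medians[regime]), config.fpkm_log10_sd)
        protein = 10.0 ** rng.normal(
            np.log10(config.protein_medians[regime]), config.protein_log10_sd
        )
        for name, value in (
            ("isoform_count", str(g.isoform_count)),
            ("fpkm", f"{fpkm:.6g}"),
            ("protein_expr", f"{protein:.6g}"),
        ):
            if config.missing_fraction > 0 and rng.random() < config.missing_fraction:
                continue
            tables[name].append((g.gene_id, value))
    return tables


def write_covariate_table(rows, path: str | Path, value_name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"gene_id\t{value_name}\n")
        for gene_id, value in rows:
            fh.write(f"{gene_id}\t{value}\n")


# ---------------------------------------------------------------------------
# One-shot fixture emission


def simulate(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full fixture set into ``outdir``; deterministic per seed.

    Emits genes.gtf, atac.narrowPeak, pop.bed, isoforms.tsv, fpkm.tsv,
    protein.tsv and truth.tsv (gene -> generating regime).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genes, regimes = generate_annotation(config, rng)
    activities = {
        g.gene_id: float(10.0 ** rng.normal(0.0, config.activity_log10_sd))
        for g in genes
    }
    # one shared significant count per balanced gene -> exact RR = 1 possible
    balanced_counts = {
        g.gene_id: int(rng.poisson(
            config.lambda_pop[BALANCED] * activities[g.gene_id] * g.length_bp / 1000.0
        ))
        for g in genes
        if regimes[g.gene_id] == BALANCED
    }
    atac_rows = generate_peaks(config, genes, regimes, "atac", rng, balanced_counts, activities)
    pop_rows = generate_peaks(config, genes, regimes, "pop", rng, balanced_counts, activities)
    covariates = generate_covariates(config, genes, regimes, rng)

    paths = {
        "gtf": outdir / "genes.gtf",
        "atac": outdir / "atac.narrowPeak",
        "pop": outdir / "pop.bed",
        "isoforms": outdir / "isoforms.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "protein": outdir / "protein.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_gtf(genes, paths["gtf"])
    write_peak_rows(atac_rows, paths["atac"])
    write_peak_rows(pop_rows, paths["pop"])
    write_covariate_table(covariates["isoform_count"], paths["isoforms"], "isoform_count")
    write_covariate_table(covariates["fpkm"], paths["fpkm"], "fpkm")
    write_covariate_table(covariates["protein_expr"], paths["protein"], "protein_expr")
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tregime\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{regimes[g.gene_id]}\n")
    return paths
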