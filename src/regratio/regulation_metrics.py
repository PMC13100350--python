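"""Per-gene regulation metrics and the three-way regulatory classification.

Transcriptional regulation is measured as the density of significant
chromatin-accessibility peaks in the expanded gene boundary (5,000 bp
upstream of the TSS, 500 bp past the 3' end); post-transcriptional
regulation as the density of significant RNA-protein occupancy peaks in the
gene body. Both densities are peaks per kb of gene length, so their ratio

    RR = (pop peaks / length) / (atac peaks / length) = pop_count / atac_count

is a pure count ratio: RR > 1 marks predominantly post-transcriptional
control, RR = 1 regulatory balance, RR < 1 predominantly transcriptional
control. RR is defined only for genes carrying at least one peak of each
kind (the gene filter). Balance is decided on the integer counts, never on
a floating-point ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneRecord, body_window, expand_window
from .peak_io import PeakSet, count_overlapping

logger = logging.getLogger(__name__)

TRANSCRIPTIONAL = "transcriptional"
BALANCED = "balanced"
POST_TRANSCRIPTIONAL = "post_transcriptional"
CATEGORIES = (TRANSCRIPTIONAL, BALANCED, POST_TRANSCRIPTIONAL)


class GeneFilterError(ValueError):
    """Raised when RR is requested for a gene failing the peak filter."""


@dataclass
class RegulationProfile:
    gene_id: str
    length_bp: int
    atac_count: int
    pop_count: int
    td: float  # transcriptional density, peaks/kb
    ptd: float  # post-transcriptional density, peaks/kb
    rr: Optional[float] = None
    log2_rr: Optional[float] = None
    category: Optional[str] = None

    @property
    def passes_filter(self) -> bool:
        return self.atac_count >= 1 and self.pop_count >= 1


def transcriptional_density(atac_count: int, length_bp: int) -> float:
    """Significant accessibility peaks per kb of gene length."""
    if length_bp < 1:
        raise ValueError("gene length must be positive")
    if atac_count < 0:
        raise ValueError("peak count must be nonnegative")
    return atac_count * 1000.0 / length_bp


def posttranscriptional_density(pop_count: int, length_bp: int) -> float:
    """Significant RNA-protein occupancy peaks per kb of gene length."""
    return transcriptional_density(pop_count, length_bp)


def regulation_ratio(pop_count: int, atac_count: int) -> float:
    """RR = pop_count / atac_count; requires both counts >= 1."""
    if pop_count < 1 or atac_count < 1:
        raise GeneFilterError(
            "regulation ratio is undefined for genes without at least one "
            "peak of each kind; exclude the gene (filter)"
        )
    return float(Fraction(pop_count, atac_count))


def classify(rr: float) -> str:
    """Three-way classification on RR."""
    if rr <= 0:
        raise ValueError("rr must be positive")
    if rr > 1:
        return POST_TRANSCRIPTIONAL
    if rr < 1:
        return TRANSCRIPTIONAL
    return BALANCED


def _category_from_counts(pop_count: int, atac_count: int) -> str:
    # exact integer comparison: no float misclassification at RR = 1
    if pop_count > atac_count:
        return POST_TRANSCRIPTIONAL
    if pop_count < atac_count:
        return TRANSCRIPTIONAL
    return BALANCED


def build_profiles(
    genes: Sequence[GeneRecord],
    atac: PeakSet,
    pop: PeakSet,
    upstream_bp: int = 5000,
    downstream_bp: int = 500,
    stranded: bool = True,
    min_overlap_bp: int = 1,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> list[RegulationProfile]:
    """Count peaks per gene and derive RR profiles (annotation order).

    ``atac`` and ``pop`` must already be significance-filtered. ATAC peaks
    are counted in the expanded window, POP peaks in the gene body.
    """
    if not genes:
        raise ValueError("empty gene set")
    expanded = [
        expand_window(
            g,
            upstream_bp,
            downstream_bp,
            chrom_length=None if chrom_lengths is None else chrom_lengths.get(g.chrom),
            stranded=stranded,
        )
        for g in genes
    ]
    bodies = [body_window(g) for g in genes]
    atac_counts = count_overlapping(atac, expanded, min_overlap_bp)
    pop_counts = count_overlapping(pop, bodies, min_overlap_bp)

    profiles = []
    for g in genes:
        a, p = atac_counts[g.gene_id], pop_counts[g.gene_id]
        prof = RegulationProfile(
            gene_id=g.gene_id,
            length_bp=g.length_bp,
            atac_count=a,
            pop_count=p,
            td=transcriptional_density(a, g.length_bp),
            ptd=posttranscriptional_density(p, g.length_bp),
        )
        if prof.passes_filter:
            prof.rr = regulation_ratio(p, a)
            prof.log2_rr = math.log2(p) - math.log2(a)
            prof.category = _category_from_counts(p, a)
        profiles.append(prof)

    logger.info("profiles: %s", summarize_profiles(profiles))
    return profiles


def summarize_profiles(profiles: Sequence[RegulationProfile]) -> dict:
    """Run summary: totals and the category split over passing genes."""
    passing = [p for p in profiles if p.passes_filter]
    counts = {c: sum(1 for p in passing if p.category == c) for c in CATEGORIES}
    pct = {
        c: (100.0 * counts[c] / len(passing)) if passing else float("nan")
        for c in CATEGORIES
    }
    return {
        "n_genes": len(profiles),
        "n_passing": len(passing),
        "category_counts": counts,
        "category_pct": pct,
    }


def density_correlation(profiles: Sequence[RegulationProfile]) -> dict:
    """Pearson correlation of log10 densities over passing genes.

    Both densities are strictly positive for passing genes, so the logs are
    finite. Degenerate (zero-variance) input is reported as undefined.
    """
    passing = [p for p in profiles if p.passes_filter]
    if len(passing) < 3:
        raise ValueError("need at least 3 passing profiles")
    x = np.log10([p.td for p in passing])
    y = np.log10([p.ptd for p in passing])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"pearson_r": float("nan"), "r_squared": float("nan"),
                "n": len(passing), "defined": False}
    r = stats.pearsonr(x, y).statistic
    return {"pearson_r": float(r), "r_squared": float(r * r),
            "n": len(passing), "defined": True}


# ---------------------------------------------------------------------------
# Profile TSV round-trip

_PROFILE_COLUMNS = [
    "gene_id", "length_bp", "atac_count", "pop_count",
    "td", "ptd", "rr", "log2_rr", "category", "passes_filter",
]


def write_profiles(profiles: Iterable[RegulationProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        rows.append({
            "gene_id": p.gene_id,
            "length_bp": p.length_bp,
            "atac_count": p.atac_count,
            "pop_count": p.pop_count,
            "td": repr(p.td),
            "ptd": repr(p.ptd),
            "rr": "" if p.rr is None else repr(p.rr),
            "log2_rr": "" if p.log2_rr is None else repr(p.log2_rr),
            "category": p.category or "",
            "passes_filter": str(p.passes_filter),
        })
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[RegulationProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        out.append(RegulationProfile(
            gene_id=r["gene_id"],
            length_bp=int(r["length_bp"]),
            atac_count=int(r["atac_count"]),
            pop_count=int(r["pop_count"]),
            td=float(r["td"]),
            ptd=float(r["ptd"]),
            rr=float(r["rr"]) if r["rr"] else None,
            log2_rr=float(r["log2_rr"]) if r["log2_rr"] else None,
            category=r["category"] or None,
        ))
    return out
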