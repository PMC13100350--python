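"""Peak input: narrowPeak / BED parsing, FDR filtering, interval overlap counts.

ATAC-seq peaks arrive as ENCODE narrowPeak (MACS3 dialect: columns 8 and 9
carry -log10 p and -log10 q); RNA-protein occupancy (POP-seq) peaks arrive as
BED6+ with a raw p-value column (Piranha dialect). Significance filtering
keeps peaks at FDR-corrected p < alpha, either by trusting caller-supplied
q-values or by Benjamini-Hochberg adjustment of raw p-values across the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .annotation_io import GeneWindow

logger = logging.getLogger(__name__)

ATAC = "atac"
POP = "pop"


class PeakFormatError(ValueError):
    """Raised for unparseable peak files or missing significance fields."""


@dataclass
class PeakRecord:
    """One called peak. Coordinates are 0-based half-open.

    ``raw`` keeps the original tab-separated columns so retained rows can be
    written back bit-identically after filtering.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: Optional[float] = None
    p_value: Optional[float] = None
    q_value: Optional[float] = None
    source: str = ATAC
    raw: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PeakFormatError(
                f"peak {self.name}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class PeakSet:
    """Peaks from one assay plus a per-chromosome interval index."""

    source: str
    peaks: list[PeakRecord] = field(default_factory=list)
    n_rejected: int = 0
    _index: Optional[dict[str, IntervalTree]] = field(
        default=None, repr=False, compare=False
    )

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def index(self) -> dict[str, IntervalTree]:
        if self._index is None:
            trees: dict[str, IntervalTree] = {}
            for i, pk in enumerate(self.peaks):
                trees.setdefault(pk.chrom, IntervalTree()).addi(pk.start, pk.end, i)
            self._index = trees
        return self._index


def _parse_float(text: str, path, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise PeakFormatError(
            f"{path}: line {lineno}: non-numeric {what}: {text!r}"
        ) from exc


def load_narrowpeak(path: str | Path, source: str = ATAC) -> PeakSet:
    """Load an ENCODE narrowPeak (BED6+4) file.

    Columns 8/9 are -log10(p)/-log10(q); the sentinel -1 means "not
    computed" and maps to an absent value. Files without exactly 10 columns
    fall back to :func:`load_bed` with a warning.
    """
    with open(path) as fh:
        lines = fh.readlines()
    data = [
        (i, ln.rstrip("\n"))
        for i, ln in enumerate(lines, start=1)
        if ln.strip() and not ln.startswith(("#", "track", "browser"))
    ]
    if any(len(ln.split("\t")) != 10 for _, ln in data):
        logger.warning(
            "%s: not 10-column narrowPeak; falling back to generic BED", path
        )
        return load_bed(path, source=source)

    peaks = []
    for lineno, ln in data:
        f = ln.split("\t")
        neg_log_p = _parse_float(f[7], path, lineno, "-log10(p) column")
        neg_log_q = _parse_float(f[8], path, lineno, "-log10(q) column")
        peaks.append(
            PeakRecord(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                name=f[3],
                score=_parse_float(f[4], path, lineno, "score column"),
                p_value=None if neg_log_p == -1 else 10.0 ** (-neg_log_p),
                q_value=None if neg_log_q == -1 else 10.0 ** (-neg_log_q),
                source=source,
                raw=tuple(f),
            )
        )
    return PeakSet(source=source, peaks=peaks)


def load_bed(
    path: str | Path, source: str = POP, pvalue_col: Optional[int] = None
) -> PeakSet:
    """Load a generic BED3+ file; ``pvalue_col`` is a 1-based column index.

    Rows with start >= end are rejected with a warning and counted in
    ``n_rejected``.
    """
    peaks: list[PeakRecord] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            f = ln.split("\t")
            if len(f) < 3:
                raise PeakFormatError(
                    f"{path}: line {lineno}: fewer than 3 columns"
                )
            start, end = int(f[1]), int(f[2])
            if start >= end:
                logger.warning(
                    "%s: line %d: rejected degenerate interval [%d, %d)",
                    path,
                    lineno,
                    start,
                    end,
                )
                n_rejected += 1
                continue
            p_value = None
            if pvalue_col is not None:
                if len(f) < pvalue_col:
                    raise PeakFormatError(
                        f"{path}: line {lineno}: p-value column {pvalue_col} absent"
                    )
                p_value = _parse_float(f[pvalue_col - 1], path, lineno, "p-value")
            peaks.append(
                PeakRecord(
                    chrom=f[0],
                    start=start,
                    end=end,
                    name=f[3] if len(f) > 3 else ".",
                    score=float(f[4]) if len(f) > 4 and f[4] != "." else None,
                    p_value=p_value,
                    source=source,
                    raw=tuple(f),
                )
            )
    return PeakSet(source=source, peaks=peaks, n_rejected=n_rejected)


def concat_peaksets(peaksets: Sequence[PeakSet]) -> PeakSet:
    """Concatenate record lists (no interval merging)."""
    sources = {ps.source for ps in peaksets}
    if len(sources) != 1:
        raise ValueError("cannot concatenate peak sets from different assays")
    merged = PeakSet(source=sources.pop())
    for ps in peaksets:
        merged.peaks.extend(ps.peaks)
        merged.n_rejected += ps.n_rejected
    return merged


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    """Write peaks back out; rows loaded from a file are reproduced verbatim."""
    with open(path, "w") as fh:
        for pk in peakset.peaks:
            if pk.raw is not None:
                fh.write("\t".join(pk.raw) + "\n")
            else:
                fields = [pk.chrom, str(pk.start), str(pk.end), pk.name]
                if pk.score is not None:
                    fields.append(repr(pk.score))
                fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Significance filtering


def filter_significant(
    peakset: PeakSet, alpha: float = 0.05, method: str = "use_q"
) -> PeakSet:
    """Keep peaks significant at FDR-corrected p < ``alpha`` (strict).

    ``use_q`` trusts caller-supplied q-values (MACS3 narrowPeak);
    ``bh_on_p`` applies Benjamini-Hochberg across all raw p-values in the
    set (Piranha BED output carries only raw p). Input order is preserved.
    """
    if method not in {"use_q", "bh_on_p"}:
        raise ValueError(f"unknown filter method {method!r}")
    if not peakset.peaks:
        return PeakSet(source=peakset.source)

    if method == "use_q":
        for pk in peakset.peaks:
            if pk.q_value is None:
                raise PeakFormatError(
                    f"peak {pk.name} ({pk.chrom}:{pk.start}-{pk.end}) lacks a "
                    f"q-value; cannot filter with method 'use_q'"
                )
        kept = [pk for pk in peakset.peaks if pk.q_value < alpha]
    else:
        for pk in peakset.peaks:
            if pk.p_value is None:
                raise PeakFormatError(
                    f"peak {pk.name} ({pk.chrom}:{pk.start}-{pk.end}) lacks a "
                    f"p-value; cannot filter with method 'bh_on_p'"
                )
        p = np.array([pk.p_value for pk in peakset.peaks])
        adjusted = stats.false_discovery_control(p, method="bh")
        kept = [pk for pk, q in zip(peakset.peaks, adjusted) if q < alpha]
    return PeakSet(source=peakset.source, peaks=kept)


# ---------------------------------------------------------------------------
# Overlap counting


def count_overlapping(
    peakset: PeakSet,
    windows: Iterable[GeneWindow],
    min_overlap_bp: int = 1,
) -> dict[str, int]:
    """Count peaks overlapping each window by >= ``min_overlap_bp`` bases.

    A peak overlapping k windows contributes to all k counts — peaks in
    overlapping expanded gene boundaries are counted for every such gene.
    Windows on chromosomes absent from the peak set get count 0.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    index = peakset.index
    counts: dict[str, int] = {}
    for w in windows:
        tree = index.get(w.chrom)
        n = 0
        if tree is not None:
            for iv in tree.overlap(w.start, w.end):
                if min(iv.end, w.end) - max(iv.begin, w.start) >= min_overlap_bp:
                    n += 1
        counts[w.gene_id] = n
    return counts
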