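"""Gene-model input: GTF parsing, covariate joins, and gene windows.

All coordinates inside the package are 0-based half-open (BED convention).
GTF input (1-based, closed) is converted on load. "Upstream"/"downstream"
are strand-aware by default: upstream of the TSS, downstream of the gene's
3' end; an unstranded mode treats upstream as lower-coordinate side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: default expanded-boundary margins (bp): promoter/enhancer capture upstream,
#: short downstream extension past the 3' end
DEFAULT_UPSTREAM_BP = 5000
DEFAULT_DOWNSTREAM_BP = 500


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent gene annotation input."""


@dataclass
class GeneRecord:
    """One gene: span, strand, transcript biotypes and optional covariates.

    ``start``/``end`` are 0-based half-open. ``biotypes`` is a multiset
    (one label per annotated transcript, Ensembl vocabulary) stored as a
    tuple in annotation order.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotypes: tuple[str, ...] = ()
    isoform_count: Optional[int] = None
    fpkm: Optional[float] = None
    protein_expr: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneWindow:
    """A genomic window attributed to a gene: the body or the expanded boundary."""

    gene_id: str
    chrom: str
    start: int
    end: int
    kind: str  # "expanded" or "body"


def expand_window(
    gene: GeneRecord,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
    chrom_length: Optional[int] = None,
    stranded: bool = True,
) -> GeneWindow:
    """Expanded gene boundary for accessibility-peak counting.

    Extends the gene body ``upstream_bp`` on the promoter side and
    ``downstream_bp`` past the 3' end (mirrored for - strand genes when
    ``stranded``). Bounds are clipped at 0 and ``chrom_length``.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window margins must be nonnegative")
    if stranded and gene.strand == "-":
        lo, hi = gene.start - downstream_bp, gene.end + upstream_bp
    else:
        lo, hi = gene.start - upstream_bp, gene.end + downstream_bp
    lo = max(0, lo)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return GeneWindow(gene.gene_id, gene.chrom, lo, hi, "expanded")


def body_window(gene: GeneRecord) -> GeneWindow:
    """The gene's own span, used for RNA-protein occupancy peak counting."""
    return GeneWindow(gene.gene_id, gene.chrom, gene.start, gene.end, "body")


# ---------------------------------------------------------------------------
# GTF loading


def _parse_gtf_features(gtf_path: str | Path):
    """Yield (line_number, gffutils Feature) for each feature line."""
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if line.count("\t") < 8:
                raise AnnotationError(
                    f"{gtf_path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields"
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationError(
                    f"{gtf_path}: malformed GTF line {lineno}: {exc}"
                ) from exc
            yield lineno, feat


def _attr(feat, *names: str) -> Optional[str]:
    for name in names:
        vals = feat.attributes.get(name)
        if vals:
            return vals[0]
    return None


def load_gene_annotation(
    gtf_path: str | Path,
    isoform_table: Optional[str | Path] = None,
    fpkm_table: Optional[str | Path] = None,
    protein_table: Optional[str | Path] = None,
) -> list[GeneRecord]:
    """Load gene records from an Ensembl-dialect GTF, with optional covariates.

    ``gene`` features become records; ``transcript`` features contribute one
    biotype label each (``transcript_biotype`` or ``transcript_type``
    attribute) and set ``isoform_count``. Covariate tables are two-column
    TSVs (gene_id, value) with a header; rows for unknown genes are dropped
    with a warning. Returns records in annotation order.
    """
    records: dict[str, GeneRecord] = {}
    transcript_labels: dict[str, list[str]] = {}

    for lineno, feat in _parse_gtf_features(gtf_path):
        gene_id = _attr(feat, "gene_id")
        if gene_id is None:
            raise AnnotationError(
                f"{gtf_path}: line {lineno}: feature lacks gene_id attribute"
            )
        if feat.featuretype == "gene":
            if gene_id in records:
                raise AnnotationError(
                    f"{gtf_path}: line {lineno}: duplicate gene_id {gene_id!r}"
                )
            strand = feat.strand if feat.strand in {"+", "-"} else None
            if strand is None:
                logger.warning(
                    "gene %s has no strand annotation; treating as + strand",
                    gene_id,
                )
                strand = "+"
            records[gene_id] = GeneRecord(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GTF 1-based closed -> 0-based half-open
                end=feat.end,
                strand=strand,
            )
        elif feat.featuretype == "transcript":
            label = _attr(feat, "transcript_biotype", "transcript_type")
            transcript_labels.setdefault(gene_id, []).append(
                label if label is not None else "unknown"
            )

    if not records:
        raise AnnotationError(f"{gtf_path}: no gene features found")

    for gene_id, labels in transcript_labels.items():
        if gene_id not in records:
            logger.warning(
                "transcripts reference unknown gene %s; ignored", gene_id
            )
            continue
        rec = records[gene_id]
        records[gene_id] = replace(
            rec, biotypes=tuple(labels), isoform_count=len(labels)
        )

    genes = list(records.values())
    _join_covariate(genes, isoform_table, "isoform_count", int)
    _join_covariate(genes, fpkm_table, "fpkm", float)
    _join_covariate(genes, protein_table, "protein_expr", float)
    return genes


def _join_covariate(genes: list[GeneRecord], path, attr: str, cast) -> None:
    """Left-join a two-column (gene_id, value) TSV onto the gene list, in place."""
    if path is None:
        return
    table = pd.read_csv(path, sep="\t", header=0)
    if table.shape[1] != 2:
        raise AnnotationError(f"{path}: covariate table must have 2 columns")
    table.columns = ["gene_id", "value"]
    known = {g.gene_id: i for i, g in enumerate(genes)}
    dropped = 0
    for gene_id, value in zip(table["gene_id"], table["value"]):
        idx = known.get(str(gene_id))
        if idx is None:
            dropped += 1
            continue
        if pd.isna(value):
            continue
        genes[idx] = replace(genes[idx], **{attr: cast(value)})
    if dropped:
        logger.warning(
            "%s: %d covariate rows for gene_ids absent from annotation dropped",
            path,
            dropped,
        )


# ---------------------------------------------------------------------------
# Internal TSV round-trip representation

_GENE_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "biotypes",
    "isoform_count",
    "fpkm",
    "protein_expr",
]


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "biotypes": ",".join(g.biotypes),
                "isoform_count": "" if g.isoform_count is None else g.isoform_count,
                "fpkm": "" if g.fpkm is None else repr(g.fpkm),
                "protein_expr": "" if g.protein_expr is None else repr(g.protein_expr),
            }
        )
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    genes = []
    for _, row in df.iterrows():
        genes.append(
            GeneRecord(
                gene_id=row["gene_id"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                biotypes=tuple(row["biotypes"].split(",")) if row["biotypes"] else (),
                isoform_count=int(row["isoform_count"]) if row["isoform_count"] else None,
                fpkm=float(row["fpkm"]) if row["fpkm"] else None,
                protein_expr=float(row["protein_expr"]) if row["protein_expr"] else None,
            )
        )
    return genes
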