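"""Pre-ranked gene list export for external gene-set enrichment analysis.

Writes the two-column, headerless .rnk format (gene_id, log2 RR) that
GSEA's pre-ranked mode consumes, sorted by score descending with ties broken
by gene id. Running GSEA itself is out of scope; this module only prepares
its input. An optional id-mapping table can translate annotation ids to the
symbols a gene-set collection expects.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

from .regulation_metrics import RegulationProfile


def ranked_entries(
    profiles: Sequence[RegulationProfile],
    id_map: Optional[Mapping[str, str]] = None,
) -> list[tuple[str, float]]:
    """(gene_id, log2_rr) for passing genes, descending, gene-id tie-break."""
    entries = []
    seen = set()
    for p in profiles:
        if not p.passes_filter:
            continue
        gene_id = id_map.get(p.gene_id, p.gene_id) if id_map else p.gene_id
        if gene_id in seen:
            raise ValueError(f"duplicate gene id in ranked list: {gene_id!r}")
        seen.add(gene_id)
        entries.append((gene_id, p.log2_rr))
    if not entries:
        raise ValueError("no passing profiles to rank")
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries


def export_rnk(
    profiles: Sequence[RegulationProfile],
    path: str | Path,
    id_map: Optional[Mapping[str, str]] = None,
) -> list[tuple[str, float]]:
    """Write the ranked list as .rnk (tab-separated, no header)."""
    entries = ranked_entries(profiles, id_map=id_map)
    with open(path, "w") as fh:
        for gene_id, score in entries:
            fh.write(f"{gene_id}\t{score:.6f}\n")
    return entries


def read_rnk(path: str | Path) -> list[tuple[str, float]]:
    entries = []
    with open(path) as fh:
        for line in fh:
            gene_id, score = line.rstrip("\n").split("\t")
            entries.append((gene_id, float(score)))
    return entries
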