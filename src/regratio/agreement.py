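"""Cross-sample concordance of regulatory classifications.

Given RR profiles from two or more samples (cell lines), restricts to the
genes passing the peak filter in every sample and breaks the classification
agreement down into: full agreement (identical category everywhere),
exactly-one-pair agreement (that pair matches, everyone else differs), and
no agreement. For three samples these classes partition the common gene set,
which is what lets the percentages sum to 100.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .regulation_metrics import RegulationProfile

FULL = "full"
NONE = "none"
MULTI = "multi_pair"  # only reachable with >= 4 samples


@dataclass
class AgreementSummary:
    samples: tuple[str, ...]
    common_genes: int
    full_agreement_pct: float
    pairwise_agreement_pct: dict[tuple[str, str], float]
    none_pct: float
    multi_pair_pct: float
    per_gene: dict[str, tuple[str, ...]]  # gene_id -> category vector


def intersect_passing(
    profile_sets: Sequence[Sequence[RegulationProfile]],
) -> list[str]:
    """Gene ids passing the filter in every profile set (sorted)."""
    if len(profile_sets) < 2:
        raise ValueError("need >= 2 profile sets")
    common = None
    for profiles in profile_sets:
        ids = {p.gene_id for p in profiles if p.passes_filter}
        common = ids if common is None else common & ids
    return sorted(common)


def classify_vector(categories: Sequence[str]) -> str:
    """Agreement class of one gene's category vector across samples."""
    k = len(categories)
    if len(set(categories)) == 1:
        return FULL
    agreeing = [
        (i, j)
        for i, j in itertools.combinations(range(k), 2)
        if categories[i] == categories[j]
    ]
    if not agreeing:
        return NONE
    if len(agreeing) == 1:
        return f"pair_{agreeing[0][0]}_{agreeing[0][1]}"
    return MULTI


def agreement_breakdown(
    profile_sets: Sequence[Sequence[RegulationProfile]],
    names: Optional[Sequence[str]] = None,
) -> AgreementSummary:
    """Agreement breakdown over genes passing the filter in all samples."""
    k = len(profile_sets)
    if names is None:
        names = tuple(f"sample{i + 1}" for i in range(k))
    names = tuple(names)
    if len(names) != k:
        raise ValueError("one name per profile set required")

    common = intersect_passing(profile_sets)
    if not common:
        raise ValueError("no gene passes the filter in every sample")

    maps = [
        {p.gene_id: p.category for p in profiles if p.passes_filter}
        for profiles in profile_sets
    ]
    per_gene = {g: tuple(m[g] for m in maps) for g in common}

    n = len(common)
    counts = {FULL: 0, NONE: 0, MULTI: 0}
    pair_counts = {
        (names[i], names[j]): 0 for i, j in itertools.combinations(range(k), 2)
    }
    for vec in per_gene.values():
        cls = classify_vector(vec)
        if cls.startswith("pair_"):
            _, i, j = cls.split("_")
            pair_counts[(names[int(i)], names[int(j)])] += 1
        else:
            counts[cls] += 1

    pct = lambda c: 100.0 * c / n
    return AgreementSummary(
        samples=names,
        common_genes=n,
        full_agreement_pct=pct(counts[FULL]),
        pairwise_agreement_pct={pair: pct(c) for pair, c in pair_counts.items()},
        none_pct=pct(counts[NONE]),
        multi_pair_pct=pct(counts[MULTI]),
        per_gene=per_gene,
    )
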