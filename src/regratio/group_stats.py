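"""Nonparametric group comparisons and transcript-biotype enrichment.

Covers the statistics used to contrast covariates (gene length, isoform
count, transcript abundance, protein expression, peak densities) across the
three regulatory categories: Mann-Whitney U (exact by full enumeration for
small samples, normal approximation with tie correction otherwise),
Kruskal-Wallis, Cliff's delta effect sizes, Bonferroni correction, median
fold changes, and Fisher's-exact-test biotype enrichment with odds ratios.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation_io import GeneRecord
from .regulation_metrics import (
    BALANCED,
    CATEGORIES,
    POST_TRANSCRIPTIONAL,
    TRANSCRIPTIONAL,
    RegulationProfile,
)

logger = logging.getLogger(__name__)

#: below this pooled sample size the Mann-Whitney p is computed by full
#: enumeration of group assignments (handles ties exactly)
EXACT_MWU_TOTAL_N = 16

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}

#: pairwise comparison order: trans vs balanced, post vs balanced,
#: trans vs post (the conventional reporting order)
PAIR_ORDER = (
    (TRANSCRIPTIONAL, BALANCED),
    (POST_TRANSCRIPTIONAL, BALANCED),
    (TRANSCRIPTIONAL, POST_TRANSCRIPTIONAL),
)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x over y: #{x_i > y_j} + 0.5 #{x_i = y_j} via midranks."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _exact_mwu_tails(x: np.ndarray, y: np.ndarray, u_obs: float) -> tuple[float, float]:
    """(P[U >= u_obs], P[U <= u_obs]) over all group assignments of the pool."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    offset = n * (n + 1) / 2.0
    total = ge = le = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if u >= u_obs - 1e-9:
            ge += 1
        if u <= u_obs + 1e-9:
            le += 1
    return ge / total, le / total


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> dict:
    """Mann-Whitney U test; U counts pairs with x above y (ties count 1/2).

    The p-value is exact (full enumeration, tie-aware) when the pooled
    sample size is at most ``EXACT_MWU_TOTAL_N``, otherwise the normal
    approximation with tie correction is used.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")

    u = _u_statistic(x, y)
    if x.size + y.size <= EXACT_MWU_TOTAL_N:
        p_ge, p_le = _exact_mwu_tails(x, y, u)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative=_ALTERNATIVES[alternative], method="asymptotic"
        )
        p = float(res.pvalue)
        method = "asymptotic"
    return {"u": u, "p": p, "method": method}


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> dict:
    """Kruskal-Wallis H (tie-corrected) with a chi-square p-value.

    With every observation identical the statistic degenerates (the tie
    correction divides by zero); H is reported as 0 and p as undefined
    (NaN).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 nonempty groups")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return {"h": 0.0, "p": float("nan")}
    h, p = stats.kruskal(*arrays)
    return {"h": float(h), "p": float(p)}


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (n*m), in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    # chunk the broadcast so n*m pair matrices stay modest
    total = 0.0
    step = max(1, int(4e6 // max(1, y.size)))
    for i in range(0, x.size, step):
        total += np.sign(x[i : i + step, None] - y[None, :]).sum()
    return float(total / (x.size * y.size))


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni correction: p -> min(1, m*p); m defaults to len(p_values)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p-value out of (0, 1]: {p}")
    return [min(1.0, m * p) for p in p_values]


def median_fold_change(x: Sequence[float], y: Sequence[float]) -> float:
    """median(x) / median(y)."""
    med_y = float(np.median(np.asarray(y, dtype=float)))
    if med_y <= 0:
        raise ValueError("median of the denominator sample must be positive")
    return float(np.median(np.asarray(x, dtype=float))) / med_y


def density_contrast(profiles: Sequence[RegulationProfile]) -> dict:
    """Contrast the two per-gene density distributions over passing genes.

    Compares post-transcriptional vs transcriptional peak density with a
    Mann-Whitney U test, the median fold change, and Cliff's delta.
    """
    passing = [p for p in profiles if p.passes_filter]
    if len(passing) < 2:
        raise ValueError("need >= 2 passing profiles")
    ptd = [p.ptd for p in passing]
    td = [p.td for p in passing]
    mwu = mann_whitney_u(ptd, td)
    return {
        "u": mwu["u"],
        "p": mwu["p"],
        "median_fold_change": median_fold_change(ptd, td),
        "cliffs_delta": cliffs_delta(ptd, td),
        "n": len(passing),
    }


# ---------------------------------------------------------------------------
# Covariate comparison across the three categories


@dataclass
class PairwiseResult:
    u_statistic: float
    p_raw: float
    p_bonferroni: float
    cliffs_delta: float


@dataclass
class CategoryComparison:
    covariate: str
    kw_h: float
    kw_p: float
    n_per_category: dict[str, int]
    n_missing: int
    medians: dict[str, float]
    pairwise: dict[tuple[str, str], PairwiseResult]
    fold_changes: dict[tuple[str, str], float]


def _covariate_values(
    profiles: Sequence[RegulationProfile],
    covariate: str,
    genes: Optional[Mapping[str, GeneRecord]],
    values: Optional[Mapping[str, float]],
) -> tuple[dict[str, list[float]], int]:
    groups: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    n_missing = 0
    for prof in profiles:
        if not prof.passes_filter:
            continue
        if covariate == "length_bp":
            v = prof.length_bp
        elif values is not None:
            v = values.get(prof.gene_id)
        elif genes is not None:
            v = getattr(genes[prof.gene_id], covariate)
        else:
            raise ValueError(
                f"covariate {covariate!r} needs a gene collection or a "
                f"values mapping"
            )
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_missing += 1
            continue
        groups[prof.category].append(float(v))
    return groups, n_missing


def compare_covariate(
    profiles: Sequence[RegulationProfile],
    covariate: str,
    genes: Optional[Mapping[str, GeneRecord]] = None,
    values: Optional[Mapping[str, float]] = None,
) -> CategoryComparison:
    """Compare one covariate across the regulatory categories.

    Runs Kruskal-Wallis over the populated categories, then pairwise
    Mann-Whitney U tests (Bonferroni-corrected over the pairs run, three in
    the usual case) with Cliff's delta and median fold changes. Genes
    missing the covariate are excluded and counted in ``n_missing``; an
    empty category degrades the comparison to the populated pair(s) with a
    warning.
    """
    groups, n_missing = _covariate_values(profiles, covariate, genes, values)
    populated = [c for c in CATEGORIES if groups[c]]
    if len(populated) < 2:
        raise ValueError("need >= 2 populated categories")
    if len(populated) < len(CATEGORIES):
        logger.warning(
            "covariate %s: categories %s empty; comparing %s only",
            covariate,
            sorted(set(CATEGORIES) - set(populated)),
            populated,
        )

    kw = kruskal_wallis([groups[c] for c in populated])
    medians = {c: float(np.median(groups[c])) for c in populated}

    pairs = [p for p in PAIR_ORDER if p[0] in populated and p[1] in populated]
    raw = {}
    for a, b in pairs:
        raw[(a, b)] = mann_whitney_u(groups[a], groups[b])
    corrected = bonferroni([raw[p]["p"] for p in pairs], m=len(pairs))
    pairwise = {}
    fold_changes = {}
    for (a, b), p_bonf in zip(pairs, corrected):
        pairwise[(a, b)] = PairwiseResult(
            u_statistic=raw[(a, b)]["u"],
            p_raw=raw[(a, b)]["p"],
            p_bonferroni=p_bonf,
            cliffs_delta=cliffs_delta(groups[a], groups[b]),
        )
        fold_changes[(a, b)] = median_fold_change(groups[a], groups[b])

    return CategoryComparison(
        covariate=covariate,
        kw_h=kw["h"],
        kw_p=kw["p"],
        n_per_category={c: len(groups[c]) for c in CATEGORIES},
        n_missing=n_missing,
        medians=medians,
        pairwise=pairwise,
        fold_changes=fold_changes,
    )


# ---------------------------------------------------------------------------
# Transcript-biotype enrichment


@dataclass
class EnrichmentResult:
    label: str
    category: str
    in_category_with_label: int
    in_category_without: int
    background_with_label: int
    background_without: int
    odds_ratio: float
    p_value: float
    abundance_pct: float
    zero_cell_corrected: bool = False


def biotype_enrichment(
    profiles: Sequence[RegulationProfile],
    genes: Mapping[str, GeneRecord],
    background: Optional[Counter] = None,
    min_abundance_pct: float = 1.0,
) -> list[EnrichmentResult]:
    """Transcript-type enrichment per regulatory category.

    Counting units are transcripts (a gene contributes one count per
    annotated transcript). Per category, labels whose abundance share is at
    most ``min_abundance_pct`` percent are dropped; each retained (label,
    category) yields a 2x2 transcript-count table (category vs background,
    label vs not) tested with Fisher's exact test. The background defaults
    to all transcripts of all genes in the annotation. A zero cell gets the
    Haldane-Anscombe 0.5 correction for the odds ratio and is flagged.
    """
    if background is None:
        background = Counter()
        for g in genes.values():
            background.update(g.biotypes)
    bg_total = sum(background.values())
    if bg_total == 0:
        raise ValueError("background has no transcripts")

    by_category: dict[str, Counter] = {c: Counter() for c in CATEGORIES}
    for prof in profiles:
        if not prof.passes_filter:
            continue
        gene = genes.get(prof.gene_id)
        if gene is None:
            raise KeyError(f"profile gene {prof.gene_id} absent from annotation")
        by_category[prof.category].update(gene.biotypes)

    results = []
    for category in CATEGORIES:
        counts = by_category[category]
        cat_total = sum(counts.values())
        if cat_total == 0:
            continue
        labels = sorted(counts, key=lambda lb: (-counts[lb], lb))
        for label in labels:
            abundance_pct = 100.0 * counts[label] / cat_total
            if abundance_pct <= min_abundance_pct:
                continue
            a = counts[label]
            b = cat_total - a
            c = background[label]
            d = bg_total - c
            p = float(stats.fisher_exact([[a, b], [c, d]]).pvalue)
            corrected = False
            if min(a, b, c, d) == 0:
                a2, b2, c2, d2 = (v + 0.5 for v in (a, b, c, d))
                odds = (a2 * d2) / (b2 * c2)
                corrected = True
            else:
                odds = (a * d) / (b * c)
            results.append(
                EnrichmentResult(
                    label=label,
                    category=category,
                    in_category_with_label=a,
                    in_category_without=b,
                    background_with_label=c,
                    background_without=d,
                    odds_ratio=float(odds),
                    p_value=p,
                    abundance_pct=abundance_pct,
                    zero_cell_corrected=corrected,
                )
            )
    return results
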