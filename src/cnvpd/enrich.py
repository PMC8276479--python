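"""Overlap of CNVRs with gene/QTL annotations and category
over/under-representation tests.

Representation of a category (a GO-style term or a QTL trait class) among
the features overlapping CNVRs is tested with a two-sided exact binomial
test against the category's genome-wide proportion, Bonferroni-corrected
across the categories tested. The two-sided p-value follows the minimum-
likelihood convention: the sum of all outcome probabilities not exceeding
the observed outcome's probability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import Cnvr, FeatureRecord

#: Symbols the gene-level analysis drops by default: hypothetical /
#: putative / predicted / uncharacterized genes, pseudogenes, and LOC ids.
DEFAULT_GENE_EXCLUDES = (
    r"^LOC\d+",
    r"(?i)hypothetical",
    r"(?i)putative",
    r"(?i)predicted",
    r"(?i)uncharacteri[sz]ed",
    r"(?i)pseudo",
)


def exclude_gene_symbols(
    features: Iterable[FeatureRecord],
    patterns: Sequence[str] = DEFAULT_GENE_EXCLUDES,
) -> list[FeatureRecord]:
    """Drop features whose id matches any exclude regex."""
    regs = [re.compile(p) for p in patterns]
    return [f for f in features if not any(r.search(f.feature_id) for r in regs)]


def overlap_features(
    cnvrs: Sequence[Cnvr],
    features: Sequence[FeatureRecord],
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """All (feature, CNVR) pairs overlapping by >= ``min_overlap_bp``.

    Columns: feature_id, category, cnvr_id, overlap_bp, cnvr_type_class.
    Intervals are half-open, so adjacent intervals do not overlap.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for r in cnvrs:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
    rows = []
    for f in features:
        tree = trees.get(f.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(f.start, f.end)):
            r: Cnvr = iv.data
            ov = min(f.end, r.end) - max(f.start, r.start)
            if ov >= min_overlap_bp:
                rows.append(
                    (f.feature_id, f.category, r.cnvr_id, ov, r.type_class.value)
                )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "category", "cnvr_id", "overlap_bp", "cnvr_type_class"],
    )


def most_significant_cnvr_per_gene(
    overlaps: pd.DataFrame, kw_table: pd.DataFrame
) -> pd.DataFrame:
    """One CNVR per gene: among a gene's overlapping CNVRs keep the one
    most significant in the Kruskal-Wallis test (smallest p; ties broken by
    larger H, then lexicographically smallest cnvr_id)."""
    kw = kw_table.set_index("cnvr_id")
    missing = set(overlaps["cnvr_id"]) - set(kw.index)
    if missing:
        raise ValueError(f"missing Kruskal-Wallis results for {sorted(missing)[:5]}")
    merged = overlaps.merge(
        kw[["pvalue", "h_statistic"]], left_on="cnvr_id", right_index=True
    )
    merged = merged.sort_values(
        ["feature_id", "pvalue", "h_statistic", "cnvr_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = merged.drop_duplicates(subset="feature_id", keep="first")
    return best[["feature_id", "cnvr_id", "pvalue", "h_statistic"]].reset_index(
        drop=True
    )


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    category: str
    n_observed: int
    n_total_in_annotation: int
    n_selected: int
    expected_p: float
    pvalue_raw: float
    pvalue_bonferroni: float
    direction: str  # "over" | "under"
    tie: bool = False  # observed exactly matches expectation


def binomial_representation(
    category_counts_selected: Mapping[str, int],
    category_counts_total: Mapping[str, int],
    *,
    n_selected: int | None = None,
    n_total: int | None = None,
) -> list[EnrichmentResult]:
    """Two-sided binomial over/under-representation per category.

    For each category, ``expected_p`` is its share of the whole annotation;
    the observed count among the ``n_selected`` CNVR-overlapping features is
    tested against Binomial(n_selected, expected_p). Bonferroni multiplies
    by the number of categories tested (all keys of
    ``category_counts_total``). Features may carry several categories, so
    counts may sum to more than the number of distinct features.
    """
    total_all = n_total if n_total is not None else sum(category_counts_total.values())
    selected_all = (
        n_selected if n_selected is not None else sum(category_counts_selected.values())
    )
    if total_all <= 0:
        raise ValueError("total annotation is empty")
    unknown = set(category_counts_selected) - set(category_counts_total)
    if unknown:
        raise ValueError(f"categories absent from total annotation: {sorted(unknown)}")
    n_categories = len(category_counts_total)
    results = []
    for category in sorted(category_counts_total):
        total = category_counts_total[category]
        if total <= 0:
            raise ValueError(f"category {category!r} has nonpositive total {total}")
        observed = int(category_counts_selected.get(category, 0))
        if observed > selected_all:
            raise ValueError(
                f"category {category!r}: observed {observed} exceeds n_selected"
            )
        expected_p = total / total_all
        p_raw = float(
            stats.binomtest(observed, selected_all, expected_p).pvalue
        )
        expected = selected_all * expected_p
        tie = observed == expected
        direction = "over" if observed >= expected else "under"
        results.append(
            EnrichmentResult(
                category=category,
                n_observed=observed,
                n_total_in_annotation=total,
                n_selected=selected_all,
                expected_p=expected_p,
                pvalue_raw=p_raw,
                pvalue_bonferroni=min(1.0, p_raw * n_categories),
                direction=direction,
                tie=tie,
            )
        )
    return results


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in results])


def category_counts(
    features: Iterable[FeatureRecord], *, split: str | None = None
) -> dict[str, int]:
    """Count features per category label; ``split`` optionally splits
    multi-label category strings (e.g. comma-separated GO terms)."""
    counts: dict[str, int] = {}
    for f in features:
        cats = f.category.split(split) if split else [f.category]
        for cat in cats:
            cat = cat.strip()
            if cat:
                counts[cat] = counts.get(cat, 0) + 1
    return counts


def term_gene_counts(
    term2gene: pd.DataFrame, genes: Iterable[str]
) -> tuple[dict[str, int], int]:
    """Per-term counts restricted to ``genes`` from a term->gene mapping
    table (columns: term, gene). Returns (counts, n distinct genes hit)."""
    if not {"term", "gene"}.issubset(term2gene.columns):
        raise ValueError("term->gene mapping needs columns 'term' and 'gene'")
    genes = set(genes)
    sub = term2gene[term2gene["gene"].isin(genes)]
    counts = sub.groupby("term")["gene"].nunique().to_dict()
    return {str(k): int(v) for k, v in counts.items()}, int(sub["gene"].nunique())
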