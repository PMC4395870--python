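"""Tiling-array region classification of splicing misregulation.

Probe-level intensities from two genotypes (wild type and a
splicing-factor mutant) are averaged per annotated gene region (exon or
intron); the region fold change is the mutant/wild-type ratio of those
means.  Regions are called at a fold threshold (default 1.5, strict
inequality, symmetric on the log scale for down-calls):

* exon  with fold > 1.5          -> ``exon_up``
* exon  with fold < 1/1.5        -> ``exon_down``
* intron with fold > 1.5         -> ``intron_up``   (intron retention)
* anything else                  -> ``none``

There is no intron-down category: loss of an unspliced intron signal has
no interpretation in this design.  A gene enters a category when at least
one of its regions carries it; genes in several categories are counted in
each and reported separately.  Because a splicing factor's direct targets
are expected among genes with multiple isoforms, each category's
proportion of alternatively spliced (AS) genes is compared between
categories (chi-square, 2x2 with continuity correction, exact fallback
for small expectations) and against the genome-wide AS background
(~25%, exact binomial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "region_fold_changes",
    "classify_regions",
    "aggregate_genes",
    "as_proportion",
    "as_enrichment",
    "CATEGORIES",
]

log = logging.getLogger(__name__)

CATEGORIES = ("exon_up", "exon_down", "intron_up")

REQUIRED_PROBE_COLUMNS = ("gene", "region_id", "region_type", "genotype", "intensity")


class SpliceDataError(ValueError):
    """Raised when probe tables violate the expected layout."""


def region_fold_changes(
    probes: pd.DataFrame,
    wt_label: str = "wt",
    mut_label: str = "mut",
) -> pd.DataFrame:
    """Per-region genotype means and mutant/wild-type fold change.

    Regions whose wild-type mean is zero or negative cannot form a ratio;
    they are excluded with ``excluded=True`` and a reason, not silently
    dropped.
    """
    missing = [c for c in REQUIRED_PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise SpliceDataError(f"probe table lacks column(s): {missing}")
    genotypes = set(probes["genotype"].unique())
    for label in (wt_label, mut_label):
        if label not in genotypes:
            raise SpliceDataError(f"genotype {label!r} absent from probe table")
    bad_types = set(probes["region_type"].unique()) - {"exon", "intron"}
    if bad_types:
        raise SpliceDataError(f"unknown region_type values: {sorted(bad_types)}")

    means = (
        probes.groupby(["gene", "region_id", "region_type", "genotype"], sort=False)[
            "intensity"
        ]
        .mean()
        .unstack("genotype")
    )
    for label in (wt_label, mut_label):
        if means[label].isna().any():
            bad = means[means[label].isna()].index.get_level_values("region_id").tolist()
            raise SpliceDataError(f"regions missing {label!r} probes: {bad[:5]}")
    calls = means.reset_index().rename(
        columns={wt_label: "mean_wt", mut_label: "mean_mut"}
    )
    calls.columns.name = None
    calls["excluded"] = calls["mean_wt"] <= 0
    calls["exclude_reason"] = np.where(calls["excluded"], "nonpositive wild-type mean", "")
    n_bad = int(calls["excluded"].sum())
    if n_bad:
        log.warning("%d region(s) excluded: nonpositive wild-type mean", n_bad)
    calls["fold"] = np.where(
        calls["excluded"], np.nan, calls["mean_mut"] / calls["mean_wt"]
    )
    return calls


def classify_regions(calls: pd.DataFrame, threshold: float = 1.5) -> pd.DataFrame:
    """Assign a category to every region at a strict fold threshold."""
    if threshold <= 1:
        raise SpliceDataError("fold threshold must exceed 1")
    out = calls.copy()
    fold = out["fold"].to_numpy()
    is_exon = (out["region_type"] == "exon").to_numpy()
    category = np.full(len(out), "none", dtype=object)
    with np.errstate(invalid="ignore"):
        up = fold > threshold
        down = fold < 1.0 / threshold
    category[is_exon & up] = "exon_up"
    category[is_exon & down] = "exon_down"
    category[~is_exon & up] = "intron_up"
    category[out["excluded"].to_numpy(dtype=bool)] = "none"
    out["category"] = category
    return out


@dataclass
class GeneCounts:
    """Category bookkeeping at gene and region level."""

    genes: dict[str, int]
    regions: dict[str, int]
    multi_category_genes: list[str]
    total_genes: int
    total_called_regions: int


def aggregate_genes(classified: pd.DataFrame) -> tuple[pd.DataFrame, GeneCounts]:
    """Gene-level category sets plus per-category gene/region counts.

    A gene is counted once in every category for which it has at least one
    called region; genes carrying more than one category are additionally
    listed in ``multi_category_genes``.  ``total_genes`` counts distinct
    genes with any call.
    """
    called = classified[classified["category"] != "none"]
    gene_cats = (
        called.groupby("gene")["category"].agg(lambda s: tuple(sorted(set(s))))
        if len(called)
        else pd.Series(dtype=object)
    )
    summary = pd.DataFrame(
        {"gene": gene_cats.index, "categories": gene_cats.to_numpy()}
    )
    genes = {c: int((called.groupby("gene")["category"]
                     .agg(lambda s, c=c: c in set(s))).sum()) for c in CATEGORIES}
    regions = {c: int((called["category"] == c).sum()) for c in CATEGORIES}
    multi = sorted(g for g, cats in gene_cats.items() if len(cats) > 1)
    counts = GeneCounts(
        genes=genes,
        regions=regions,
        multi_category_genes=multi,
        total_genes=int(len(gene_cats)),
        total_called_regions=int(len(called)),
    )
    return summary, counts


def as_proportion(k: int, n: int) -> tuple[float, int]:
    """Percentage ``100*k/n``, exact and rounded to the nearest integer."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("count must lie between 0 and the denominator")
    pct = 100.0 * k / n
    return pct, int(round(pct))


def _two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[str, float, float]:
    """Chi-square with continuity correction, exact (Fisher) fallback.

    The fallback triggers when any expected cell count drops below 5,
    where the chi-square approximation is unreliable.
    """
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        res = stats.fisher_exact(table, alternative="two-sided")
        log.info("expected cell < 5; exact test used instead of chi-square")
        return "fisher_exact", float(res.statistic), float(res.pvalue)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return "chi2_cc", float(chi2), float(p)


def as_enrichment(
    summary: pd.DataFrame,
    annotation: pd.DataFrame,
    background: float = 0.25,
) -> pd.DataFrame:
    """AS proportions per category with pairwise and background tests.

    Returns a tidy frame with one row per category (n genes, n AS,
    percentage, exact binomial p against ``background``) followed by one
    row per category pair (test name, statistic, p-value).
    """
    if not 0 < background < 1:
        raise ValueError("background proportion must lie in (0, 1)")
    as_map = annotation.set_index("gene")["as_flag"].astype(bool)
    unknown = set(summary["gene"]) - set(as_map.index)
    if unknown:
        raise SpliceDataError(f"genes missing from annotation: {sorted(unknown)[:5]}")

    per_cat: dict[str, tuple[int, int]] = {}
    for cat in CATEGORIES:
        genes = summary.loc[
            summary["categories"].map(lambda cs, c=cat: c in cs), "gene"
        ]
        n = len(genes)
        k = int(as_map.loc[genes].sum()) if n else 0
        per_cat[cat] = (k, n)

    rows = []
    for cat, (k, n) in per_cat.items():
        if n == 0:
            rows.append({"kind": "category", "name": cat, "n_genes": 0, "n_as": 0,
                         "as_percent": np.nan, "test": "", "statistic": np.nan,
                         "pvalue": np.nan})
            continue
        pct, _ = as_proportion(k, n)
        binom = stats.binomtest(k, n, background, alternative="two-sided")
        rows.append({"kind": "category", "name": cat, "n_genes": n, "n_as": k,
                     "as_percent": pct, "test": "binomial_vs_background",
                     "statistic": float(k), "pvalue": float(binom.pvalue)})
    cats = [c for c in CATEGORIES if per_cat[c][1] > 0]
    for i, c1 in enumerate(cats):
        for c2 in cats[i + 1 :]:
            k1, n1 = per_cat[c1]
            k2, n2 = per_cat[c2]
            name, statistic, p = _two_proportion_test(k1, n1, k2, n2)
            rows.append({"kind": "pairwise", "name": f"{c1}_vs_{c2}",
                         "n_genes": n1 + n2, "n_as": k1 + k2, "as_percent": np.nan,
                         "test": name, "statistic": statistic, "pvalue": p})
    return pd.DataFrame(rows)
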