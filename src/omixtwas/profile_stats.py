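"""Descriptive and enrichment statistics: tissue-specificity classification,
transcriptome-complexity curves, and over-representation tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpecificityCall",
    "EnrichmentResult",
    "classify_specificity",
    "complexity_curve",
    "ora_hypergeometric",
    "ks_shift_enrichment",
    "permutation_category_enrichment",
]

CATEGORIES = ("enriched", "group_enriched", "enhanced", "low_specificity", "not_detected")


@dataclass
class SpecificityCall:
    feature_id: str
    category: str
    supporting_tissues: list[str]


@dataclass
class EnrichmentResult:
    test: str
    statistic: float
    p: float
    odds_ratio: float | None = None
    shift: float | None = None
    n_permutations: int | None = None


def classify_specificity(
    expr_by_tissue: pd.DataFrame,
    fold: float = 4.0,
    detect_threshold: float = 1.0,
    max_group: int = 5,
) -> list[SpecificityCall]:
    """HPA-style tissue-specificity categories, one call per feature.

    ``expr_by_tissue`` is features x tissues. Evaluation order: not_detected
    (all tissues below ``detect_threshold``), then enriched (top tissue at
    least ``fold`` x any other), group_enriched (a group of 2..``max_group``
    tissues each at least ``fold`` x any tissue outside the group), enhanced
    (some tissue at least ``fold`` x the cross-tissue mean), else
    low_specificity. Calls are invariant to positive rescaling of the
    abundances except through ``detect_threshold``.
    """
    if expr_by_tissue.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    tissues = list(expr_by_tissue.columns)
    calls = []
    for fid, row in expr_by_tissue.iterrows():
        v = row.to_numpy(dtype=float)
        order = np.argsort(-v, kind="stable")
        sv = v[order]
        if (v < detect_threshold).all():
            calls.append(SpecificityCall(str(fid), "not_detected", []))
            continue
        if len(v) >= 2 and sv[0] >= fold * sv[1]:
            calls.append(SpecificityCall(str(fid), "enriched", [tissues[order[0]]]))
            continue
        group = None
        for g in range(2, min(max_group, len(v) - 1) + 1):
            outside_max = sv[g] if g < len(v) else 0.0
            if sv[g - 1] >= fold * outside_max:
                group = [tissues[i] for i in order[:g]]
                break
        if group is not None:
            calls.append(SpecificityCall(str(fid), "group_enriched", group))
            continue
        mean = v.mean()
        if mean > 0 and sv[0] >= fold * mean:
            calls.append(SpecificityCall(str(fid), "enhanced", [tissues[order[0]]]))
            continue
        calls.append(SpecificityCall(str(fid), "low_specificity", []))
    return calls


def complexity_curve(values: np.ndarray) -> dict:
    """Cumulative transcriptome share by expression rank.

    ``values`` is a features x samples abundance matrix (or a 1-D vector of
    per-feature abundances). Features are ranked by median abundance
    descending; the curve gives the cumulative fraction of the total at each
    rank, plus the fractions reached by the top 25/50/75% of features.
    """
    values = np.asarray(values, dtype=float)
    per_gene = np.median(values, axis=1) if values.ndim == 2 else values
    total = per_gene.sum()
    if total <= 0:
        raise ValueError("all-zero expression matrix")
    share = np.sort(per_gene)[::-1] / total
    curve = np.cumsum(share)
    g = len(per_gene)
    at = {}
    for q in (0.25, 0.50, 0.75):
        k = max(1, int(np.floor(q * g)))
        at[q] = float(curve[k - 1])
    return {"curve": curve, "fraction_at_quartile": at}


def ora_hypergeometric(hits: set, gene_set: set, universe: set) -> EnrichmentResult:
    """One-sided (upper tail) hypergeometric over-representation test."""
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe or not gene_set <= universe:
        raise ValueError("hits and gene_set must be subsets of the universe")
    N = len(universe)
    K = len(gene_set)
    n = len(hits)
    x = len(hits & gene_set)
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    a = x
    b = n - x
    c = K - x
    d = N - K - b
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return EnrichmentResult("hypergeometric", float(x), p, odds_ratio=float(odds))


def ks_shift_enrichment(values_in_class, values_background, direction: str) -> EnrichmentResult:
    """One-sided two-sample Kolmogorov-Smirnov shift test.

    ``direction='greater'`` tests whether the class values are shifted toward
    higher values than the background (D+ statistic), ``'less'`` the reverse.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(values_in_class, dtype=float)
    b = np.asarray(values_background, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    # scipy alternative names refer to the CDF of the first sample: a class
    # shifted toward HIGHER values has a SMALLER ('less') empirical CDF.
    # method='auto' uses the exact one-sided null at small sample sizes and
    # the asymptotic tail otherwise.
    alt = "less" if direction == "greater" else "greater"
    res = stats.ks_2samp(a, b, alternative=alt, method="auto")
    return EnrichmentResult("ks_one_sided", float(res.statistic), float(res.pvalue))


def permutation_category_enrichment(
    query_genes: set,
    category_assignment: dict,
    universe: list,
    n_perm: int = 100_000,
    seed: int = 0,
) -> dict[str, EnrichmentResult]:
    """Permutation enrichment of each category among the query genes.

    Null: categories counted in random query-size gene sets drawn without
    replacement from the universe. One-sided p = (1 + #{null >= observed}) /
    (n_perm + 1), so the smallest attainable p is 1/(n_perm+1).
    """
    universe = list(universe)
    if not set(query_genes) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    rng = np.random.default_rng(seed)
    categories = sorted(set(category_assignment.values()))
    cat_codes = {c: i for i, c in enumerate(categories)}
    codes = np.array([cat_codes.get(category_assignment.get(g), -1) for g in universe])
    q = len(query_genes)
    obs = np.zeros(len(categories), dtype=int)
    for g in query_genes:
        c = category_assignment.get(g)
        if c is not None:
            obs[cat_codes[c]] += 1
    exceed = np.zeros(len(categories), dtype=np.int64)
    chunk = max(1, min(n_perm, int(2e7 // max(len(universe), 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, len(universe)))
        picks = np.argpartition(keys, q - 1, axis=1)[:, :q]
        picked_codes = codes[picks]
        for ci in range(len(categories)):
            null_counts = (picked_codes == ci).sum(axis=1)
            exceed[ci] += int((null_counts >= obs[ci]).sum())
        done += m
    out = {}
    for c, ci in cat_codes.items():
        if (codes == ci).sum() == 0:
            warnings.warn(f"category {c!r} absent from universe", stacklevel=2)
            out[c] = EnrichmentResult("permutation", float(obs[ci]), 1.0, n_permutations=n_perm)
            continue
        p = (1 + exceed[ci]) / (n_perm + 1)
        out[c] = EnrichmentResult("permutation", float(obs[ci]), float(p), n_permutations=n_perm)
    return out
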