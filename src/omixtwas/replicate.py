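"""Two-cohort reciprocal replication, locus bookkeeping and tissue ranking.

Replication design: within each cohort x trait, BH-FDR over the full tested
feature set defines discovery; features significant in one cohort are
followed up in the other with BH-FDR recomputed over the followed-up subset
only. The union over both discovery directions is kept, and a feature counts
as replicated only when significant in both cohorts with the same effect
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReplicatedHit",
    "GwasLocusSet",
    "TissueScore",
    "bh_fdr",
    "reciprocal_replicate",
    "build_locus_set",
    "map_features_to_loci",
    "rank_tissues",
]


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving and monotone."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ReplicatedHit:
    feature_id: str
    trait: str
    z_discovery: float
    z_replication: float
    q_discovery: float
    q_replication: float
    direction_consistent: bool
    discovery_cohort: str


def reciprocal_replicate(
    results_c1: pd.DataFrame,
    results_c2: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> list[ReplicatedHit]:
    """Reciprocal two-cohort replication with per-trait BH-FDR.

    Inputs are TWAS result tables with columns (feature, trait, z, p)
    covering the same feature universe per trait. Returns the union of hits
    over both discovery directions, direction-consistency enforced.
    """
    hits: dict[tuple[str, str], ReplicatedHit] = {}
    for disc, repl, disc_name in (
        (results_c1, results_c2, "cohort1"),
        (results_c2, results_c1, "cohort2"),
    ):
        traits_d = set(disc["trait"])
        if traits_d != set(repl["trait"]):
            raise ValueError("trait sets differ between cohorts")
        for trait in sorted(traits_d):
            d = disc[disc["trait"] == trait].reset_index(drop=True)
            r = repl[repl["trait"] == trait].set_index("feature")
            if set(d["feature"]) != set(r.index):
                raise ValueError(f"feature universes differ for trait {trait!r}")
            qd = bh_fdr(d["p"].to_numpy())
            sig = qd < fdr_threshold
            if not sig.any():
                continue
            followed = d[sig].reset_index(drop=True)
            pr = r.loc[followed["feature"], "p"].to_numpy()
            qr = bh_fdr(pr)
            zr = r.loc[followed["feature"], "z"].to_numpy()
            for i, row in enumerate(followed.itertuples(index=False)):
                consistent = np.sign(row.z) == np.sign(zr[i])
                if qr[i] < fdr_threshold and consistent:
                    key = (row.feature, trait)
                    hit = ReplicatedHit(
                        feature_id=row.feature,
                        trait=trait,
                        z_discovery=float(row.z),
                        z_replication=float(zr[i]),
                        q_discovery=float(qd[sig][i]),
                        q_replication=float(qr[i]),
                        direction_consistent=bool(consistent),
                        discovery_cohort=disc_name,
                    )
                    if key not in hits or hit.q_discovery < hits[key].q_discovery:
                        hits[key] = hit
    return sorted(hits.values(), key=lambda h: (h.trait, h.feature_id))


# ---------------------------------------------------------------------------
# GWAS loci
# ---------------------------------------------------------------------------


@dataclass
class GwasLocusSet:
    """Merged sentinel +- 1 Mb intervals; disjoint after merging."""

    loci: pd.DataFrame  # locus_id, chrom, start, end, sentinel_id, sentinel_pos


def build_locus_set(sentinels: pd.DataFrame, flank_bp: int = 1_000_000) -> GwasLocusSet:
    """Sentinel variants -> merged loci.

    ``sentinels`` has (id, chrom, pos[, p]); each contributes pos +- flank_bp
    (0-based half-open), overlapping intervals merge, and the most significant
    sentinel (smallest p; falling back to input order) labels each locus.
    Merging is idempotent and independent of input order.
    """
    if len(sentinels) == 0:
        return GwasLocusSet(pd.DataFrame(columns=["locus_id", "chrom", "start", "end", "sentinel_id", "sentinel_pos"]))
    s = sentinels.copy()
    if "p" not in s.columns:
        s["p"] = 1.0
    s = s.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    rows = []
    for chrom, sub in s.groupby("chrom", sort=True):
        cur_start = cur_end = None
        cur_members = []
        for row in sub.itertuples(index=False):
            start = max(0, row.pos - 1 - flank_bp)
            end = row.pos - 1 + flank_bp + 1
            if cur_end is None or start > cur_end:
                if cur_end is not None:
                    rows.append((chrom, cur_start, cur_end, cur_members))
                cur_start, cur_end, cur_members = start, end, [row]
            else:
                cur_end = max(cur_end, end)
                cur_members.append(row)
        rows.append((chrom, cur_start, cur_end, cur_members))
    recs = []
    for k, (chrom, start, end, members) in enumerate(rows):
        best = min(members, key=lambda r: (r.p, r.pos))
        recs.append((f"locus{k}", chrom, int(start), int(end), best.id, int(best.pos)))
    return GwasLocusSet(pd.DataFrame(recs, columns=["locus_id", "chrom", "start", "end", "sentinel_id", "sentinel_pos"]))


def map_features_to_loci(features: pd.DataFrame, loci: GwasLocusSet) -> pd.DataFrame:
    """Assign features to loci by TSS-in-interval; outsiders are 'novel'.

    ``features`` needs (feature_id, chrom, tss) with tss 0-based.
    """
    out = features.copy()
    out["locus_id"] = None
    out["novel"] = True
    if len(loci.loci) == 0:
        return out
    for row in loci.loci.itertuples(index=False):
        inside = (out["chrom"] == row.chrom) & (out["tss"] >= row.start) & (out["tss"] < row.end)
        out.loc[inside & out["novel"], "locus_id"] = row.locus_id
        out.loc[inside, "novel"] = False
    return out


# ---------------------------------------------------------------------------
# tissue prioritisation
# ---------------------------------------------------------------------------


@dataclass
class TissueScore:
    tissue: str
    trait: str
    prop_independent_genes: float
    mean_sq_z: float
    n_outside_loci: int
    rank_per_metric: tuple[float, float, float]
    overall_rank_score: float


def _greedy_independent(sub: pd.DataFrame, corr: pd.DataFrame | None, r2_max: float = 0.05,
                        span_bp: int = 2_000_000) -> pd.DataFrame:
    """Greedy pruning by |z| descending: genes within ``span_bp`` whose
    imputed-expression R^2 exceeds ``r2_max`` collapse onto the stronger one;
    genes further apart are independent by definition."""
    sub = sub.sort_values("z", key=lambda s: -s.abs(), kind="stable").reset_index(drop=True)
    kept = []
    for row in sub.itertuples(index=False):
        ok = True
        for k in kept:
            if row.chrom == k.chrom and abs(row.tss - k.tss) <= span_bp:
                r2 = 0.0
                if corr is not None and row.feature in corr.index and k.feature in corr.columns:
                    r2 = float(corr.loc[row.feature, k.feature]) ** 2
                if r2 >= r2_max:
                    ok = False
                    break
        if ok:
            kept.append(row)
    return pd.DataFrame(kept, columns=sub.columns)


def rank_tissues(
    per_tissue_results: dict[str, pd.DataFrame],
    loci: GwasLocusSet,
    traits: tuple[str, ...] = ("SBP", "DBP"),
    grex_corr: dict[str, pd.DataFrame] | None = None,
    r2_max: float = 0.05,
) -> list[TissueScore]:
    """Three-metric tissue ranking and the overall rank-sum.

    ``per_tissue_results`` maps tissue -> DataFrame with columns
    (feature, trait, chrom, tss, z, significant); ``grex_corr`` optionally
    maps tissue -> gene x gene imputed-expression correlation. Per trait:
    metric 1 = proportion of significant genes that are independent,
    metric 2 = mean z^2 over the independent significant genes,
    metric 3 = count of significant genes outside known GWAS loci.
    Tissues are ranked per metric (higher better, average ranks on ties);
    the overall score sums the three ranks over the listed traits.
    """
    tissues = sorted(per_tissue_results)
    scores: list[TissueScore] = []
    overall: dict[str, float] = {t: 0.0 for t in tissues}
    for trait in traits:
        metrics = np.zeros((len(tissues), 3))
        per_tissue_rows = {}
        for ti, tissue in enumerate(tissues):
            df = per_tissue_results[tissue]
            sub = df[(df["trait"] == trait) & df["significant"]].copy()
            if len(sub) == 0:
                metrics[ti] = (0.0, 0.0, 0.0)
                per_tissue_rows[tissue] = (0.0, 0.0, 0)
                continue
            corr = grex_corr.get(tissue) if grex_corr else None
            indep = _greedy_independent(sub, corr, r2_max=r2_max)
            mapped = map_features_to_loci(
                indep.rename(columns={"feature": "feature_id"})[["feature_id", "chrom", "tss"]], loci
            )
            prop = len(indep) / len(sub)
            msz = float((indep["z"] ** 2).mean())
            outside = int(
                map_features_to_loci(
                    sub.rename(columns={"feature": "feature_id"})[["feature_id", "chrom", "tss"]], loci
                )["novel"].sum()
            )
            metrics[ti] = (prop, msz, outside)
            per_tissue_rows[tissue] = (prop, msz, outside)
        # rank each metric: 1 = best (largest); average ranks on ties
        ranks = np.column_stack(
            [stats.rankdata(-metrics[:, k], method="average") for k in range(3)]
        )
        for ti, tissue in enumerate(tissues):
            prop, msz, outside = per_tissue_rows[tissue]
            rank_tuple = tuple(float(x) for x in ranks[ti])
            overall[tissue] += float(ranks[ti].sum())
            scores.append(
                TissueScore(
                    tissue=tissue,
                    trait=trait,
                    prop_independent_genes=float(prop),
                    mean_sq_z=float(msz),
                    n_outside_loci=int(outside),
                    rank_per_metric=rank_tuple,
                    overall_rank_score=0.0,  # filled below once all traits seen
                )
            )
    for sc in scores:
        sc.overall_rank_score = overall[sc.tissue]
    return scores
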