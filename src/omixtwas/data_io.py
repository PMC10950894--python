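"""Core data containers, variant/expression QC, normalization and allele harmonization.

Conventions
-----------
* Genomic intervals (BED, annotation tracks, windows) are 0-based half-open.
* Variant positions are 1-based (VCF convention); a variant at position ``p``
  overlaps interval ``[s, e)`` iff ``s <= p - 1 < e``.
* Dosages count the a1 (effect) allele, values in [0, 2]; missing is NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "AnnotationTracks",
    "WindowSet",
    "variant_qc",
    "hwe_exact_test",
    "filter_expressed",
    "normalize_expression",
    "inverse_normal_transform",
    "quantile_normalize",
    "harmonize_alleles",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gwas_tsv",
    "write_gwas_tsv",
]

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypeMatrix:
    """Dosage matrix (samples x variants) with variant metadata.

    ``variants`` is a DataFrame with columns id, chrom, pos (1-based), a1
    (effect allele, counted by the dosage), a2 (other allele).
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant ids")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be strictly positive (1-based)")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[idx],
            variants=self.variants,
            dosages=self.dosages[idx, :],
        )

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant (NaN-aware)."""
        f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)


@dataclass
class ExpressionMatrix:
    """Abundance or residual matrix (features x samples) plus feature metadata.

    ``feature_meta`` carries at least (feature_id, chrom, tss); ``counts`` is
    the paired raw read-count matrix needed by expression filtering.
    """

    feature_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    feature_meta: pd.DataFrame | None = None
    counts: np.ndarray | None = None

    def __post_init__(self):
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape must be (n_features, n_samples)")
        if self.counts is not None and self.counts.shape != self.values.shape:
            raise ValueError("counts shape must match values shape")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_features(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        meta = None
        if self.feature_meta is not None:
            meta = (
                self.feature_meta.set_index("feature_id")
                .loc[self.feature_ids[idx]]
                .reset_index()
            )
        return ExpressionMatrix(
            feature_ids=self.feature_ids[idx],
            sample_ids=self.sample_ids,
            values=self.values[idx, :],
            feature_meta=meta,
            counts=None if self.counts is None else self.counts[idx, :],
        )


class AnnotationTracks:
    """Named sets of genomic intervals (0-based half-open), e.g. epigenomic peaks."""

    def __init__(self, tracks: dict[str, pd.DataFrame]):
        self.tracks = {}
        for name, df in tracks.items():
            df = df[["chrom", "start", "end"]].copy()
            if (df["start"] >= df["end"]).any():
                raise ValueError(f"track {name!r}: start must be < end")
            self.tracks[name] = df.sort_values(["chrom", "start"]).reset_index(drop=True)

    def names(self) -> list[str]:
        return list(self.tracks)

    def overlap_mask(self, chrom: np.ndarray, pos: np.ndarray, track: str) -> np.ndarray:
        """True where the 1-based variant position overlaps an interval of ``track``."""
        df = self.tracks[track]
        out = np.zeros(len(pos), dtype=bool)
        p0 = np.asarray(pos) - 1  # 0-based coordinate of the variant
        chrom = np.asarray(chrom)
        for c, sub in df.groupby("chrom", sort=False):
            sel = chrom == c
            if not sel.any():
                continue
            out[sel] = _points_in_intervals(p0[sel], sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    def essential_mask(self, variants: pd.DataFrame) -> np.ndarray:
        """Union overlap over all tracks: the 'essential variant' definition."""
        mask = np.zeros(len(variants), dtype=bool)
        for name in self.tracks:
            mask |= self.overlap_mask(variants["chrom"].to_numpy(), variants["pos"].to_numpy(), name)
        return mask


def _points_in_intervals(p0: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of 0-based points in a union of half-open intervals."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # merge overlapping intervals so searchsorted logic is valid
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    merged_s = np.asarray(merged_s)
    merged_e = np.asarray(merged_e)
    k = np.searchsorted(merged_s, p0, side="right") - 1
    ok = k >= 0
    out = np.zeros(len(p0), dtype=bool)
    out[ok] = p0[ok] < merged_e[k[ok]]
    return out


WINDOW_KINDS = ("tad", "loop", "fixed_1mb", "fixed_250kb")


class WindowSet:
    """Per-gene candidate cis windows, one interval list per window kind."""

    def __init__(self, windows: dict[str, dict[str, list[tuple[str, int, int]]]]):
        for gene, kinds in windows.items():
            for k in ("fixed_1mb", "fixed_250kb"):
                if k not in kinds:
                    raise ValueError(f"gene {gene!r}: fixed window {k!r} missing")
        self.windows = windows

    def genes(self) -> list[str]:
        return list(self.windows)

    def intervals(self, gene: str, kind: str) -> list[tuple[str, int, int]]:
        return self.windows[gene][kind]

    def variant_mask(self, gene: str, kind: str, variants: pd.DataFrame) -> np.ndarray:
        ivs = self.windows[gene][kind]
        mask = np.zeros(len(variants), dtype=bool)
        p0 = variants["pos"].to_numpy() - 1
        chrom = variants["chrom"].to_numpy()
        for c, s, e in ivs:
            mask |= (chrom == c) & (p0 >= s) & (p0 < e)
        return mask

    def total_span(self, gene: str, kind: str) -> int:
        return sum(e - s for _, s, e in self.windows[gene][kind])


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value (Wigginton et al. construction).

    The two-sided p is the total probability, under the exact conditional
    distribution of the heterozygote count given allele counts, of all
    genotype configurations no more probable than the observed one.
    """
    n_hom1, n_het, n_hom2 = int(n_hom1), int(n_het), int(n_hom2)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele count
    # heterozygote counts share the parity of the rare allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    log_probs = np.empty(len(het_values))
    for i, h in enumerate(het_values):
        r_hom = (rare - h) // 2
        c_hom = n - h - r_hom
        # log multinomial-style exact probability (up to common constant)
        log_probs[i] = (
            h * np.log(2)
            - _lgamma1p(h)
            - _lgamma1p(r_hom)
            - _lgamma1p(c_hom)
        )
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    obs = probs[het_values == n_het][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _lgamma1p(k):
    from scipy.special import gammaln

    return gammaln(k + 1)


def variant_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.05,
    hwe_p_min: float = 1e-3,
) -> GenotypeMatrix:
    """Filter variants on MAF, missingness and exact-test HWE; order preserved.

    Fractional dosages are rounded to hard calls for the HWE test only.
    """
    maf = g.maf()
    miss = g.missingness()
    hwe_p = np.ones(g.n_variants)
    hard = np.rint(g.dosages)
    for j in range(g.n_variants):
        col = hard[:, j]
        col = col[~np.isnan(col)]
        counts = [(col == 0).sum(), (col == 1).sum(), (col == 2).sum()]
        hwe_p[j] = hwe_exact_test(*counts)
    keep = (maf >= maf_min) & (miss <= missing_max) & (hwe_p >= hwe_p_min)
    if not keep.any():
        warnings.warn("variant_qc removed every variant", stacklevel=2)
    return g.subset_variants(keep)


# ---------------------------------------------------------------------------
# expression filtering and normalization
# ---------------------------------------------------------------------------


def filter_expressed(
    e: ExpressionMatrix,
    tpm_min: float = 0.1,
    count_min: float = 5,
    sample_frac: float = 0.20,
    drop_zero_iqr: bool = False,
) -> ExpressionMatrix:
    """Keep features whose abundance and read count clear thresholds in enough samples.

    A feature passes when ``abundance > tpm_min`` and ``count > count_min`` in
    at least ``sample_frac`` of samples. ``drop_zero_iqr`` additionally removes
    features with zero interquartile range (the miRNA filtering mode).
    """
    if e.counts is None:
        raise ValueError("filter_expressed requires a paired read-count matrix (ExpressionMatrix.counts)")
    passing = (e.values > tpm_min) & (e.counts > count_min)
    frac = passing.mean(axis=1)
    keep = frac >= sample_frac
    if drop_zero_iqr:
        q75, q25 = np.percentile(e.values, [75, 25], axis=1)
        keep &= (q75 - q25) > 0
    return e.subset_features(keep)


def quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Cross-sample quantile normalization of a features x samples matrix.

    Every sample's empirical distribution is mapped onto the mean of the
    sorted values across samples (the limma/aroma convention). Ties get the
    average of the reference values they span.
    """
    x = np.asarray(x, dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    nf = x.shape[0]
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average") - 1  # 0-based, may be half-integers
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (ref[lo] + ref[np.minimum(hi, nf - 1)])
    return out


def inverse_normal_transform(x: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps values to ``Phi^{-1}((rank - c) / (n + 1 - 2c))`` per row; ties get
    average ranks. A constant row maps to zeros.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        if np.ptp(x[i]) == 0:
            out[i] = 0.0
            continue
        ranks = stats.rankdata(x[i], method="average")
        out[i] = stats.norm.ppf((ranks - c) / (n + 1 - 2 * c))
    return out


def normalize_expression(
    e: ExpressionMatrix,
    covariates: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Full normalization chain: log2(x+1), quantile normalization, rank
    inverse-normal transform, then residualization on covariates.

    ``covariates`` is a samples x covariates table (numeric); an intercept is
    always included, so residuals have mean ~0 per feature. Constant features
    become zero vectors with a warning.
    """
    vals = np.log2(e.values + 1.0)
    constant = np.ptp(vals, axis=1) == 0  # constant on input stays zeroed
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s) set to zero", stacklevel=2)
    if e.n_features > 1:
        vals = quantile_normalize(vals)
    vals = inverse_normal_transform(vals)
    if covariates is not None and len(covariates.columns) > 0:
        C = np.column_stack([np.ones(e.n_samples), covariates.to_numpy(dtype=float)])
    else:
        C = np.ones((e.n_samples, 1))
    # residualize all features at once: vals (features x samples)
    beta, *_ = np.linalg.lstsq(C, vals.T, rcond=None)
    vals = vals - (C @ beta).T
    vals[constant] = 0.0
    return ExpressionMatrix(
        feature_ids=e.feature_ids,
        sample_ids=e.sample_ids,
        values=vals,
        feature_meta=e.feature_meta,
        counts=e.counts,
    )


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------


def harmonize_alleles(
    a: pd.DataFrame,
    b: pd.DataFrame,
    effect_cols_b: tuple[str, ...] = ("beta", "z"),
) -> pd.DataFrame:
    """Join two effect tables on variant id with allele-aware sign correction.

    Both inputs need columns (id, a1, a2). Rows of ``b`` whose alleles are
    swapped relative to ``a`` get the listed effect columns sign-flipped;
    strand-ambiguous variants (A/T, C/G) and allele mismatches are dropped.
    Returns the inner join with ``a``'s allele orientation; columns of ``b``
    are suffixed ``_b`` on collision.
    """
    for df, name in ((a, "a"), (b, "b")):
        if df["id"].duplicated().any():
            raise ValueError(f"duplicate variant ids in input {name}")
    m = a.merge(b, on="id", suffixes=("", "_b"), how="inner")
    if len(m) == 0:
        warnings.warn("harmonize_alleles: no shared variant ids", stacklevel=2)
        return m
    up = lambda s: s.astype(str).str.upper()
    a1, a2 = up(m["a1"]), up(m["a2"])
    b1, b2 = up(m["a1_b"]), up(m["a2_b"])
    ambiguous = pd.Series(list(zip(a1, a2)), index=m.index).isin(AMBIGUOUS_PAIRS)
    same = (a1 == b1) & (a2 == b2)
    swapped = (a1 == b2) & (a2 == b1)
    keep = (same | swapped) & ~ambiguous
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"harmonize_alleles: dropped {dropped} variant(s)", stacklevel=2)
    m = m[keep].copy()
    flip = swapped[keep]
    for col in effect_cols_b:
        for cand in (f"{col}_b", col):
            if cand in m.columns and cand not in a.columns:
                m.loc[flip, cand] = -m.loc[flip, cand]
                break
        else:
            if f"{col}_b" in m.columns:
                m.loc[flip, f"{col}_b"] = -m.loc[flip, f"{col}_b"]
    m = m.drop(columns=[c for c in ("a1_b", "a2_b") if c in m.columns])
    return m.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT (hard call) and DS (dosage) fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT (a1)">\n')
        chroms = pd.unique(g.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, g.sample_ids)) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in enumerate(g.variants.itertuples(index=False)):
            ds = g.dosages[:, j]
            cells = []
            for d in ds:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    hard = int(np.rint(d))
                    cells.append(f"{gt_map[hard]}:{d:.6g}")
            # a1 is the counted (ALT) allele, a2 the reference
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.a2}\t{row.a1}\t.\t.\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (DS field preferred, else GT hard calls)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.asarray(vcf.samples, dtype=object)
    ids, chroms, poss, a1s, a2s, cols = [], [], [], [], [], []
    for v in vcf:
        ids.append(v.ID)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        a2s.append(v.REF)
        a1s.append(v.ALT[0] if v.ALT else ".")
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = ds[:, 0].astype(float)
        else:
            gts = np.asarray(v.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
            col = np.where(gts == 3, 2.0, gts)
            col[gts == 2] = np.nan
        cols.append(col)
    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s})
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(sample_ids=samples, variants=variants, dosages=dosages)


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """Write BED3/BED4 (columns chrom, start, end[, name]); 0-based half-open."""
    cols = ["chrom", "start", "end"] + (["name"] if "name" in intervals.columns else [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(4, df.shape[1])]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


def write_expression_tsv(e: ExpressionMatrix, path: str) -> None:
    df = pd.DataFrame(e.values, index=e.feature_ids, columns=e.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_expression_tsv(path: str, feature_meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        feature_ids=df.index.to_numpy(dtype=object),
        sample_ids=df.columns.to_numpy(dtype=object),
        values=df.to_numpy(dtype=float),
        feature_meta=feature_meta,
    )


GWAS_COLUMNS = ["variant_id", "chrom", "pos", "a1", "a2", "beta", "se", "z", "n"]


def write_gwas_tsv(df: pd.DataFrame, path: str) -> None:
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS TSV missing required columns: {missing}")
    return df
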