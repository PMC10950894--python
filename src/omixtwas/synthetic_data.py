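"""Synthetic multi-omics data with planted truth.

Generates every input the analysis chain consumes — block-LD genotypes,
epigenomic annotation tracks and 3D-genome windows, expression with a sparse
annotation-enriched cis-eQTL architecture, and two-cohort GWAS summary
statistics whose trait is partly driven through genetically regulated
expression (GReX), with a molecular mediator on the GReX -> trait path.

Genotypes come from a Gaussian copula: per haplotype, a latent AR(1) chain
within each LD block is thresholded at Phi^{-1}(MAF) to produce alleles, and
the two haplotypes are summed to a dosage. Because thresholding attenuates
correlation (the phi coefficient of two thresholded Gaussians is smaller than
their latent correlation), the latent adjacent-pair correlation is calibrated
per pair — by inverting the bivariate-normal orthant probability — so that
the *dosage* correlation of adjacent variants matches ``ld_decay_rho``.

Mediation algebra
-----------------
With exposure GReX ``G`` (variance ~ v_G), the mediator is

    M = b_M * G + g_M + e_M            (g_M: mediator-specific genetic part)
    Y = c * M + d * G + confound + e

so the total exposure effect is ``b_M * c + d`` and the mediated (indirect)
fraction is ``MP = b_M * c / (b_M * c + d)``. Given ``alpha_grex_trait`` (the
total effect) and ``mediation_proportion_true`` the generator sets b_M = 1,
``c = MP * alpha`` and ``d = (1 - MP) * alpha``, which hits the target MP
exactly in expectation. The mediator-specific variants that generate ``g_M``
are disjoint from every gene's cis region, so two-step MR with the mediator's
own instruments identifies ``c`` (they touch the trait only through M).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats, optimize

from .data_io import (
    AnnotationTracks,
    ExpressionMatrix,
    GenotypeMatrix,
    WindowSet,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_annotations_and_windows",
    "simulate_expression",
    "simulate_gwas_cohorts",
    "simulate_all",
]

LOCUS_SPAN = 1_000_000  # bp allotted to each gene locus on the synthetic genome
ANNOTATION_TRACK_NAMES = ("H3K27ac", "H3K4me3", "DNase", "CTCF")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the defaults are the study conditions.

    Sample sizes mirror a desk-scale version of a kidney eQTL panel
    (hundreds of genotyped kidneys) feeding TWAS in two large GWAS cohorts.
    """

    n_individuals_ref: int = 400
    n_cohort1: int = 2000
    n_cohort2: int = 2000
    n_genes: int = 50
    n_variants_per_locus: int = 30
    ld_block_size: int = 10
    ld_decay_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_eqtl: int = 2
    essential_enrichment: float = 5.0
    h2_cis: float = 0.3
    alpha_grex_trait: float = 0.3
    mediation_proportion_true: float = 0.5
    causal_gene_fraction: float = 0.2
    confound_sd: float = 0.5
    n_mediator_variants: int = 20
    h2_mediator_own: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_individuals_ref",
            "n_cohort1",
            "n_cohort2",
            "n_genes",
            "n_variants_per_locus",
            "ld_block_size",
            "n_causal_eqtl",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.ld_decay_rho < 1:
            raise ValueError("ld_decay_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.h2_cis <= 1:
            raise ValueError("h2_cis must be in [0, 1]")
        if not 0 <= self.mediation_proportion_true <= 1:
            raise ValueError("mediation_proportion_true must be in [0, 1]")
        if self.essential_enrichment < 1:
            raise ValueError("essential_enrichment must be >= 1")
        if self.n_causal_eqtl > self.n_variants_per_locus:
            raise ValueError("n_causal_eqtl cannot exceed n_variants_per_locus")


@dataclass
class SyntheticTruth:
    """Planted ground truth recovery is scored against."""

    causal_variants: dict[str, list[int]]  # gene -> indices into the full variant table
    eqtl_betas: dict[str, list[float]]  # gene -> per-causal-variant effects (dosage scale)
    causal_genes: list[str]
    causal_gene_per_locus: dict[str, str]  # locus id -> causal gene (fine-mapping truth)
    true_MP: float
    true_alpha: float
    mediated_gene: str = ""  # the one exposure gene whose effect is partly mediated
    alpha_per_gene: dict[str, float] = field(default_factory=dict)
    mediator_variants: list[int] = field(default_factory=list)
    mediator_betas: list[float] = field(default_factory=list)
    mediator_b_EM: float = 1.0
    mediator_c_MO: float = 0.0
    direct_effect: float = 0.0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _phi_coefficient(rho: float, t1: float, t2: float, p1: float, p2: float) -> float:
    """Correlation of two Bernoulli indicators from thresholded bivariate normals."""
    p11 = stats.multivariate_normal.cdf([t1, t2], mean=[0, 0], cov=[[1, rho], [rho, 1]])
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def _calibrate_latent_rho(target: float, p1: float, p2: float) -> float:
    """Latent Gaussian correlation whose thresholded phi coefficient equals ``target``."""
    if target == 0:
        return 0.0
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    hi = 1 - 1e-9
    f = lambda r: _phi_coefficient(r, t1, t2, p1, p2) - target
    if f(hi) < 0:  # target unattainable for these margins; saturate
        return hi
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-6))


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Block-LD dosages for the reference panel layout defined by ``config``.

    Variants are laid out one locus per gene, ``n_variants_per_locus`` evenly
    spaced variants per locus, grouped into LD blocks of ``ld_block_size``
    with AR(1)-style within-block dosage correlation ``ld_decay_rho`` and
    independence across blocks. Appends ``n_mediator_variants`` on a separate
    contig used only by the mediator GWAS.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_gene_variants = config.n_genes * config.n_variants_per_locus
    p = n_gene_variants + config.n_mediator_variants
    # variants in strong LD share allele frequency: draw one MAF per block
    n_blocks = (p + config.ld_block_size - 1) // config.ld_block_size
    block_mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_blocks)
    mafs = np.repeat(block_mafs, config.ld_block_size)[:p]
    variants = _variant_table(config, mafs)
    dosages = _draw_dosages(config, mafs, config.n_individuals_ref, rng)
    samples = np.array([f"ref{i:05d}" for i in range(config.n_individuals_ref)], dtype=object)
    g = GenotypeMatrix(sample_ids=samples, variants=variants, dosages=dosages)
    g.variants.attrs["mafs"] = mafs
    return g


def _variant_table(config: SimulationConfig, mafs: np.ndarray) -> pd.DataFrame:
    ids, chroms, poss = [], [], []
    step = LOCUS_SPAN // (config.n_variants_per_locus + 1)
    k = 0
    for gi in range(config.n_genes):
        for vi in range(config.n_variants_per_locus):
            ids.append(f"rs{k}")
            chroms.append("chr1")
            poss.append(gi * LOCUS_SPAN + (vi + 1) * step + 1)  # 1-based
            k += 1
    for vi in range(config.n_mediator_variants):
        ids.append(f"rsM{vi}")
        chroms.append("chrM1")
        poss.append((vi + 1) * 10_000 + 1)
        k += 1
    return pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "a1": "A", "a2": "G"}
    )


def _block_latent_coeffs(config: SimulationConfig, mafs: np.ndarray) -> np.ndarray:
    """Per-variant AR coefficient of the latent chain (0 at block starts).

    Calibrated so the realized adjacent-dosage correlation matches
    ld_decay_rho; calibration is cached by rounded MAF pair to stay cheap.
    """
    p = len(mafs)
    coeffs = np.zeros(p)
    if config.ld_decay_rho == 0:
        return coeffs
    cache: dict[tuple[float, float], float] = {}
    for j in range(1, p):
        if j % config.ld_block_size == 0:
            continue  # new block: independent
        key = (round(mafs[j - 1], 2), round(mafs[j], 2))
        if key not in cache:
            cache[key] = _calibrate_latent_rho(config.ld_decay_rho, *key)
        coeffs[j] = cache[key]
    return coeffs


def _draw_dosages(
    config: SimulationConfig, mafs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    p = len(mafs)
    coeffs = _block_latent_coeffs(config, mafs)
    thresholds = stats.norm.ppf(mafs)
    dos = np.zeros((n, p))
    for _hap in range(2):
        z = np.empty((n, p))
        eps = rng.standard_normal((n, p))
        z[:, 0] = eps[:, 0]
        for j in range(1, p):
            a = coeffs[j]
            z[:, j] = a * z[:, j - 1] + np.sqrt(1 - a * a) * eps[:, j]
        dos += (z < thresholds).astype(float)
    return dos


# ---------------------------------------------------------------------------
# annotations and windows
# ---------------------------------------------------------------------------


def simulate_annotations_and_windows(
    config: SimulationConfig,
    variants: pd.DataFrame,
    rng: np.random.Generator | None = None,
    essential_fraction: float = 0.3,
) -> tuple[AnnotationTracks, WindowSet]:
    """Binary epigenomic tracks over variants plus four candidate windows per gene.

    Roughly ``essential_fraction`` of variants end up under at least one of
    the four tracks. TADs partition each locus into two segments at a random
    breakpoint; chromatin loops connect two short anchors near a subset of
    TSSs. Window kinds: tad (TAD containing the TSS), loop (anchors of loops
    touching [TSS-5kb, TSS+5kb) plus the gene body; falls back to fixed_1mb),
    fixed_1mb and fixed_250kb around the TSS.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    gene_mask = variants["chrom"] == "chr1"
    gv = variants[gene_mask]
    tracks: dict[str, list[tuple[str, int, int]]] = {t: [] for t in ANNOTATION_TRACK_NAMES}
    # choose the essential subset, then scatter it over the four tracks
    n_ess = max(1, int(round(essential_fraction * len(gv))))
    ess_idx = rng.choice(len(gv), size=n_ess, replace=False)
    for i in ess_idx:
        pos0 = int(gv["pos"].iloc[i]) - 1
        track = ANNOTATION_TRACK_NAMES[rng.integers(len(ANNOTATION_TRACK_NAMES))]
        tracks[track].append(("chr1", pos0 - 100, pos0 + 100))
    track_frames = {
        name: pd.DataFrame(ivs or [("chr1", 0, 1)], columns=["chrom", "start", "end"])
        for name, ivs in tracks.items()
    }
    annotations = AnnotationTracks(track_frames)

    # TADs: each locus split in two at a random interior breakpoint
    tads = []
    for gi in range(config.n_genes):
        start = gi * LOCUS_SPAN
        bp = start + int(rng.uniform(0.25, 0.75) * LOCUS_SPAN)
        tads.append(("chr1", start, bp))
        tads.append(("chr1", bp, start + LOCUS_SPAN))
    # loops: ~half of genes get a loop anchored at the TSS reaching across the locus
    loops = []
    tss = {f"gene{gi}": gi * LOCUS_SPAN + LOCUS_SPAN // 2 for gi in range(config.n_genes)}
    for gi in range(config.n_genes):
        if rng.random() < 0.5:
            t = tss[f"gene{gi}"]
            far = gi * LOCUS_SPAN + int(rng.uniform(0.05, 0.95) * LOCUS_SPAN)
            loops.append(("chr1", t - 5_000, t + 5_000, "chr1", far - 5_000, far + 5_000))

    windows = build_windows(
        genes={g: ("chr1", t) for g, t in tss.items()},
        tads=pd.DataFrame(tads, columns=["chrom", "start", "end"]),
        loops=pd.DataFrame(
            loops, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
        ),
    )
    windows.tads = pd.DataFrame(tads, columns=["chrom", "start", "end"])
    windows.loops = pd.DataFrame(
        loops, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    )
    return annotations, windows


def build_windows(
    genes: dict[str, tuple[str, int]],
    tads: pd.DataFrame | None = None,
    loops: pd.DataFrame | None = None,
    gene_body: dict[str, tuple[int, int]] | None = None,
) -> WindowSet:
    """Assemble the four candidate cis windows for each gene.

    ``genes`` maps gene id -> (chrom, tss, 0-based). Fixed windows are
    [tss-250kb, tss+250kb) and [tss-1Mb, tss+1Mb) clipped at 0. The TAD
    window is the TAD containing the TSS; the loop window is the union of
    both anchors of every loop with an anchor overlapping [tss-5kb, tss+5kb)
    plus the gene body; both fall back to fixed_1mb when undefined.
    """
    out: dict[str, dict[str, list[tuple[str, int, int]]]] = {}
    for gene, (chrom, tss) in genes.items():
        fixed_1mb = [(chrom, max(0, tss - 1_000_000), tss + 1_000_000)]
        fixed_250 = [(chrom, max(0, tss - 250_000), tss + 250_000)]
        kinds = {"fixed_1mb": fixed_1mb, "fixed_250kb": fixed_250}
        tad_win = None
        if tads is not None and len(tads):
            hit = tads[(tads["chrom"] == chrom) & (tads["start"] <= tss) & (tss < tads["end"])]
            if len(hit):
                row = hit.iloc[0]
                tad_win = [(chrom, int(row["start"]), int(row["end"]))]
        kinds["tad"] = tad_win if tad_win is not None else list(fixed_1mb)
        loop_win = None
        if loops is not None and len(loops):
            sel = []
            for row in loops.itertuples(index=False):
                for (c, s, e), (oc, os_, oe) in (
                    ((row.chrom1, row.start1, row.end1), (row.chrom2, row.start2, row.end2)),
                    ((row.chrom2, row.start2, row.end2), (row.chrom1, row.start1, row.end1)),
                ):
                    if c == chrom and s < tss + 5_000 and e > tss - 5_000:
                        sel.append((c, int(s), int(e)))
                        sel.append((oc, int(os_), int(oe)))
            if sel:
                body = gene_body.get(gene) if gene_body else None
                if body is not None:
                    sel.append((chrom, int(body[0]), int(body[1])))
                else:
                    sel.append((chrom, tss, tss + 1))
                loop_win = sorted(set(sel))
        kinds["loop"] = loop_win if loop_win is not None else list(fixed_1mb)
        out[gene] = kinds
    return WindowSet(out)


def gene_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Gene table (feature_id, chrom, tss 0-based) for the synthetic layout."""
    return pd.DataFrame(
        {
            "feature_id": [f"gene{gi}" for gi in range(config.n_genes)],
            "chrom": "chr1",
            "tss": [gi * LOCUS_SPAN + LOCUS_SPAN // 2 for gi in range(config.n_genes)],
        }
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    genotypes: GenotypeMatrix,
    annotations: AnnotationTracks,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression residuals with a sparse, annotation-enriched cis architecture.

    Per gene, ``n_causal_eqtl`` variants are drawn from the gene's locus with
    sampling weight ``essential_enrichment`` when annotated; expression is the
    causal dosage combination plus Gaussian noise scaled so the genetic
    fraction of variance equals ``h2_cis`` exactly in-sample. With
    ``h2_cis = 0`` expression is pure noise.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    ess = annotations.essential_mask(genotypes.variants)
    n = genotypes.n_samples
    values = np.zeros((config.n_genes, n))
    causal: dict[str, list[int]] = {}
    betas: dict[str, list[float]] = {}
    vpl = config.n_variants_per_locus
    for gi in range(config.n_genes):
        gene = f"gene{gi}"
        lo = gi * vpl
        idx_local = np.arange(lo, lo + vpl)
        w = np.where(ess[idx_local], config.essential_enrichment, 1.0)
        w = w / w.sum()
        chosen = rng.choice(idx_local, size=config.n_causal_eqtl, replace=False, p=w)
        b = rng.standard_normal(config.n_causal_eqtl)
        g = genotypes.dosages[:, chosen] @ b
        if config.h2_cis == 0 or np.var(g) == 0:
            e = rng.standard_normal(n)
            values[gi] = e
            causal[gene] = [int(c) for c in chosen]
            betas[gene] = [0.0] * config.n_causal_eqtl
            continue
        var_g = np.var(g)
        noise_sd = np.sqrt(var_g * (1 - config.h2_cis) / config.h2_cis) if config.h2_cis < 1 else 0.0
        values[gi] = g + noise_sd * rng.standard_normal(n)
        causal[gene] = [int(c) for c in chosen]
        betas[gene] = [float(x) for x in b]
    n_causal_genes = max(1, int(round(config.causal_gene_fraction * config.n_genes)))
    causal_genes = [f"gene{gi}" for gi in rng.choice(config.n_genes, size=n_causal_genes, replace=False)]
    mp = config.mediation_proportion_true
    alpha = config.alpha_grex_trait
    med_idx = [int(i) for i in np.flatnonzero(genotypes.variants["chrom"] == "chrM1")]
    truth = SyntheticTruth(
        causal_variants=causal,
        eqtl_betas=betas,
        causal_genes=sorted(causal_genes),
        causal_gene_per_locus={f"locus{g[4:]}": g for g in sorted(causal_genes)},
        true_MP=mp,
        true_alpha=alpha,
        mediated_gene=sorted(causal_genes)[0],
        alpha_per_gene={g: alpha for g in causal_genes},
        mediator_variants=med_idx,
        mediator_betas=[float(x) for x in rng.standard_normal(len(med_idx))],
        mediator_b_EM=1.0,
        mediator_c_MO=mp * alpha,
        direct_effect=(1 - mp) * alpha,
    )
    expr = ExpressionMatrix(
        feature_ids=np.array([f"gene{gi}" for gi in range(config.n_genes)], dtype=object),
        sample_ids=genotypes.sample_ids,
        values=values,
        feature_meta=gene_metadata(config),
    )
    return expr, truth


# ---------------------------------------------------------------------------
# GWAS cohorts
# ---------------------------------------------------------------------------


def _grex_true(dosages: np.ndarray, truth: SyntheticTruth, genes: list[str]) -> np.ndarray:
    """Summed standardized genetic value of the listed genes."""
    total = np.zeros(dosages.shape[0])
    for gene in genes:
        idx = truth.causal_variants[gene]
        b = np.asarray(truth.eqtl_betas[gene])
        g = dosages[:, idx] @ b
        sd = g.std()
        if sd > 0:
            total += g / sd
    return total


def marginal_gwas(dosages: np.ndarray, y: np.ndarray, variants: pd.DataFrame) -> pd.DataFrame:
    """Per-variant simple linear regression of ``y`` on each dosage column.

    Vectorized OLS: beta_j = cov(x_j, y)/var(x_j), se from the per-variant
    residual variance with n-2 degrees of freedom.
    """
    n = len(y)
    x = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = (x * x).sum(axis=0)
    sxy = x.T @ yc
    sxx_safe = np.where(sxx > 0, sxx, np.nan)
    beta = sxy / sxx_safe
    syy = float(yc @ yc)
    rss = syy - beta * sxy
    rss = np.clip(rss, 0, None)
    se = np.sqrt(rss / (n - 2) / sxx_safe)
    se = np.where(se > 0, se, np.nan)
    z = beta / se
    out = variants[["id", "chrom", "pos", "a1", "a2"]].copy()
    out = out.rename(columns={"id": "variant_id"})
    out["beta"] = beta
    out["se"] = se
    out["z"] = z
    out["n"] = n
    return out


def simulate_gwas_cohorts(
    config: SimulationConfig,
    truth: SyntheticTruth,
    mafs_or_genotypes=None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two independent trait GWAS plus one mediator GWAS, as summary statistics.

    Each cohort draws fresh genotypes from the same LD machinery, builds the
    trait as ``c*M + d*G + confound + noise`` (see module docstring) and
    computes per-variant marginal regressions — so summary-level and
    individual-level pipelines can be cross-checked. The mediator GWAS comes
    from a third independent sample of the same size as cohort 1.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    if mafs_or_genotypes is None:
        raise ValueError("pass the reference GenotypeMatrix (for MAFs and the variant table)")
    ref = mafs_or_genotypes
    mafs = ref.variants.attrs.get("mafs")
    if mafs is None:
        f = np.nanmean(ref.dosages, axis=0) / 2.0
        mafs = f
    variants = ref.variants

    out = []
    for cohort, n in (("cohort1", config.n_cohort1), ("cohort2", config.n_cohort2)):
        dos = _draw_dosages(config, mafs, n, rng)
        y, _ = _build_trait(dos, truth, config, rng)
        df = marginal_gwas(dos, y, variants)
        df["cohort"] = cohort
        df["trait"] = "trait"
        out.append(df)

    dos3 = _draw_dosages(config, mafs, config.n_cohort1, rng)
    _, mediator = _build_trait(dos3, truth, config, rng)
    dfm = marginal_gwas(dos3, mediator, variants)
    dfm["cohort"] = "mediator_cohort"
    dfm["trait"] = "mediator"
    out.append(dfm)
    return tuple(out)


def _build_trait(
    dos: np.ndarray,
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Trait and mediator vectors for one cohort's dosages.

    The mediator loads on the single ``mediated_gene``; the remaining causal
    genes act on the trait directly with effect ``true_alpha`` per
    standardized genetic value.
    """
    n = dos.shape[0]
    star = truth.mediated_gene or (truth.causal_genes[0] if truth.causal_genes else None)
    others = [g for g in truth.causal_genes if g != star]
    G_star = _grex_true(dos, truth, [star]) if star is not None else np.zeros(n)
    G_other = _grex_true(dos, truth, others)
    g_M = np.zeros(n)
    if truth.mediator_variants:
        g_M = dos[:, truth.mediator_variants] @ np.asarray(truth.mediator_betas)
        sd = g_M.std()
        if sd > 0:
            h2 = config.h2_mediator_own
            # own-genetics variance as a fraction h2 of the non-exposure
            # mediator variance (own genetics + unit noise)
            g_M = g_M / sd * np.sqrt(h2 / (1 - h2)) if h2 < 1 else g_M / sd
    mediator = truth.mediator_b_EM * G_star + g_M + rng.standard_normal(n)
    confound = config.confound_sd * rng.standard_normal(n)
    y = (
        truth.mediator_c_MO * mediator
        + truth.direct_effect * G_star
        + truth.true_alpha * G_other
        + confound
        + rng.standard_normal(n)
    )
    return y, mediator


def simulate_all(config: SimulationConfig):
    """One-call generation of every synthetic input, fully seed-determined.

    Returns (genotypes, annotations, windows, expression, truth,
    gwas_cohort1, gwas_cohort2, gwas_mediator).
    """
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    annotations, windows = simulate_annotations_and_windows(config, genotypes.variants, rng)
    expression, truth = simulate_expression(genotypes, annotations, config, rng)
    g1, g2, gm = simulate_gwas_cohorts(config, truth, genotypes, rng)
    return genotypes, annotations, windows, expression, truth, g1, g2, gm
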