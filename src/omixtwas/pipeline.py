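"""End-to-end orchestration: simulate -> QC -> train -> validate -> TWAS x 2
cohorts -> reciprocal replication -> MR gates -> fine-mapping -> mediation,
with a manifest and an auditable funnel of counts at every stage."""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import synthetic_data as synth
from .assoc import GwasSummary, LDReference, cis_eqtl_scan, twas_all_genes
from .data_io import ExpressionMatrix, variant_qc
from .finemap import build_locus_inputs, finemap_loci
from .grex import TrainingConfig, models_to_tsv, train_all_genes, validate_models
from .mr import InstrumentSet, ivw, ld_clump, mr_egger, two_step_mediation
from .replicate import reciprocal_replicate
from .synthetic_data import SimulationConfig

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    fdr: float = 0.05
    validate_r: float = 0.1
    clump_p: float = 1e-3
    clump_r2: float = 0.5
    mr_alpha: float = 0.05
    out_dir: str | None = None
    run_mediation: bool = True
    n_holdout: int = 200

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")


@dataclass
class PipelineResult:
    funnel: dict
    models: list
    validation: list
    twas: dict
    replicated: list
    mr_passing: list
    finemap: pd.DataFrame
    mediation: object | None
    truth: synth.SyntheticTruth
    manifest: dict


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic analysis chain; optionally write stage TSVs."""
    sim = config.simulation
    stage_log: dict = {}

    # --- simulate ----------------------------------------------------------
    genotypes, annotations, windows, expression, truth, g1, g2, gm = synth.simulate_all(sim)
    mafs = genotypes.variants.attrs.get("mafs")
    stage_log["simulate"] = {
        "n_variants": genotypes.n_variants,
        "n_genes": sim.n_genes,
        "genotype_hash": _hash_array(genotypes.dosages),
    }

    # --- QC ----------------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genotypes_qc = variant_qc(genotypes, maf_min=0.01, missing_max=0.05, hwe_p_min=1e-6)
    stage_log["variant_qc"] = {"kept": genotypes_qc.n_variants, "input": genotypes.n_variants}
    if mafs is not None:
        kept_ids = set(genotypes_qc.variants["id"])
        keep_mask = genotypes.variants["id"].isin(kept_ids).to_numpy()
        genotypes_qc.variants.attrs["mafs"] = np.asarray(mafs)[keep_mask]

    # --- train + validate --------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models = train_all_genes(genotypes_qc, expression, annotations, windows, config.training)
    stage_log["train"] = {"models_trained": len(models)}

    rng = np.random.default_rng(sim.seed + 17)
    holdout_dos = synth._draw_dosages(sim, genotypes.variants.attrs["mafs"] if mafs is not None else np.nanmean(genotypes.dosages, 0) / 2, config.n_holdout, rng)
    from .data_io import GenotypeMatrix

    holdout = GenotypeMatrix(
        sample_ids=np.array([f"hold{i}" for i in range(config.n_holdout)], dtype=object),
        variants=genotypes.variants,
        dosages=holdout_dos,
    )
    hold_expr_vals = np.zeros((sim.n_genes, config.n_holdout))
    for gi in range(sim.n_genes):
        gene = f"gene{gi}"
        idx = truth.causal_variants[gene]
        b = np.asarray(truth.eqtl_betas[gene])
        g = holdout_dos[:, idx] @ b
        if np.any(b) and np.var(g) > 0 and sim.h2_cis > 0:
            noise_sd = np.sqrt(np.var(g) * (1 - sim.h2_cis) / sim.h2_cis) if sim.h2_cis < 1 else 0
            hold_expr_vals[gi] = g + noise_sd * rng.standard_normal(config.n_holdout)
        else:
            hold_expr_vals[gi] = rng.standard_normal(config.n_holdout)
    hold_expr = ExpressionMatrix(
        feature_ids=expression.feature_ids,
        sample_ids=holdout.sample_ids,
        values=hold_expr_vals,
        feature_meta=expression.feature_meta,
    )
    validation = validate_models(models, holdout, hold_expr)
    validated_genes = {v.gene_id for v in validation if v.validated}
    models_validated = [m for m in models if m.gene_id in validated_genes]
    stage_log["validate"] = {"models_validated": len(models_validated)}

    # --- TWAS in both cohorts ----------------------------------------------
    ld = LDReference(genotypes)
    twas = {}
    for cohort, gdf in (("cohort1", g1), ("cohort2", g2)):
        gs = GwasSummary(gdf.rename(columns={"id": "variant_id"}), trait_name="trait", cohort_name=cohort)
        twas[cohort] = twas_all_genes(models_validated, gs, ld)
    stage_log["twas"] = {c: len(t) for c, t in twas.items()}

    # --- reciprocal replication --------------------------------------------
    replicated = reciprocal_replicate(twas["cohort1"], twas["cohort2"], fdr_threshold=config.fdr)
    stage_log["replicate"] = {"replicated": len(replicated)}

    # --- MR gate (IVW + Egger pleiotropy screen per replicated gene) --------
    gene_meta = expression.feature_meta
    eqtls = cis_eqtl_scan(expression, genotypes_qc, gene_meta)
    meta_gwas = g1.set_index("variant_id")
    mr_passing = []
    for hit in replicated:
        gene = hit.feature_id
        if gene not in eqtls:
            continue
        try:
            instr_tab = ld_clump(eqtls[gene], ld, p_max=config.clump_p, r2_max=config.clump_r2)
        except ValueError:
            continue
        ids = instr_tab["variant_id"].tolist()
        present = [v for v in ids if v in meta_gwas.index]
        if not present:
            continue
        sub = instr_tab.set_index("variant_id").loc[present]
        out = meta_gwas.loc[present]
        instr = InstrumentSet(
            variant_ids=present,
            beta_exposure=sub["beta"].to_numpy(),
            se_exposure=sub["se"].to_numpy(),
            beta_outcome=out["beta"].to_numpy(),
            se_outcome=out["se"].to_numpy(),
            correlation=ld.correlation(present),
        )
        res = ivw(instr, penalized=True)
        pleio_p = None
        if len(instr) >= 3:
            try:
                pleio_p = mr_egger(instr).egger_intercept_p
            except ValueError:
                pleio_p = None
        if res.significant_causal(pleiotropy_p=pleio_p, alpha=config.mr_alpha):
            mr_passing.append((gene, res, pleio_p))
    stage_log["mr"] = {"mr_passing": len(mr_passing)}

    # --- fine-mapping -------------------------------------------------------
    # disjoint LD blocks = the synthetic gene loci, merged into multi-gene
    # blocks of consecutive loci so some blocks carry >1 TWAS signal
    blocks = _synthetic_blocks(sim)
    mr_genes = {g for g, *_ in mr_passing}
    twas_for_fm = twas["cohort1"][twas["cohort1"]["feature"].isin(mr_genes)]
    loci = build_locus_inputs(twas_for_fm, models_validated, genotypes, blocks, gene_meta)
    fm = finemap_loci(loci)
    n_fm_retained = int(fm["retained"].sum()) if len(fm) else 0
    # genes in single-signal blocks pass through un-fine-mapped
    fm_genes = set(fm["gene"]) if len(fm) else set()
    passthrough = mr_genes - fm_genes
    stage_log["finemap"] = {
        "loci": len(loci),
        "finemap_retained": n_fm_retained,
        "single_signal_passthrough": len(passthrough),
    }

    # --- mediation ----------------------------------------------------------
    mediation = None
    if config.run_mediation and truth.causal_genes:
        mediation = _mediation_analysis(truth, eqtls, g1, gm, ld, config)
    stage_log["mediation"] = {
        "MP": None if mediation is None else mediation.MP,
    }

    funnel = {
        "models_trained": len(models),
        "models_validated": len(models_validated),
        "replicated_genes": len(replicated),
        "mr_passing_genes": len(mr_passing),
        "finemap_retained_genes": n_fm_retained + len(passthrough),
    }
    manifest = {
        "seed": sim.seed,
        "config": {"simulation": asdict(sim), "fdr": config.fdr},
        "stages": stage_log,
        "funnel": funnel,
    }
    result = PipelineResult(
        funnel=funnel,
        models=models,
        validation=validation,
        twas=twas,
        replicated=replicated,
        mr_passing=mr_passing,
        finemap=fm,
        mediation=mediation,
        truth=truth,
        manifest=manifest,
    )
    if config.out_dir:
        _write_outputs(config.out_dir, result, twas)
    return result


def _synthetic_blocks(sim: SimulationConfig, loci_per_block: int = 2) -> pd.DataFrame:
    span = synth.LOCUS_SPAN
    rows = []
    n_blocks = (sim.n_genes + loci_per_block - 1) // loci_per_block
    for b in range(n_blocks):
        rows.append(("chr1", b * loci_per_block * span, min((b + 1) * loci_per_block, sim.n_genes) * span))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _mediation_analysis(truth, eqtls, gwas_trait, gwas_mediator, ld, config):
    """Two-step MR mediation for the first causal gene with usable instruments."""
    med_gwas = gwas_mediator.set_index("variant_id")
    trait_gwas = gwas_trait.set_index("variant_id")
    genes = [truth.mediated_gene] if truth.mediated_gene else truth.causal_genes
    for gene in genes:
        if gene not in eqtls:
            continue
        try:
            instr_tab = ld_clump(eqtls[gene], ld, p_max=config.clump_p, r2_max=config.clump_r2)
        except ValueError:
            continue
        ids = [v for v in instr_tab["variant_id"] if v in med_gwas.index and v in trait_gwas.index]
        if not ids:
            continue
        sub = instr_tab.set_index("variant_id").loc[ids]
        corr = ld.correlation(ids)
        # correlated-instrument (GLS) estimators: clumping at r^2 < 0.5
        # leaves moderate LD among the cis instruments
        em = ivw(InstrumentSet(ids, sub["beta"].to_numpy(), sub["se"].to_numpy(),
                               med_gwas.loc[ids, "beta"].to_numpy(), med_gwas.loc[ids, "se"].to_numpy(),
                               correlation=corr), use_correlation=True)
        eo = ivw(InstrumentSet(ids, sub["beta"].to_numpy(), sub["se"].to_numpy(),
                               trait_gwas.loc[ids, "beta"].to_numpy(), trait_gwas.loc[ids, "se"].to_numpy(),
                               correlation=corr), use_correlation=True)
        # mediator's own instruments: dedicated mediator variants, strongest
        # mediator-GWAS signals pruned to near-independence (r^2 < 0.1)
        med_ids = [f"rsM{i}" for i in range(len(truth.mediator_variants))]
        med_ids = [v for v in med_ids if v in med_gwas.index and v in trait_gwas.index]
        sig = med_gwas.loc[med_ids]
        keep = list(sig.index[(2 * _norm_sf(np.abs(sig["z"].to_numpy()))) < 5e-8])
        if len(keep) == 0:
            keep = list(sig["z"].abs().sort_values(ascending=False).index[:5])
        pruned = []
        for v in sorted(keep, key=lambda v: -abs(sig.loc[v, "z"])):
            if all(ld.correlation([v, u], regularize=False)[0, 1] ** 2 < 0.1 for u in pruned):
                pruned.append(v)
        mcorr = ld.correlation(pruned)
        mo = ivw(InstrumentSet(pruned,
                               med_gwas.loc[pruned, "beta"].to_numpy(), med_gwas.loc[pruned, "se"].to_numpy(),
                               trait_gwas.loc[pruned, "beta"].to_numpy(), trait_gwas.loc[pruned, "se"].to_numpy(),
                               correlation=mcorr), use_correlation=True)
        return two_step_mediation(em, mo, eo)
    return None


def _norm_sf(x):
    from scipy.stats import norm

    return norm.sf(x)


def _write_outputs(out_dir: str, result: PipelineResult, twas: dict) -> None:
    os.makedirs(out_dir, exist_ok=True)
    models_to_tsv(result.models, os.path.join(out_dir, "models.tsv"))
    for cohort, tab in twas.items():
        tab.to_csv(os.path.join(out_dir, f"twas_{cohort}.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            (h.feature_id, h.trait, h.z_discovery, h.z_replication, h.q_discovery, h.q_replication)
            for h in result.replicated
        ],
        columns=["feature", "trait", "z_discovery", "z_replication", "q_discovery", "q_replication"],
    ).to_csv(os.path.join(out_dir, "replicated.tsv"), sep="\t", index=False)
    if len(result.finemap):
        result.finemap.to_csv(os.path.join(out_dir, "finemap.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)
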