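# omixtwas

A kidney-flavoured multi-omics TWAS toolkit: epigenome- and 3D-genome-informed
imputation of genetically regulated expression (GReX), summary-statistic
transcriptome-wide association with reciprocal two-cohort replication, tissue
prioritisation, two-sample Mendelian-randomization mediation, conditional-Z
adjustment of correlated signals, and gene-level probabilistic fine-mapping —
all runnable end-to-end on synthetic data with planted ground truth.

## Who this is for

Statistical geneticists who want a tested, desk-scale reference implementation
of the full discovery chain that links tissue eQTL panels to GWAS summary
statistics: from training per-gene expression prediction models through to a
short list of putatively causal, replicated, fine-mapped genes with mediation
estimates. Every stage consumes and emits standard formats (VCF, BED, TSV),
and a synthetic-data module generates inputs with known truth so the whole
chain is testable without any restricted downloads.

## The models at the core

**Differentially penalized GReX imputation.** For one gene, let `E` be
residualized expression across n individuals, `X1` the standardized dosages of
*essential* variants (those overlapping supplied epigenomic annotation
tracks: H3K27ac, H3K4me3, DNase, CTCF peaks) and `X2` the remaining cis
variants. Weights minimize

```
L(b1, b2; λ, φ) = ||E − X1·b1 − X2·b2||²
                  + (1/2)(λ/2)(φ||b1||₂² + ||b2||₂²)
                  + (1/2)·λ·(φ||b1||₁ + ||b2||₁),      φ ≤ 1
```

so annotated variants are penalized no more than the rest. φ, λ, and the cis
window `w` — the TAD containing the TSS, chromatin-loop anchors, ±1 Mb, or
±250 kb — are tuned jointly by nested cross-validation; models are retained
only when the out-of-fold correlation exceeds 0.10 with p < 0.05, and are
re-validated in an independent panel (r > 0.1). At φ = 1 the objective is an
ordinary elastic net (sklearn mapping: `alpha = λ/(2n)`, `l1_ratio = 1/2`),
which the test suite uses as an exact oracle.

**Summary-statistic TWAS.** Gene association from GWAS z-scores, model
weights `w` and reference LD `Σ`:
`Z_g = Σ_l w_l (σ_l/σ_g) z_l` with `σ_g² = wᵀ diag(σ) Σ diag(σ) w`.
Discovery runs in two cohorts with BH-FDR per cohort and trait; a gene counts
as significant only when it replicates reciprocally with a consistent
direction of effect.

**Causal gating and decomposition.** cis-eQTL-derived instruments (LD-clumped
at r² < 0.5) feed IVW / penalized-IVW / MR-Egger estimators — GLS variants
when instruments are correlated — with the gate: effect p < 0.05 and Egger
pleiotropy p > 0.05. Two-step MR decomposes a gene→trait effect through a
molecular mediator: indirect = B_EM·B_MO, mediation proportion
MP = indirect/total, with delta-method standard errors. Conditional z-scores
`Z_cond = (Z_gene − r·Z_miRNA)/√(1−r²)` adjust a gene's signal for a
correlated feature's signal via their cis genetic correlation `r`.

**Fine-mapping.** Within multi-gene loci, a spike-and-slab enumeration over
causal configurations (FOCUS-style) yields per-gene posterior inclusion
probabilities; genes are retained when they sit in the 95% credible set with
PIP > 0.5.

## Worked example

```python
from omixtwas import PipelineConfig, run_pipeline, SimulationConfig, TrainingConfig

config = PipelineConfig(
    simulation=SimulationConfig(
        n_individuals_ref=300,          # reference eQTL panel
        n_cohort1=1500, n_cohort2=1500, # the two GWAS cohorts
        n_genes=30, n_variants_per_locus=20,
        h2_cis=0.35,                    # cis heritability of expression
        alpha_grex_trait=0.35,          # GReX -> trait effect
        mediation_proportion_true=0.5,  # planted mediated fraction
        causal_gene_fraction=0.2,
        seed=11,
    ),
    training=TrainingConfig(n_lambda=8, phi_grid=(1.0, 0.5),
                            outer_folds=3, inner_folds=3, seed=0),
)
result = run_pipeline(config)
print("funnel:", result.funnel)
print("replicated:", sorted(h.feature_id for h in result.replicated))
print(result.mediation.summary())
```

prints

```
funnel: {'models_trained': 30, 'models_validated': 30, 'replicated_genes': 6,
         'mr_passing_genes': 6, 'finemap_retained_genes': 6}
replicated: ['gene11', 'gene17', 'gene22', 'gene23', 'gene24', 'gene9']
Two-step MR mediation
  exposure->mediator B_EM = +5.7045 (se 0.2176)
  mediator->outcome B_MO = +0.1344 (se 0.0724)
  total effect     B_tot = +1.7790 (se 0.2105)
  indirect = +0.7665 (se 0.4140, p 0.0641)
  mediation proportion MP = 0.4309 (se 0.2382)
```

All 6 planted causal genes (and no others) survive training, validation,
reciprocal replication and the MR gates, and the recovered mediation
proportion (0.43 ± 0.24) brackets the planted 0.5. A command-line interface
mirrors the stages (`omixtwas simulate|train|twas|replicate|condz|run`).

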