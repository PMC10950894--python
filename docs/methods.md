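# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions taken where the design was genuinely open.
It states nothing the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. GReX model and solver

The per-gene objective (README, "models at the core") applies an L1+L2
penalty with multiplier `φ ≤ 1` on annotated ("essential") predictors and 1
on the rest, with the specific constant layout `(1/2)(λ/2)` on the ridge term
and `(1/2)λ` on the lasso term. These constants are unusual but implemented
verbatim; the mapping to the conventional elastic-net parameterization at
φ = 1 is

```
(1/2n)||y−Xb||² + α·l1·||b||₁ + α(1−l1)/2·||b||₂²
with  α = λ/(2n),  l1_ratio = 1/2
```

so the φ = 1 solution is cross-checked against an independent elastic-net
solver to 1e-6 (and the general-φ solution against a smooth-reformulation
SLSQP minimizer to 1e-4 in objective).

Solver: cyclic coordinate descent. Columns are standardized (zero mean, unit
variance); the coordinate update is the soft threshold
`b_j ← S(2 x_jᵀr̃, λm_j/2) / (2 x_jᵀx_j + λm_j/2)` with `m_j ∈ {φ, 1}`.
`λ_max` (the smallest λ with an all-zero stationary point) comes from the KKT
condition `|2 x_jᵀy| ≤ (λ/2) m_j`. Defaults: λ grid log-spaced from `λ_max`
down 4 decades; φ ∈ {1, 0.5, 0.25, 0.1}; 5×5 nested CV. The default fit path
asserts a non-increasing objective every sweep; cross-validation uses an
equivalent Gram-matrix (covariance-update) kernel, JIT-compiled when numba is
available, verified against the checked path to 1e-9. Convergence is max
coefficient change < `tol` (1e-7 default); non-convergence discards the
model. Ties in inner-CV score break toward larger λ, then larger φ, then the
smaller window (parsimony).

Window construction: the TAD window is the TAD containing the TSS; the loop
window is the union of both anchors of every loop with an anchor overlapping
[TSS−5 kb, TSS+5 kb) plus the gene body; both fall back to the ±1 Mb window
when undefined. Essential status is overlap with the union of the supplied
annotation tracks.

Retention and validation use one-sided p for the out-of-fold correlation
(t distribution, n−2 df): cv_r > 0.10 and cv_p < 0.05; holdout validation
requires Pearson r > 0.1 in an independent panel.

## 2. TWAS

`Z_g = Σ_l w_l (σ_l/σ_g) z_l`, `σ_g² = wᵀ diag(σ) Σ diag(σ) w`, with σ and Σ
from the reference panel and `Σ ← 0.95·Σ + 0.05·I` for stabilization. Model
variants missing from the GWAS are dropped (not imputed) and counted.
Allele handling: GWAS effects are harmonized to the model's effect allele
(sign flips on swaps; strand-ambiguous A/T and C/G variants dropped), then
both weights and z re-oriented to the panel's coding, which makes `Z_g`
exactly invariant to any variant's allele coding. The MHC interval
(chr6:28–34 Mb) can be excluded by a config filter before association.

Firth logistic regression (for binary recapitulation analyses) maximizes the
Jeffreys-penalized likelihood by Newton steps on the modified score with
step-halving; p-values are penalized likelihood ratios. It is checked against
a derivative-free maximizer of the same penalized likelihood and against
plain logistic regression at balanced large n.

## 3. Replication, loci, tissue ranking

Per cohort × trait, BH-FDR runs over the full feature set for discovery;
features significant in one cohort are followed up in the other with BH-FDR
over the followed-up subset only (the two-stage design); the union over both
discovery directions is kept with direction-consistency required. Loci are
sentinel ± 1 Mb intervals, merged when overlapping, labelled by the most
significant sentinel; features map to loci by TSS. Tissue ranking uses three
metrics per trait — proportion of independent significant genes (greedy
pruning by |z| descending, collapsing pairs within 2 Mb with imputed-expression
R² ≥ 0.05), mean z² over the independent genes, count of significant genes
outside known loci — each rank-transformed (average ranks on ties) and
summed across metrics and traits.

## 4. MR and mediation

IVW is a weighted regression through the origin (weights 1/se_out²);
"penalized" IVW down-weights instrument j by `min(1, q_crit/q_j)` where `q_j`
is its Cochran-Q contribution and `q_crit` the χ²₁ 0.95 quantile — one
standard robust-IVW construction, chosen because the penalization itself is
not otherwise pinned down. With correlated instruments the estimator is GLS
with covariance `diag(se)·Σ·diag(se)`; the identity-correlation GLS equals
plain IVW exactly. MR-Egger orients instruments so beta_exposure ≥ 0, fits
weighted regression with an intercept, and scales SEs by the multiplicative
overdispersion floored at 1 — which makes the intercept (pleiotropy) test
conservative at small instrument counts, a property the tests assert rather
than fight. The significance gate everywhere: effect p < 0.05 AND pleiotropy
p > 0.05 when testable.

Mediation: `indirect = B_EM·B_MO`,
`SE_ind = √(B_EM²·SE_MO² + B_MO²·SE_EM²)`; `MP = indirect/total`,
`SE_MP = |MP|·√(SE_ind²/ind² + SE_tot²/tot²)`, treating numerator and
denominator as independent — a deliberately conservative choice since their
covariance is not identified from the three summary fits; the replicate
(parametric-bootstrap) comparison in the acceptance suite quantifies the
residual error (SE ratio within 15% at the simulated scale, provided the
correlated-instrument GLS is used — with fixed-effect IVW on correlated
instruments the SEs understate the truth by more than half, which is why the
pipeline defaults to GLS).

Conditional Z: `Z_cond = (Z_gene − r·Z_miRNA)/√(1−r²)`; mediation verdict iff
|r| > 0.1, |Z_gene| > |Z_cond| > 2, and sign(Z_cond) = sign(Z_gene). `r` is
the Pearson correlation of the two models' imputed scores in a reference
panel.

## 5. Fine-mapping

Spike-and-slab enumeration: under configuration `c`,
`z | c ~ N(0, Ω + nσ²·Ω[:,c]Ω[c,:])` with Ω the predicted-expression
correlation (ridge 0.1 toward identity, rescaled to unit diagonal). Per-gene
prior 1/k; prior variance `nσ² = max(0, mean(z²) − 1)` — the locus's excess
association variance. Posterior normalization is log-sum-exp stable; the
credible set takes genes by descending PIP (normalized by 1 − P(null) by
default; a flag switches to null-inclusive normalization) until 0.95, with
equal-PIP ties entering together; retained = credible-set members with
PIP > 0.5. Exact enumeration is limited to 20 genes; beyond that a clearly
labelled max-one-causal per-gene Bayes-factor approximation is provided.
The enumeration is verified against an independently coded naive enumerator
to 1e-10.

## 6. Synthetic-data generator

What it emulates: a genotyped reference expression panel (hundreds of
individuals), block-LD genotypes, a sparse annotation-enriched cis-eQTL
architecture, two independent GWAS cohorts whose trait is partly driven
through GReX, and a mediator GWAS from a third cohort.

* **Genotypes.** Per haplotype, a latent AR(1) Gaussian chain within each LD
  block is thresholded at Φ⁻¹(MAF); the two haplotypes sum to a dosage (so
  Hardy–Weinberg holds by construction). Thresholding attenuates correlation
  (phi coefficient < latent correlation), so the latent adjacent-pair
  correlation is calibrated by inverting the bivariate-normal orthant
  probability until the *dosage* correlation matches `ld_decay_rho`; variants
  within a block share one MAF (as variants in strong LD do in real data —
  and without which the target correlation can be unattainable). Blocks are
  independent. Default `ld_decay_rho` 0.7, MAF ~ U(0.05, 0.5).
* **Expression.** Per gene, `n_causal_eqtl` (default 2) cis variants drawn
  with weight `essential_enrichment` (default 5) when annotated; Gaussian
  noise scaled so the genetic variance fraction equals `h2_cis` (default 0.3,
  a typical strongly-heritable-gene value) exactly in-sample.
* **Trait and mediator.** One designated causal gene is the mediated
  exposure: `M = G* + g_M + ε_M`, `Y = c·M + d·G* + α·ΣG_other + confound + ε`
  with `c = MP·α`, `d = (1−MP)·α`, which hits the target mediation proportion
  exactly in expectation (MP is scale-free, so the eQTL-vs-standardized-score
  scale cancels). The mediator's own genetic component `g_M` lives on
  dedicated variants on a separate contig — disjoint from every cis region —
  so the mediator's instruments touch the trait only through the mediator and
  two-step MR identifies `c`. Summary statistics are produced by actually
  regressing the simulated trait on each dosage, never analytically, so
  summary-level and individual-level pipelines can be cross-checked.

What it does **not** emulate: realistic haplotype structure, allele-frequency
spectra, population stratification beyond a single confound term, sex
chromosomes, dosage-imputation uncertainty, trans effects, or LD between
loci. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative assumptions, not robustness to the full
messiness of real cohort data.

## 7. Problem sizes and other fixed choices

The test and acceptance runs use desk-scale study conditions chosen once:
reference panels of 250–2000, GWAS cohorts of 1000–8000, 6–200 genes with
15–20 variants each, reduced tuning grids (8–10 λ values, φ ∈ {1, 0.5},
3×3 nested CV) for the multi-gene suites while solver-level checks run the
full default grids. The mediation suite uses a large reference panel (2000)
and cohort (8000) because the delta-method-vs-replicate-SE comparison is an
asymptotic statement. Quantile normalization maps each sample onto the mean
sorted profile (the limma/aroma convention); the inverse-normal transform
uses the Blom offset 3/8; both are stated choices where the literature names
tools rather than constants. Permutation p-values use (b+1)/(m+1) so the
smallest attainable p is 1/(m+1) and zero p-values cannot occur. The
one-sided two-sample KS test uses the exact small-sample null when sample
sizes permit and the asymptotic tail otherwise. HWE filtering uses the exact
conditional test (not χ²), robust at small panel sizes. Coordinates are
0-based half-open internally; VCF positions are 1-based, converted only at
(de)serialization; a variant at VCF position p overlaps BED interval [s, e)
iff s ≤ p−1 < e.

## 8. Known limitations

* The spike-and-slab prior variance estimate `mean(z²) − 1` is crude at loci
  with few genes; PIPs remain well-calibrated in simulation but the credible
  set can be conservative when all z are small.
* The mediation delta method ignores the indirect/total covariance (shared
  instruments make them dependent); the replicate comparison bounds the
  effect at the tested scale but it will grow with instrument overlap.
* Expression filtering requires a paired count matrix; synthetic runs supply
  abundances only and skip that stage.
* The elastic-net baseline shares the nested-CV scaffolding with the
  annotation-informed model (φ pinned at 1, window pinned at ±1 Mb), so
  baseline comparisons are like-for-like by construction.
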