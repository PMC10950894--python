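"""Association stage: summary-statistic TWAS, individual-level GReX-phenotype
regression (linear and Firth logistic), and the cis-eQTL scan feeding MR.

The summary-statistic TWAS statistic combines per-variant GWAS z-scores with
model weights against reference LD:

    Z_g = sum_l w_l (sigma_l / sigma_g) z_l,
    sigma_g^2 = w' diag(sigma) Sigma diag(sigma) w

with Sigma the reference variant correlation matrix (ridge-stabilized) and
sigma_l the reference dosage standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeMatrix, ExpressionMatrix, harmonize_alleles
from .grex import GReXModel

__all__ = [
    "GwasSummary",
    "LDReference",
    "TwasResult",
    "EqtlSummary",
    "twas_summary",
    "twas_all_genes",
    "grex_phenotype_linear",
    "FirthLogit",
    "grex_phenotype_firth",
    "cis_eqtl_scan",
    "mhc_filter",
]

MHC_REGION = ("chr6", 28_000_000, 34_000_000)  # broad MHC, 1-based inclusive bounds


@dataclass
class GwasSummary:
    """Per-variant association statistics for one trait in one cohort."""

    table: pd.DataFrame  # variant_id, chrom, pos, a1, a2, beta, se, z, n
    trait_name: str = "trait"
    cohort_name: str = "cohort"

    def __post_init__(self):
        t = self.table
        if (t["se"] <= 0).any():
            raise ValueError("standard errors must be positive")
        if not np.allclose(t["z"], t["beta"] / t["se"], atol=1e-6):
            raise ValueError("z inconsistent with beta/se")


class LDReference:
    """Variant correlation structure from a reference genotype panel."""

    def __init__(self, genotypes: GenotypeMatrix, ridge: float = 0.05):
        self.genotypes = genotypes
        self.ridge = ridge
        self._index = {v: i for i, v in enumerate(genotypes.variants["id"])}

    @property
    def variants(self) -> pd.DataFrame:
        return self.genotypes.variants

    def sd(self, variant_ids) -> np.ndarray:
        idx = [self._index[v] for v in variant_ids]
        return self.genotypes.dosages[:, idx].std(axis=0)

    def correlation(self, variant_ids, regularize: bool = True) -> np.ndarray:
        """Correlation submatrix, optionally ridge-stabilized toward identity."""
        idx = [self._index[v] for v in variant_ids]
        X = self.genotypes.dosages[:, idx]
        sd = X.std(axis=0)
        if (sd == 0).any():
            # monomorphic in the panel: correlation undefined, use identity rows
            C = np.eye(len(idx))
            ok = sd > 0
            if ok.sum() > 1:
                sub = np.corrcoef(X[:, ok], rowvar=False)
                C[np.ix_(ok, ok)] = sub
        elif len(idx) == 1:
            C = np.ones((1, 1))
        else:
            C = np.corrcoef(X, rowvar=False)
        if regularize:
            C = (1 - self.ridge) * C + self.ridge * np.eye(len(idx))
        return C

    def contains(self, variant_id: str) -> bool:
        return variant_id in self._index


@dataclass
class TwasResult:
    feature_id: str
    trait: str
    cohort: str
    z: float
    p: float
    n_model_variants: int = 0
    n_used_variants: int = 0

    @property
    def effect_direction(self) -> int:
        return int(np.sign(self.z))


def mhc_filter(table: pd.DataFrame, region=MHC_REGION) -> pd.DataFrame:
    """Drop variants in the configured MHC interval before association."""
    chrom, lo, hi = region
    drop = (table["chrom"] == chrom) & (table["pos"] >= lo) & (table["pos"] <= hi)
    return table[~drop].reset_index(drop=True)


def twas_summary(model: GReXModel, gwas: GwasSummary, ld: LDReference) -> TwasResult:
    """Gene-trait association from GWAS summary statistics and model weights."""
    w = model.weights.rename(columns={"variant_id": "id"})
    g = gwas.table.rename(columns={"variant_id": "id"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        joined = harmonize_alleles(w, g[["id", "a1", "a2", "beta", "se", "z"]], effect_cols_b=("beta", "z"))
    joined = joined[[ld.contains(v) for v in joined["id"]]]
    n_used = len(joined)
    if n_used == 0:
        raise ValueError(f"gene {model.gene_id!r}: no model variant matched GWAS and LD panel")
    ids = joined["id"].tolist()
    wts = joined["weight"].to_numpy()
    zs = joined["z"].to_numpy()
    # orient the LD panel's dosages to the model's a1: swapped alleles flip
    # the correlation sign pattern; handle by flipping weights for variants
    # whose panel a1 differs from the model a1
    panel = ld.variants.set_index("id")
    panel_a1 = panel.loc[ids, "a1"].astype(str).str.upper().to_numpy()
    model_a1 = joined["a1"].astype(str).str.upper().to_numpy()
    sign = np.where(panel_a1 == model_a1, 1.0, -1.0)
    wts = wts * sign
    zs = zs * sign  # z was harmonized to the model's a1; re-orient to panel a1
    sd = ld.sd(ids)
    C = ld.correlation(ids)
    var_g = float(wts * sd @ C @ (wts * sd))
    if var_g <= 0:
        raise ValueError(f"gene {model.gene_id!r}: non-positive GReX variance in the LD panel")
    sigma_g = np.sqrt(var_g)
    z_g = float(np.sum(wts * sd / sigma_g * zs))
    p = float(2 * stats.norm.sf(abs(z_g)))
    return TwasResult(
        feature_id=model.gene_id,
        trait=gwas.trait_name,
        cohort=gwas.cohort_name,
        z=z_g,
        p=p,
        n_model_variants=len(model.weights),
        n_used_variants=n_used,
    )


def twas_all_genes(models, gwas: GwasSummary, ld: LDReference) -> pd.DataFrame:
    rows = []
    for m in models:
        try:
            r = twas_summary(m, gwas, ld)
        except ValueError:
            continue
        rows.append((r.feature_id, r.trait, r.cohort, r.z, r.p, r.n_model_variants, r.n_used_variants))
    return pd.DataFrame(
        rows, columns=["feature", "trait", "cohort", "z", "p", "n_model_variants", "n_used_variants"]
    )


# ---------------------------------------------------------------------------
# individual-level associations
# ---------------------------------------------------------------------------


def grex_phenotype_linear(grex, phenotype, covariates: pd.DataFrame | None = None):
    """OLS of phenotype on GReX with covariate adjustment; two-sided p.

    Collinear covariates are dropped with a warning. Returns (estimate, se, p).
    """
    import statsmodels.api as sm

    grex = np.asarray(grex, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    cols = [grex]
    names = ["grex"]
    if covariates is not None:
        C = covariates.to_numpy(dtype=float)
        for k, name in enumerate(covariates.columns):
            cand = np.column_stack(cols + [C[:, k]])
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(y))] + [cand])) <= cand.shape[1]:
                warnings.warn(f"covariate {name!r} collinear; dropped", stacklevel=2)
                continue
            cols.append(C[:, k])
            names.append(str(name))
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


class FirthLogit:
    """Firth-penalized logistic regression (Jeffreys-prior bias reduction).

    Maximizes the penalized log-likelihood l(b) + 0.5 log|I(b)| by Newton
    iterations on the modified score U*(b) = X'(y - p + h(0.5 - p)), h being
    the leverages of the weighted design. Estimates stay finite under
    complete separation. Inference is by penalized likelihood ratio.
    """

    def __init__(self, endog, exog, add_intercept: bool = True):
        y = np.asarray(endog, dtype=float)
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        if add_intercept:
            X = np.column_stack([np.ones(len(y)), X])
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("need at least one case and one control")
        self.y, self.X = y, X

    def _penalized_loglike(self, beta):
        eta = self.X @ beta
        ll = float(self.y @ eta - np.logaddexp(0, eta).sum())
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        I = (self.X * W[:, None]).T @ self.X
        sign, logdet = np.linalg.slogdet(I)
        if sign <= 0:
            return -np.inf
        return ll + 0.5 * logdet

    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> "FirthLogitResults":
        X, y = self.X, self.y
        n, k = X.shape
        beta = np.zeros(k)
        trace = []
        for it in range(max_iter):
            eta = X @ beta
            p = 1 / (1 + np.exp(-eta))
            W = p * (1 - p)
            I = (X * W[:, None]).T @ X
            try:
                Iinv = np.linalg.inv(I)
            except np.linalg.LinAlgError as err:
                raise RuntimeError(f"information matrix singular at iteration {it}") from err
            # leverages of the weighted design
            h = np.einsum("ij,jk,ik->i", X * np.sqrt(W)[:, None], Iinv, X * np.sqrt(W)[:, None])
            U = X.T @ (y - p + h * (0.5 - p))
            step = Iinv @ U
            # step-halving on the penalized likelihood
            ll0 = self._penalized_loglike(beta)
            lam = 1.0
            for _ in range(20):
                cand = beta + lam * step
                if self._penalized_loglike(cand) >= ll0 - 1e-12:
                    break
                lam *= 0.5
            beta = beta + lam * step
            trace.append(float(np.max(np.abs(lam * step))))
            if trace[-1] < tol:
                se = np.sqrt(np.diag(Iinv))
                return FirthLogitResults(self, beta, se, it + 1)
        raise RuntimeError(f"Firth logistic regression did not converge; step trace: {trace[-5:]}")


class FirthLogitResults:
    def __init__(self, model: FirthLogit, params: np.ndarray, bse: np.ndarray, n_iter: int):
        self.model = model
        self.params = params
        self.bse = bse
        self.n_iter = n_iter

    def plr_pvalue(self, idx: int) -> float:
        """Penalized-likelihood-ratio p-value for coefficient ``idx`` = 0."""
        full = self.model._penalized_loglike(self.params)
        X = self.model.X
        keep = [j for j in range(X.shape[1]) if j != idx]
        sub = FirthLogit(self.model.y, X[:, keep], add_intercept=False)
        res0 = sub.fit()
        lr = 2 * (full - sub._penalized_loglike(res0.params))
        return float(stats.chi2.sf(max(lr, 0.0), df=1))

    def summary(self) -> str:
        lines = ["Firth logistic regression", f"  converged in {self.n_iter} iterations"]
        for j, (b, s) in enumerate(zip(self.params, self.bse)):
            lines.append(f"  b[{j}] = {b:+.4f} (se {s:.4f})")
        return "\n".join(lines)


def grex_phenotype_firth(grex, status, covariates: pd.DataFrame | None = None):
    """Firth logistic regression of binary status on GReX; returns
    (log-odds estimate, se, penalized-LRT p)."""
    grex = np.asarray(grex, dtype=float)
    cols = [grex]
    if covariates is not None:
        cols.extend(covariates.to_numpy(dtype=float).T)
    X = np.column_stack(cols)
    res = FirthLogit(status, X).fit()
    return float(res.params[1]), float(res.bse[1]), res.plr_pvalue(1)


# ---------------------------------------------------------------------------
# cis-eQTL scan
# ---------------------------------------------------------------------------


@dataclass
class EqtlSummary:
    gene_id: str
    table: pd.DataFrame  # variant_id, chrom, pos, a1, a2, beta, se, p


def cis_eqtl_scan(
    expression_residuals: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    gene_meta: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> dict[str, EqtlSummary]:
    """Per-gene marginal regressions of residual expression on dosage, cis only.

    ``gene_meta`` needs (feature_id, chrom, tss) with tss 0-based; a variant
    at 1-based position p is cis iff |p - 1 - tss| <= window_bp. Monomorphic
    variants are skipped.
    """
    out = {}
    vpos = genotypes.variants["pos"].to_numpy() - 1
    vchrom = genotypes.variants["chrom"].to_numpy()
    sds = genotypes.dosages.std(axis=0)
    fid = {f: i for i, f in enumerate(expression_residuals.feature_ids)}
    for row in gene_meta.itertuples(index=False):
        gene = row.feature_id
        if gene not in fid:
            continue
        sel = (vchrom == row.chrom) & (np.abs(vpos - row.tss) <= window_bp) & (sds > 0)
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            continue
        y = expression_residuals.values[fid[gene]]
        from .synthetic_data import marginal_gwas

        tab = marginal_gwas(genotypes.dosages[:, idx], y, genotypes.variants.iloc[idx])
        n = genotypes.n_samples
        tab["p"] = 2 * stats.t.sf(np.abs(tab["z"]), df=n - 2)
        out[gene] = EqtlSummary(gene_id=gene, table=tab.drop(columns=["cohort"], errors="ignore"))
    return out
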