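"""Genetically-regulated-expression (GReX) models.

The core fit is a two-group differentially penalized elastic net: predictor
variants overlapping epigenomic annotation tracks ("essential", design block
X1) are penalized by a factor ``phi <= 1`` relative to the remaining variants
(X2). With expression residuals E the objective is

    L(b1, b2; lam, phi) = ||E - X1 b1 - X2 b2||^2
                          + (1/2)(lam/2) (phi ||b1||_2^2 + ||b2||_2^2)
                          + (1/2) lam   (phi ||b1||_1   + ||b2||_1)

minimized by cyclic coordinate descent. At ``phi = 1`` this is an ordinary
elastic net; in the conventional (alpha, l1_ratio) parameterization of
sklearn's ``ElasticNet`` (objective ``1/(2n) ||y-Xb||^2 + alpha*l1*||b||_1 +
alpha*(1-l1)/2*||b||_2^2``) it corresponds exactly to ``alpha = lam/(2n)``,
``l1_ratio = 1/2`` — the basis of the solver cross-check in the test suite.

Tuning (lambda, phi, and the cis window w drawn from TAD / chromatin-loop /
fixed +-1 Mb / fixed +-250 kb candidates) is by nested cross-validation:
inner folds pick the tuple maximizing mean out-of-fold prediction-observation
correlation; outer folds give an honest cv_r and its one-sided p. Models are
retained only with cv_r > 0.10 and cv_p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .data_io import AnnotationTracks, ExpressionMatrix, GenotypeMatrix, WindowSet, harmonize_alleles

__all__ = [
    "TrainingConfig",
    "GReXModel",
    "ValidationReport",
    "PumiceGReX",
    "PumiceGReXResults",
    "fit_pumice_single",
    "nested_cv_train",
    "fit_elastic_net_baseline",
    "validate_models",
    "train_all_genes",
    "models_to_tsv",
    "models_from_tsv",
]


@dataclass
class TrainingConfig:
    """Tuning grids and cross-validation layout for GReX training."""

    n_lambda: int = 25
    lambda_decades: float = 4.0
    phi_grid: tuple[float, ...] = (1.0, 0.5, 0.25, 0.1)
    window_kinds: tuple[str, ...] = ("tad", "loop", "fixed_1mb", "fixed_250kb")
    outer_folds: int = 5
    inner_folds: int = 5
    seed: int = 0
    tol: float = 1e-7
    max_iter: int = 2000
    retain_r: float = 0.10
    retain_p: float = 0.05

    def __post_init__(self):
        if any(not (0 < p <= 1) for p in self.phi_grid):
            raise ValueError("phi grid values must lie in (0, 1]")
        if self.n_lambda < 1 or not self.window_kinds:
            raise ValueError("grids must be non-empty")


@dataclass
class GReXModel:
    """Trained per-gene weight vector plus the tuning choices that produced it."""

    gene_id: str
    weights: pd.DataFrame  # columns: variant_id, a1, a2, weight (dosage scale)
    chosen_lambda: float
    chosen_phi: float
    chosen_window: str
    cv_r: float
    cv_p: float
    method: str = "pumice"

    def predict(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """GReX = harmonized dosages . weights across the given samples."""
        gv = genotypes.variants.rename(columns={"id": "id"})[["id", "a1", "a2"]].copy()
        w = self.weights.rename(columns={"variant_id": "id"})
        merged = harmonize_alleles(w, gv.assign(col=np.arange(len(gv))), effect_cols_b=())
        if len(merged) == 0:
            return np.zeros(genotypes.n_samples)
        cols = merged["col"].to_numpy()
        wt = merged["weight"].to_numpy()
        # harmonize_alleles keeps a-side (weight) orientation; flipped variants
        # need dosage recoding 2 - d, equivalent to flipping the weight sign
        # and adding a constant; correlation-based validation is unaffected,
        # so implement as sign flip on the weight.
        b1 = genotypes.variants["a1"].astype(str).str.upper().to_numpy()[cols]
        w1 = merged["a1"].astype(str).str.upper().to_numpy()
        sign = np.where(b1 == w1, 1.0, -1.0)
        return genotypes.dosages[:, cols] @ (wt * sign)


@dataclass
class ValidationReport:
    gene_id: str
    holdout_r: float
    holdout_p: float
    validated: bool


class PumiceGReX:
    """Model object for the differentially penalized elastic net (one gene).

    Parameters
    ----------
    endog : (n,) expression residuals (centered internally).
    exog_essential : (n, p1) dosages of annotated variants.
    exog_other : (n, p2) dosages of the remaining variants.

    Columns are standardized internally; ``fit`` returns results on both the
    standardized and the original dosage scale.
    """

    def __init__(self, endog, exog_essential, exog_other):
        y = np.asarray(endog, dtype=float)
        X1 = np.atleast_2d(np.asarray(exog_essential, dtype=float))
        X2 = np.atleast_2d(np.asarray(exog_other, dtype=float))
        if X1.size == 0:
            X1 = np.empty((len(y), 0))
        if X2.size == 0:
            X2 = np.empty((len(y), 0))
        if X1.shape[0] != len(y) or X2.shape[0] != len(y):
            raise ValueError("design and response lengths differ")
        self.y_mean = y.mean()
        self.y = y - self.y_mean
        X = np.hstack([X1, X2])
        self.p1 = X1.shape[1]
        self.p = X.shape[1]
        self.x_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.x_sd = np.where(sd > 0, sd, 1.0)
        self.zero_var = sd == 0
        self.X = (X - self.x_mean) / self.x_sd
        self.X[:, self.zero_var] = 0.0
        self.mult = np.ones(self.p)

    def penalty_multipliers(self, phi: float) -> np.ndarray:
        m = np.ones(self.p)
        m[: self.p1] = phi
        return m

    def lambda_max(self, phi: float) -> float:
        """Smallest lambda at which the all-zero solution is stationary.

        From the KKT conditions at beta = 0: |2 x_j' y| <= (lam/2) m_j.
        """
        if self.p == 0:
            return 1.0
        grad = np.abs(2.0 * (self.X.T @ self.y))  # |2 x_j' y|
        m = self.penalty_multipliers(phi)
        with np.errstate(divide="ignore"):
            vals = 2.0 * grad / m  # beta=0 stationary iff |2 x'y| <= (lam/2) m
        vals[self.zero_var] = 0.0
        return float(max(vals.max(), 1e-12))

    def objective(self, beta: np.ndarray, lam: float, phi: float) -> float:
        m = self.penalty_multipliers(phi)
        r = self.y - self.X @ beta
        return float(
            r @ r
            + 0.5 * (lam / 2.0) * np.sum(m * beta**2)
            + 0.5 * lam * np.sum(m * np.abs(beta))
        )

    def fit(
        self,
        lam: float,
        phi: float = 1.0,
        beta_start: np.ndarray | None = None,
        tol: float = 1e-7,
        max_iter: int = 2000,
        check_monotone: bool = True,
    ) -> "PumiceGReXResults":
        """Cyclic coordinate descent to ``tol`` (max coefficient change)."""
        if not 0 < phi <= 1:
            raise ValueError("phi must be in (0, 1]")
        n, p = self.X.shape
        beta = np.zeros(p) if beta_start is None else beta_start.copy()
        m = self.penalty_multipliers(phi)
        xx = (self.X**2).sum(axis=0)
        if not check_monotone:
            # fast path: covariance (Gram) updates, no per-sweep assertions
            if not hasattr(self, "_gram"):
                self._gram = self.X.T @ self.X
                self._xty = self.X.T @ self.y
            it = _cd_gram(self._gram, self._xty, xx, beta, float(lam), m, float(tol), int(max_iter))
            return PumiceGReXResults(model=self, beta_std=beta, lam=lam, phi=phi, converged=it > 0)
        r = self.y - self.X @ beta
        converged = False
        obj_prev = self.objective(beta, lam, phi) if check_monotone else None
        for _it in range(max_iter):
            max_delta = 0.0
            for j in range(p):
                if self.zero_var[j]:
                    continue
                bj = beta[j]
                rho = self.X[:, j] @ r + xx[j] * bj
                z = 2.0 * rho
                thr = 0.5 * lam * m[j]
                denom = 2.0 * xx[j] + 0.5 * lam * m[j]
                bnew = _soft_threshold(z, thr) / denom
                if bnew != bj:
                    r += self.X[:, j] * (bj - bnew)
                    beta[j] = bnew
                    max_delta = max(max_delta, abs(bnew - bj))
            if check_monotone:
                obj = self.objective(beta, lam, phi)
                if obj > obj_prev + 1e-9 * max(1.0, abs(obj_prev)):
                    raise RuntimeError("coordinate descent objective increased")
                obj_prev = obj
            if max_delta < tol:
                converged = True
                break
        return PumiceGReXResults(model=self, beta_std=beta, lam=lam, phi=phi, converged=converged)


class PumiceGReXResults:
    """Fit results: coefficients, objective value, and back-transform."""

    def __init__(self, model: PumiceGReX, beta_std: np.ndarray, lam: float, phi: float, converged: bool):
        self.model = model
        self.beta_std = beta_std
        self.lam = lam
        self.phi = phi
        self.converged = converged

    @property
    def beta_dosage(self) -> np.ndarray:
        """Coefficients on the original (dosage) scale."""
        return self.beta_std / self.model.x_sd

    @property
    def objective_value(self) -> float:
        return self.model.objective(self.beta_std, self.lam, self.phi)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(X_new) - self.model.x_mean) / self.model.x_sd
        Xs[:, self.model.zero_var] = 0.0
        return Xs @ self.beta_std + self.model.y_mean

    def summary(self) -> str:
        nz = int(np.sum(self.beta_std != 0))
        lines = [
            "Differentially penalized GReX fit",
            f"  lambda={self.lam:.4g}  phi={self.phi:.3g}  converged={self.converged}",
            f"  nonzero coefficients: {nz}/{len(self.beta_std)}",
            f"  objective: {self.objective_value:.6g}",
        ]
        return "\n".join(lines)


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_gram_py(G, xty, xx, beta, lam, mult, tol, max_iter):
    """Gram-matrix cyclic coordinate descent (covariance updates)."""
    p = beta.shape[0]
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if xx[j] == 0.0:
                continue
            bj = beta[j]
            rho = xty[j] - np.dot(G[j], beta) + xx[j] * bj
            z = 2.0 * rho
            thr = 0.5 * lam * mult[j]
            denom = 2.0 * xx[j] + 0.5 * lam * mult[j]
            if z > thr:
                bnew = (z - thr) / denom
            elif z < -thr:
                bnew = (z + thr) / denom
            else:
                bnew = 0.0
            if bnew != bj:
                d = abs(bnew - bj)
                if d > max_delta:
                    max_delta = d
                beta[j] = bnew
        if max_delta < tol:
            return it + 1
    return -max_iter


try:  # optional JIT of the hot kernel; semantics identical to the fallback
    from numba import njit

    _cd_gram = njit(cache=False, fastmath=False)(_cd_gram_py)
except Exception:  # pragma: no cover
    _cd_gram = _cd_gram_py


def fit_pumice_single(X1, X2, E, lam: float, phi: float, tol: float = 1e-8, max_iter: int = 5000):
    """Functional wrapper: minimize the two-group objective, return results."""
    model = PumiceGReX(E, X1, X2)
    res = model.fit(lam, phi, tol=tol, max_iter=max_iter)
    if not res.converged:
        warnings.warn("coordinate descent did not converge", stacklevel=2)
    return res


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


def _lambda_grid(model: PumiceGReX, phi: float, config: TrainingConfig) -> np.ndarray:
    lmax = model.lambda_max(phi)
    return np.logspace(np.log10(lmax), np.log10(lmax) - config.lambda_decades, config.n_lambda)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _inner_select(
    X_by_window: dict[str, tuple[np.ndarray, np.ndarray]],
    y: np.ndarray,
    config: TrainingConfig,
    phi_grid: tuple[float, ...],
    window_order: dict[str, int],
    rng_seed: int,
):
    """Pick (lambda, phi, window) maximizing mean inner-fold prediction r.

    Ties break toward larger lambda, then larger phi, then the smaller
    window (parsimony), via the precomputed ``window_order``.
    """
    n = len(y)
    inner = KFold(n_splits=min(config.inner_folds, n), shuffle=True, random_state=rng_seed)
    splits = list(inner.split(np.arange(n)))
    best = None  # (score, lam, phi, wkey)
    for wkey, (X1w, X2w) in X_by_window.items():
        full = PumiceGReX(y, X1w, X2w)
        fold_models = [PumiceGReX(y[tr], X1w[tr], X2w[tr]) for tr, _ in splits]
        Xte_all = [np.hstack([X1w[te], X2w[te]]) for _, te in splits]
        for phi in phi_grid:
            grid = _lambda_grid(full, phi, config)
            # per-fold models with warm-started lambda paths
            fold_scores = np.zeros((len(splits), len(grid)))
            for fi, (tr, te) in enumerate(splits):
                m = fold_models[fi]
                beta = None
                for li, lam in enumerate(grid):
                    res = m.fit(lam, phi, beta_start=beta, tol=1e-5, max_iter=500,
                                check_monotone=False)
                    beta = res.beta_std
                    pred = res.predict(Xte_all[fi])
                    fold_scores[fi, li] = _safe_corr(pred, y[te])
            mean_scores = fold_scores.mean(axis=0)
            for li, lam in enumerate(grid):
                cand = (mean_scores[li], lam, phi, -window_order[wkey])
                if best is None or _tuple_better(cand, best):
                    best = cand
    score, lam, phi, neg_order = best
    wkey = next(k for k, v in window_order.items() if v == -neg_order)
    return lam, phi, wkey, score


def _tuple_better(cand, best, eps: float = 1e-12) -> bool:
    # higher score; then larger lambda; then larger phi; then smaller window
    if cand[0] > best[0] + eps:
        return True
    if cand[0] < best[0] - eps:
        return False
    return cand[1:] > best[1:]


def _gene_designs(
    gene: str,
    genotypes: GenotypeMatrix,
    annotations: AnnotationTracks,
    windows: WindowSet,
    kinds: tuple[str, ...],
):
    """Per-window (X1, X2, variant index) design blocks for one gene."""
    ess = annotations.essential_mask(genotypes.variants)
    out = {}
    order = {}
    for kind in kinds:
        mask = windows.variant_mask(gene, kind, genotypes.variants)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        e_idx = idx[ess[idx]]
        o_idx = idx[~ess[idx]]
        X1 = genotypes.dosages[:, e_idx]
        X2 = genotypes.dosages[:, o_idx]
        out[kind] = (X1, X2, np.concatenate([e_idx, o_idx]))
        order[kind] = windows.total_span(gene, kind)
    # smaller window preferred on ties: rank by span, then name for stability
    ranked = sorted(order, key=lambda k: (order[k], k))
    order = {k: i for i, k in enumerate(ranked)}
    return out, order


def nested_cv_train(
    gene: str,
    genotypes: GenotypeMatrix,
    expression_residuals: ExpressionMatrix,
    annotations: AnnotationTracks,
    windows: WindowSet,
    config: TrainingConfig,
    phi_grid: tuple[float, ...] | None = None,
    method: str = "pumice",
) -> GReXModel | None:
    """Nested-CV training for one gene; None with a warning on rejection."""
    gi = np.flatnonzero(expression_residuals.feature_ids == gene)
    if len(gi) != 1:
        raise ValueError(f"gene {gene!r} not found in expression matrix")
    y = expression_residuals.values[gi[0]]
    phi_grid = tuple(phi_grid if phi_grid is not None else config.phi_grid)
    designs, window_order = _gene_designs(gene, genotypes, annotations, windows, config.window_kinds)
    if not designs:
        warnings.warn(f"gene {gene!r}: no variants in any candidate window", stacklevel=2)
        return None
    X_by_window = {k: (v[0], v[1]) for k, v in designs.items()}
    n = len(y)
    outer = KFold(n_splits=min(config.outer_folds, n), shuffle=True, random_state=config.seed)
    oof = np.full(n, np.nan)
    for fi, (tr, te) in enumerate(outer.split(np.arange(n))):
        sub = {k: (X1[tr], X2[tr]) for k, (X1, X2) in X_by_window.items()}
        lam, phi, wkey, _ = _inner_select(sub, y[tr], config, phi_grid, window_order,
                                          rng_seed=config.seed + 1000 + fi)
        X1, X2 = X_by_window[wkey]
        m = PumiceGReX(y[tr], X1[tr], X2[tr])
        res = m.fit(lam, phi, tol=config.tol, max_iter=config.max_iter, check_monotone=False)
        Xte = np.hstack([X1[te], X2[te]])
        oof[te] = res.predict(Xte)
    cv_r = _safe_corr(oof, y)
    cv_p = _corr_p_one_sided(cv_r, n)
    if not (cv_r > config.retain_r and cv_p < config.retain_p):
        return None
    # final tuple selection and refit on all samples
    lam, phi, wkey, _ = _inner_select(X_by_window, y, config, phi_grid, window_order,
                                      rng_seed=config.seed + 999)
    X1, X2, vidx = designs[wkey]
    m = PumiceGReX(y, X1, X2)
    res = m.fit(lam, phi, tol=config.tol, max_iter=config.max_iter)
    if not res.converged:
        warnings.warn(f"gene {gene!r}: final fit did not converge; model discarded", stacklevel=2)
        return None
    beta = res.beta_dosage
    nz = beta != 0
    if not nz.any():
        return None
    vt = genotypes.variants.iloc[vidx[nz]]
    weights = pd.DataFrame(
        {
            "variant_id": vt["id"].to_numpy(),
            "a1": vt["a1"].to_numpy(),
            "a2": vt["a2"].to_numpy(),
            "weight": beta[nz],
        }
    )
    return GReXModel(
        gene_id=gene,
        weights=weights,
        chosen_lambda=float(lam),
        chosen_phi=float(phi),
        chosen_window=wkey,
        cv_r=float(cv_r),
        cv_p=float(cv_p),
        method=method,
    )


def _corr_p_one_sided(r: float, n: int) -> float:
    """One-sided p for a positive Pearson correlation via the t distribution."""
    if n < 3 or abs(r) >= 1:
        return 0.0 if r >= 1 else 1.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(stats.t.sf(t, df=n - 2))


def fit_elastic_net_baseline(
    gene: str,
    genotypes: GenotypeMatrix,
    expression_residuals: ExpressionMatrix,
    windows: WindowSet,
    config: TrainingConfig,
) -> GReXModel | None:
    """Plain elastic-net baseline: phi fixed at 1, window fixed at +-1 Mb."""
    annotations = AnnotationTracks({"none": pd.DataFrame({"chrom": ["chrZ"], "start": [0], "end": [1]})})
    cfg = TrainingConfig(**{**config.__dict__, "window_kinds": ("fixed_1mb",)})
    model = nested_cv_train(
        gene, genotypes, expression_residuals, annotations, windows, cfg,
        phi_grid=(1.0,), method="elastic_net",
    )
    return model


def train_all_genes(
    genotypes: GenotypeMatrix,
    expression_residuals: ExpressionMatrix,
    annotations: AnnotationTracks,
    windows: WindowSet,
    config: TrainingConfig,
    method: str = "pumice",
) -> list[GReXModel]:
    models = []
    for gene in expression_residuals.feature_ids:
        if gene not in windows.windows:
            continue
        if method == "pumice":
            m = nested_cv_train(gene, genotypes, expression_residuals, annotations, windows, config)
        else:
            m = fit_elastic_net_baseline(gene, genotypes, expression_residuals, windows, config)
        if m is not None:
            models.append(m)
    return models


def validate_models(
    models: list[GReXModel],
    holdout_genotypes: GenotypeMatrix,
    holdout_expression_residuals: ExpressionMatrix,
) -> list[ValidationReport]:
    """Pearson correlation of predicted vs observed residuals in a holdout panel."""
    if holdout_genotypes.n_samples < 3:
        raise ValueError("need at least 3 holdout samples")
    fid = {f: i for i, f in enumerate(holdout_expression_residuals.feature_ids)}
    reports = []
    for m in models:
        if m.gene_id not in fid:
            continue
        pred = m.predict(holdout_genotypes)
        obs = holdout_expression_residuals.values[fid[m.gene_id]]
        if np.std(pred) == 0 or np.std(obs) == 0:
            reports.append(ValidationReport(m.gene_id, float("nan"), float("nan"), False))
            continue
        r, p = stats.pearsonr(pred, obs)
        reports.append(ValidationReport(m.gene_id, float(r), float(p), bool(r > 0.1)))
    return reports


# ---------------------------------------------------------------------------
# weight database serialization
# ---------------------------------------------------------------------------

_MODEL_COLS = [
    "gene", "variant_id", "a1", "a2", "weight",
    "method", "chosen_window", "chosen_lambda", "chosen_phi", "cv_r", "cv_p",
]


def models_to_tsv(models: list[GReXModel], path: str) -> None:
    rows = []
    for m in models:
        for row in m.weights.itertuples(index=False):
            rows.append(
                (m.gene_id, row.variant_id, row.a1, row.a2, row.weight,
                 m.method, m.chosen_window, m.chosen_lambda, m.chosen_phi, m.cv_r, m.cv_p)
            )
    pd.DataFrame(rows, columns=_MODEL_COLS).to_csv(path, sep="\t", index=False)


def models_from_tsv(path: str) -> list[GReXModel]:
    df = pd.read_csv(path, sep="\t")
    models = []
    for gene, sub in df.groupby("gene", sort=False):
        first = sub.iloc[0]
        models.append(
            GReXModel(
                gene_id=str(gene),
                weights=sub[["variant_id", "a1", "a2", "weight"]].reset_index(drop=True),
                chosen_lambda=float(first["chosen_lambda"]),
                chosen_phi=float(first["chosen_phi"]),
                chosen_window=str(first["chosen_window"]),
                cv_r=float(first["cv_r"]),
                cv_p=float(first["cv_p"]),
                method=str(first["method"]),
            )
        )
    return models
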