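"""Two-sample Mendelian randomization, mediation decomposition, and the
conditional-Z host-gene test.

Estimators
----------
* IVW: weighted regression of outcome betas on exposure betas through the
  origin with weights 1/se_out^2. The penalized variant down-weights
  heterogeneous instruments by w_j <- w_j * min(1, q_crit / q_j), where q_j
  is instrument j's contribution to Cochran's Q and q_crit the chi2_1 0.95
  quantile. The correlated-instrument variant is GLS with covariance
  diag(se_out) Sigma diag(se_out).
* MR-Egger: weighted regression with an intercept after orienting
  beta_exposure >= 0; the intercept tests directional pleiotropy. Residual
  overdispersion inflates the SEs (multiplicative random-effects, floored
  at 1), the usual Egger convention.

Two-step mediation: indirect = B_EM * B_MO, MP = indirect / B_total, with
delta-method SEs treating the factors (and numerator/denominator) as
independent.

Conditional Z: Z_cond = (Z_gene - r * Z_miRNA) / sqrt(1 - r^2); mediation is
called when |r| > 0.1, |Z_gene| > |Z_cond| > 2 and sign(Z_cond) = sign(Z_gene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeMatrix
from .assoc import EqtlSummary, LDReference
from .grex import GReXModel

__all__ = [
    "InstrumentSet",
    "MRResult",
    "MediationResult",
    "ld_clump",
    "ivw",
    "mr_egger",
    "two_step_mediation",
    "conditional_z",
    "grex_genetic_correlation",
]


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effect estimates for selected instruments."""

    variant_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    correlation: np.ndarray | None = None  # instrument LD (unit diagonal)

    def __post_init__(self):
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        if self.correlation is not None:
            self.correlation = np.asarray(self.correlation, dtype=float)
            if not np.allclose(np.diag(self.correlation), 1.0):
                raise ValueError("instrument correlation must have unit diagonal")

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class MRResult:
    estimate: float
    se: float
    p: float
    method: str
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    cochran_q: float | None = None

    def significant_causal(self, pleiotropy_p: float | None = None, alpha: float = 0.05) -> bool:
        """Effect significant AND no pleiotropy evidence (when tested)."""
        ok = self.p < alpha
        if pleiotropy_p is not None:
            ok = ok and pleiotropy_p > alpha
        return bool(ok)

    def summary(self) -> str:
        lines = [
            f"MR ({self.method}), {self.n_instruments} instruments",
            f"  estimate = {self.estimate:+.4f} (se {self.se:.4f}, p {self.p:.3g})",
        ]
        if self.egger_intercept is not None:
            lines.append(
                f"  Egger intercept = {self.egger_intercept:+.4f} (p {self.egger_intercept_p:.3g})"
            )
        return "\n".join(lines)


def ld_clump(
    eqtl: EqtlSummary,
    ld: LDReference,
    p_max: float = 1e-3,
    r2_max: float = 0.5,
) -> pd.DataFrame:
    """Greedy LD clumping of cis-eQTL variants for instrument selection.

    Sort by p ascending; keep a variant iff its r^2 with every kept variant
    stays below ``r2_max``; stop once p exceeds ``p_max``.
    """
    tab = eqtl.table.dropna(subset=["p"]).sort_values(["p", "variant_id"], kind="stable")
    tab = tab[tab["p"] <= p_max]
    tab = tab[[ld.contains(v) for v in tab["variant_id"]]]
    kept: list[str] = []
    rows = []
    for row in tab.itertuples(index=False):
        if kept:
            C = ld.correlation(kept + [row.variant_id], regularize=False)
            if (C[-1, :-1] ** 2 >= r2_max).any():
                continue
        kept.append(row.variant_id)
        rows.append(row)
    if not rows:
        raise ValueError(f"gene {eqtl.gene_id!r}: no instruments survive clumping; MR cannot run")
    return pd.DataFrame(rows, columns=tab.columns)


def _q_contributions(bx, by, se_out, est):
    w = 1.0 / se_out**2
    return w * (by - est * bx) ** 2


def ivw(instr: InstrumentSet, penalized: bool = False, use_correlation: bool = False) -> MRResult:
    """Inverse-variance-weighted causal estimate (fixed-effect weights).

    With one instrument this reduces to the Wald ratio with a delta-method
    SE. ``use_correlation`` switches to GLS with the instrument LD matrix.
    """
    bx, by = instr.beta_exposure, instr.beta_outcome
    so = instr.se_outcome
    k = len(instr)
    if k == 0:
        raise ValueError("empty instrument set")
    if k == 1:
        est = float(by[0] / bx[0])
        # first-order delta method for the ratio
        se = float(
            abs(est) * np.sqrt(so[0] ** 2 / by[0] ** 2 + instr.se_exposure[0] ** 2 / bx[0] ** 2)
            if by[0] != 0
            else so[0] / abs(bx[0])
        )
        z = est / se
        return MRResult(est, se, float(2 * stats.norm.sf(abs(z))), "wald_ratio", 1)
    if use_correlation:
        if instr.correlation is None:
            raise ValueError("use_correlation=True requires an instrument correlation matrix")
        V = np.outer(so, so) * instr.correlation
        est, se = _gls_origin(bx, by, V)
        method = "ivw_correlated"
        q = None
    else:
        w = 1.0 / so**2
        est = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        q_j = _q_contributions(bx, by, so, est)
        q = float(q_j.sum())
        method = "ivw"
        if penalized:
            q_crit = stats.chi2.ppf(0.95, df=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.minimum(1.0, q_crit / q_j)
            factor[~np.isfinite(factor)] = 1.0
            w = w * factor
            est = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
            method = "ivw_penalized"
        se = float(1.0 / np.sqrt(np.sum(w * bx * bx)))
    z = est / se
    return MRResult(est, se, float(2 * stats.norm.sf(abs(z))), method, k, cochran_q=q)


def _gls_origin(bx, by, V):
    """GLS regression through the origin; regularize V if singular."""
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        V = V + 1e-8 * np.eye(len(bx)) * np.diag(V).mean()
        try:
            Vi = np.linalg.inv(V)
        except np.linalg.LinAlgError as err:
            raise ValueError("GLS covariance singular even after regularization") from err
    denom = float(bx @ Vi @ bx)
    est = float(bx @ Vi @ by) / denom
    se = float(1.0 / np.sqrt(denom))
    return est, se


def mr_egger(instr: InstrumentSet, use_correlation: bool = False) -> MRResult:
    """MR-Egger regression: slope = causal estimate, intercept = pleiotropy.

    Instruments are oriented so beta_exposure >= 0 (InSIDE convention).
    """
    k = len(instr)
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    flip = np.sign(instr.beta_exposure)
    flip[flip == 0] = 1.0
    bx = instr.beta_exposure * flip
    by = instr.beta_outcome * flip
    so = instr.se_outcome
    if np.ptp(bx) == 0:
        raise ValueError("identical exposure betas: Egger slope inestimable")
    X = np.column_stack([np.ones(k), bx])
    if use_correlation:
        if instr.correlation is None:
            raise ValueError("use_correlation=True requires an instrument correlation matrix")
        R = instr.correlation * np.outer(flip, flip)
        V = np.outer(so, so) * R
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        cov = np.linalg.inv(XtVi @ X)
        coef = cov @ (XtVi @ by)
        resid = by - X @ coef
        phi = max(1.0, float(resid @ Vi @ resid) / (k - 2))
    else:
        w = 1.0 / so**2
        W = np.diag(w)
        cov = np.linalg.inv(X.T @ W @ X)
        coef = cov @ (X.T @ W @ by)
        resid = by - X @ coef
        phi = max(1.0, float(np.sum(w * resid**2)) / (k - 2))
    cov = cov * phi
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    icpt, icpt_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    t_slope = slope / slope_se
    t_icpt = icpt / icpt_se
    p_slope = float(2 * stats.t.sf(abs(t_slope), df=k - 2))
    p_icpt = float(2 * stats.t.sf(abs(t_icpt), df=k - 2))
    return MRResult(
        slope, slope_se, p_slope,
        "egger_correlated" if use_correlation else "egger",
        k, egger_intercept=icpt, egger_intercept_p=p_icpt,
    )


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    """Two-step MR mediation decomposition with delta-method uncertainty."""

    B_EM: float
    SE_EM: float
    B_MO: float
    SE_MO: float
    B_total: float
    SE_total: float
    B_indirect: float
    SE_indirect: float
    MP: float
    SE_MP: float
    p_indirect: float
    gates: dict | None = None

    def summary(self) -> str:
        return "\n".join(
            [
                "Two-step MR mediation",
                f"  exposure->mediator B_EM = {self.B_EM:+.4f} (se {self.SE_EM:.4f})",
                f"  mediator->outcome B_MO = {self.B_MO:+.4f} (se {self.SE_MO:.4f})",
                f"  total effect     B_tot = {self.B_total:+.4f} (se {self.SE_total:.4f})",
                f"  indirect = {self.B_indirect:+.4f} (se {self.SE_indirect:.4f}, p {self.p_indirect:.3g})",
                f"  mediation proportion MP = {self.MP:.4f} (se {self.SE_MP:.4f})",
            ]
        )


def two_step_mediation(
    mr_EM: MRResult,
    mr_MO: MRResult,
    mr_EO: MRResult,
    gates: dict | None = None,
    total_tol: float = 1e-12,
) -> MediationResult:
    """Combine the three univariable MR fits into the mediation decomposition.

    indirect = B_EM * B_MO, SE by the product delta method; MP = indirect /
    B_total with numerator and denominator treated as independent. Gate
    outcomes (per-step significance / pleiotropy screens) are carried along,
    not enforced.
    """
    b_em, se_em = mr_EM.estimate, mr_EM.se
    b_mo, se_mo = mr_MO.estimate, mr_MO.se
    b_tot, se_tot = mr_EO.estimate, mr_EO.se
    b_ind = b_em * b_mo
    se_ind = float(np.sqrt(b_em**2 * se_mo**2 + b_mo**2 * se_em**2))
    if se_ind > 0:
        p_ind = float(2 * stats.norm.sf(abs(b_ind) / se_ind))
    else:
        p_ind = 0.0 if b_ind != 0 else 1.0
    if abs(b_tot) <= total_tol:
        warnings.warn("total effect ~ 0: mediation proportion undefined", stacklevel=2)
        mp = float("nan")
        se_mp = float("nan")
    else:
        mp = b_ind / b_tot
        if b_ind == 0:
            se_mp = float(se_ind / abs(b_tot))
        else:
            se_mp = float(abs(mp) * np.sqrt(se_ind**2 / b_ind**2 + se_tot**2 / b_tot**2))
    return MediationResult(
        B_EM=float(b_em), SE_EM=float(se_em),
        B_MO=float(b_mo), SE_MO=float(se_mo),
        B_total=float(b_tot), SE_total=float(se_tot),
        B_indirect=float(b_ind), SE_indirect=se_ind,
        MP=float(mp), SE_MP=se_mp, p_indirect=p_ind,
        gates=gates,
    )


# ---------------------------------------------------------------------------
# conditional Z
# ---------------------------------------------------------------------------


@dataclass
class ConditionalZResult:
    z_conditional: float
    mediation_verdict: bool


def conditional_z(z_gene: float, z_mirna: float, r: float) -> ConditionalZResult:
    """Condition a gene's TWAS z-score on a correlated miRNA's signal.

    Z_cond = (Z_gene - r Z_miRNA) / sqrt(1 - r^2). The mediation verdict is
    positive iff |r| > 0.1, |Z_gene| > |Z_cond| > 2 and sign(Z_cond) equals
    sign(Z_gene).
    """
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1 (degenerate genetic correlation)")
    z_cond = (z_gene - r * z_mirna) / np.sqrt(1 - r * r)
    verdict = (
        abs(r) > 0.1
        and abs(z_gene) > abs(z_cond) > 2
        and np.sign(z_cond) == np.sign(z_gene)
    )
    return ConditionalZResult(float(z_cond), bool(verdict))


def grex_genetic_correlation(
    model_a: GReXModel,
    model_b: GReXModel,
    reference_genotypes: GenotypeMatrix,
) -> float:
    """cis genetic correlation: Pearson r of the two imputed scores in a panel."""
    sa = model_a.predict(reference_genotypes)
    sb = model_b.predict(reference_genotypes)
    if np.std(sa) == 0 or np.std(sb) == 0:
        warnings.warn("zero-variance imputed score: genetic correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(sa, sb)[0, 1])
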