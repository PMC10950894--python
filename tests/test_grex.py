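"""Solver correctness (elastic-net collapse, KKT bounds, closed forms,
brute-force oracle), nested-CV behaviour and the retention/validation rules."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import ElasticNet

from omixtwas.data_io import AnnotationTracks, ExpressionMatrix, GenotypeMatrix
from omixtwas.grex import (
    GReXModel,
    PumiceGReX,
    TrainingConfig,
    fit_elastic_net_baseline,
    fit_pumice_single,
    models_from_tsv,
    models_to_tsv,
    nested_cv_train,
    train_all_genes,
    validate_models,
)
from omixtwas.synthetic_data import (
    SimulationConfig,
    simulate_annotations_and_windows,
    simulate_expression,
    simulate_genotypes,
    _draw_dosages,
)


def brute_force_objective(model: PumiceGReX, lam: float, phi: float) -> float:
    """Independent minimizer: smooth reformulation beta = b+ - b- with
    non-negativity bounds, solved by SLSQP."""
    p = model.X.shape[1]
    mult = model.penalty_multipliers(phi)

    def f(u):
        bp, bm = u[:p], u[p:]
        b = bp - bm
        r = model.y - model.X @ b
        return r @ r + 0.5 * (lam / 2) * np.sum(mult * b**2) + 0.5 * lam * np.sum(mult * (bp + bm))

    res = minimize(f, np.zeros(2 * p), bounds=[(0, None)] * (2 * p), method="SLSQP",
                   options={"maxiter": 1000, "ftol": 1e-14})
    b = res.x[:p] - res.x[p:]
    return model.objective(b, lam, phi)


class TestSolver:
    def test_phi_one_equals_elastic_net(self, rng):
        """At phi=1 the two-group objective is an ordinary elastic net with
        sklearn parameters alpha = lam/(2n), l1_ratio = 1/2."""
        n, p = 150, 10
        X = rng.standard_normal((n, p))
        y = X[:, :3] @ np.array([0.5, -0.3, 0.2]) + rng.standard_normal(n)
        m = PumiceGReX(y, X[:, :4], X[:, 4:])
        for lam in (5.0, 20.0, 80.0):
            mine = m.fit(lam, 1.0, tol=1e-12, max_iter=50000).beta_std
            en = ElasticNet(alpha=lam / (2 * n), l1_ratio=0.5, fit_intercept=False,
                            tol=1e-12, max_iter=200000).fit(m.X, m.y)
            np.testing.assert_allclose(mine, en.coef_, atol=1e-6)

    def test_all_zero_beyond_lambda_max(self, rng):
        X = rng.standard_normal((100, 6))
        y = X[:, 0] * 0.8 + rng.standard_normal(100)
        m = PumiceGReX(y, X[:, :3], X[:, 3:])
        for phi in (1.0, 0.5, 0.1):
            lmax = m.lambda_max(phi)
            assert np.all(m.fit(lmax * 1.000001, phi).beta_std == 0)
            assert np.any(m.fit(lmax * 0.99, phi).beta_std != 0)

    def test_univariate_soft_threshold_closed_form(self, rng):
        """Single essential predictor: the coordinate-descent solution equals
        the explicit soft-threshold formula with phi-scaled penalties."""
        n = 200
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n)
        m = PumiceGReX(y, x.reshape(-1, 1), np.empty((n, 0)))
        xs = m.X[:, 0]
        for lam, phi in [(10.0, 1.0), (10.0, 0.25), (300.0, 0.5)]:
            z = 2.0 * xs @ m.y
            thr = 0.5 * lam * phi
            expected = np.sign(z) * max(abs(z) - thr, 0) / (2 * xs @ xs + 0.5 * lam * phi)
            got = m.fit(lam, phi, tol=1e-14).beta_std[0]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_brute_force_minimizer(self, rng):
        for trial in range(4):
            n = 80
            p1, p2 = rng.integers(1, 4), rng.integers(1, 4)
            X = rng.standard_normal((n, p1 + p2))
            y = X @ rng.standard_normal(p1 + p2) * 0.3 + rng.standard_normal(n)
            m = PumiceGReX(y, X[:, :p1], X[:, p1:])
            for lam, phi in [(10.0, 1.0), (40.0, 0.5), (100.0, 0.1)]:
                mine = m.fit(lam, phi, tol=1e-12, max_iter=50000).objective_value
                brute = brute_force_objective(m, lam, phi)
                assert mine <= brute + 1e-4
                assert abs(mine - brute) < 1e-4

    def test_objective_monotone_under_assertions(self, rng):
        # the monotonicity guard runs every sweep in the default fit path
        X = rng.standard_normal((120, 15))
        y = X[:, :5] @ rng.standard_normal(5) + rng.standard_normal(120)
        m = PumiceGReX(y, X[:, :7], X[:, 7:])
        res = m.fit(25.0, 0.5, check_monotone=True)
        assert res.converged

    def test_smaller_phi_never_shrinks_essential_more(self, rng):
        """On orthogonal designs the essential L1 norm is non-decreasing as
        phi decreases (closed-form per-coordinate soft threshold)."""
        n = 64
        Q, _ = np.linalg.qr(rng.standard_normal((n, 8)))
        X = Q * np.sqrt(n)  # orthonormal columns after standardization
        y = X[:, :4] @ np.array([0.5, -0.4, 0.3, 0.2]) + 0.1 * rng.standard_normal(n)
        m = PumiceGReX(y, X[:, :4], X[:, 4:])
        lam = m.lambda_max(1.0) * 0.3
        norms = []
        for phi in (1.0, 0.5, 0.25, 0.1):
            b = m.fit(lam, phi, tol=1e-12).beta_std
            norms.append(np.abs(b[:4]).sum())
        assert all(norms[i + 1] >= norms[i] - 1e-10 for i in range(len(norms) - 1))

    def test_invalid_phi_rejected(self, rng):
        X = rng.standard_normal((30, 2))
        m = PumiceGReX(X @ [1, 1], X[:, :1], X[:, 1:])
        for phi in (0.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                m.fit(1.0, phi)

    def test_fast_path_agrees_with_checked_path(self, rng):
        X = rng.standard_normal((90, 12))
        y = X[:, :4] @ rng.standard_normal(4) + rng.standard_normal(90)
        m = PumiceGReX(y, X[:, :6], X[:, 6:])
        slow = m.fit(30.0, 0.5, tol=1e-12, check_monotone=True).beta_std
        fast = m.fit(30.0, 0.5, tol=1e-12, check_monotone=False).beta_std
        np.testing.assert_allclose(slow, fast, atol=1e-9)


def _sim_training_set(n_genes=30, n=400, h2=0.5, seed=0, enrichment=50.0):
    cfg = SimulationConfig(
        n_individuals_ref=n, n_genes=n_genes, n_variants_per_locus=20,
        h2_cis=h2, essential_enrichment=enrichment, seed=seed,
    )
    g = simulate_genotypes(cfg)
    ann, win = simulate_annotations_and_windows(cfg, g.variants)
    expr, truth = simulate_expression(g, ann, cfg)
    return cfg, g, ann, win, expr, truth


@pytest.fixture(scope="module")
def planted():
    return _sim_training_set(n_genes=30, n=400, h2=0.5, seed=21)


@pytest.fixture(scope="module")
def models_pair(planted):
    cfg, g, ann, win, expr, truth = planted
    tc = TrainingConfig(n_lambda=10, phi_grid=(1.0, 0.5, 0.25), outer_folds=3,
                        inner_folds=3, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pumice = train_all_genes(g, expr, ann, win, tc)
        enet = train_all_genes(g, expr, ann, win, tc, method="enet")
    return pumice, enet


class TestNestedCV:
    def test_heritable_genes_mostly_retained(self, models_pair, planted):
        pumice, _ = models_pair
        assert len(pumice) >= 0.8 * planted[0].n_genes

    def test_retained_models_satisfy_filter(self, models_pair):
        for m in models_pair[0]:
            assert m.cv_r > 0.10 and m.cv_p < 0.05
            assert len(m.weights) > 0

    def test_pumice_at_least_as_good_as_baseline(self, models_pair):
        pumice, enet = models_pair
        pr = {m.gene_id: m.cv_r for m in pumice}
        er = {m.gene_id: m.cv_r for m in enet}
        shared = sorted(set(pr) & set(er))
        assert len(shared) >= 10
        diff = np.mean([pr[g] - er[g] for g in shared])
        assert diff > -0.02  # annotation-informed fit not worse on average

    def test_null_genes_rarely_retained(self):
        cfg, g, ann, win, expr, truth = _sim_training_set(n_genes=100, n=200, h2=0.0, seed=22)
        tc = TrainingConfig(n_lambda=6, phi_grid=(1.0,), window_kinds=("fixed_1mb",),
                            outer_folds=3, inner_folds=3, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = train_all_genes(g, expr, ann, win, tc)
        assert len(models) <= 7  # near the nominal 5% of the cv_p filter

    def test_rejection_when_no_variants_in_window(self):
        cfg, g, ann, win, expr, truth = _sim_training_set(n_genes=2, n=100, seed=23)
        # point the gene at an empty region
        win.windows["gene0"] = {k: [("chrX", 0, 10)] for k in win.windows["gene0"]}
        tc = TrainingConfig(n_lambda=4, phi_grid=(1.0,), outer_folds=2, inner_folds=2, seed=3)
        with pytest.warns(UserWarning, match="no variants"):
            out = nested_cv_train("gene0", g, expr, ann, win, tc)
        assert out is None

    def test_unknown_gene_raises(self, planted):
        cfg, g, ann, win, expr, truth = planted
        tc = TrainingConfig(seed=0)
        with pytest.raises(ValueError, match="not found"):
            nested_cv_train("nope", g, expr, ann, win, tc)


@pytest.fixture(scope="module")
def trained():
    # genes span a range of cis heritabilities so discovery performance
    # has real between-gene variation to track in validation
    cfg = SimulationConfig(n_individuals_ref=400, n_genes=40,
                           n_variants_per_locus=20, seed=31)
    g = simulate_genotypes(cfg)
    ann, win = simulate_annotations_and_windows(cfg, g.variants)
    rng = np.random.default_rng(31)
    h2s = np.linspace(0.1, 0.7, cfg.n_genes)
    causal, betas = {}, {}
    vals = np.zeros((cfg.n_genes, cfg.n_individuals_ref))
    for gi in range(cfg.n_genes):
        idx = [gi * 20 + 3, gi * 20 + 11]
        b = rng.standard_normal(2)
        gv = g.dosages[:, idx] @ b
        sd = np.sqrt(np.var(gv) * (1 - h2s[gi]) / h2s[gi])
        vals[gi] = gv + sd * rng.standard_normal(cfg.n_individuals_ref)
        causal[f"gene{gi}"], betas[f"gene{gi}"] = idx, b
    expr = ExpressionMatrix(
        feature_ids=np.array([f"gene{i}" for i in range(cfg.n_genes)], dtype=object),
        sample_ids=g.sample_ids, values=vals,
    )
    tc = TrainingConfig(n_lambda=8, phi_grid=(1.0, 0.5), outer_folds=3, inner_folds=3,
                        window_kinds=("fixed_1mb", "fixed_250kb"), seed=4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models = train_all_genes(g, expr, ann, win, tc)
    # independent holdout drawn from the same generative process
    mafs = g.variants.attrs["mafs"]
    hd = _draw_dosages(cfg, mafs, 250, rng)
    hold = GenotypeMatrix(
        sample_ids=np.array([f"h{i}" for i in range(250)], dtype=object),
        variants=g.variants, dosages=hd,
    )
    hvals = np.zeros((cfg.n_genes, 250))
    for gi in range(cfg.n_genes):
        gv = hd[:, causal[f"gene{gi}"]] @ betas[f"gene{gi}"]
        sd = np.sqrt(np.var(gv) * (1 - h2s[gi]) / h2s[gi])
        hvals[gi] = gv + sd * rng.standard_normal(250)
    hexpr = ExpressionMatrix(
        feature_ids=expr.feature_ids, sample_ids=hold.sample_ids, values=hvals,
    )
    return models, hold, hexpr


class TestValidation:

    def test_holdout_performance_tracks_cv(self, trained):
        models, hold, hexpr = trained
        reports = validate_models(models, hold, hexpr)
        assert len(reports) == len(models)
        cv = np.array([m.cv_r for m in models])
        ho = np.array([r.holdout_r for r in reports])
        assert abs(np.median(ho) - np.median(cv)) < 0.1
        # discovery vs validation performance strongly correlated
        assert np.corrcoef(cv, ho)[0, 1] > 0.6
        assert np.mean([r.validated for r in reports]) > 0.7

    def test_zero_weight_model_flagged(self, trained):
        models, hold, hexpr = trained
        dummy = GReXModel(
            gene_id=models[0].gene_id,
            weights=pd.DataFrame({"variant_id": ["rs0"], "a1": ["A"], "a2": ["G"], "weight": [0.0]}),
            chosen_lambda=1.0, chosen_phi=1.0, chosen_window="fixed_1mb",
            cv_r=0.5, cv_p=0.01,
        )
        rep = validate_models([dummy], hold, hexpr)[0]
        assert not rep.validated and np.isnan(rep.holdout_r)

    def test_too_few_holdout_samples(self, trained):
        models, hold, hexpr = trained
        tiny = hold.subset_samples(np.arange(2))
        with pytest.raises(ValueError, match="holdout"):
            validate_models(models, tiny, hexpr)

    def test_model_tsv_round_trip(self, trained, tmp_path):
        models, *_ = trained
        path = str(tmp_path / "models.tsv")
        models_to_tsv(models, path)
        back = models_from_tsv(path)
        assert len(back) == len(models)
        np.testing.assert_allclose(
            back[0].weights["weight"].to_numpy(), models[0].weights["weight"].to_numpy()
        )
        assert back[0].chosen_window == models[0].chosen_window
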