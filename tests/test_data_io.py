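"""IO, QC and normalization: exact HWE vs enumeration, threshold rules,
the normalization chain's closed forms, allele harmonization, round-trips."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from omixtwas.data_io import (
    ExpressionMatrix,
    GenotypeMatrix,
    harmonize_alleles,
    hwe_exact_test,
    inverse_normal_transform,
    normalize_expression,
    quantile_normalize,
    filter_expressed,
    read_bed,
    read_expression_tsv,
    read_gwas_tsv,
    variant_qc,
    write_bed,
    write_expression_tsv,
    write_gwas_tsv,
)


def _hwe_enumeration(n_hom1, n_het, n_hom2):
    """Independent brute-force exact HWE p: enumerate heterozygote counts and
    sum exact conditional probabilities no larger than the observed one."""
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het  # allele A count
    probs = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        r = (na - h) // 2
        c = n - h - r
        if r < 0 or c < 0:
            continue
        # P(h | allele counts) via multinomial / binomial identity
        probs[h] = (
            comb(n, r, exact=True) * comb(n - r, h, exact=True) * 2**h
        )
    total = sum(probs.values())
    obs = probs[n_het]
    return sum(v for v in probs.values() if v <= obs) / total


class TestHWE:
    def test_perfect_proportions_high_p(self):
        assert hwe_exact_test(25, 50, 25) >= 0.5

    def test_extreme_disequilibrium_tiny_p(self):
        assert hwe_exact_test(50, 0, 50) < 1e-10

    @pytest.mark.parametrize("counts", [
        (25, 50, 25), (50, 0, 50), (10, 5, 1), (0, 10, 0), (3, 3, 3),
        (40, 20, 40), (1, 1, 1), (90, 9, 1), (7, 0, 3),
    ])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(_hwe_enumeration(*counts), rel=1e-9)

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(30):
            c = tuple(int(x) for x in rng.integers(0, 40, size=3))
            if sum(c) == 0:
                continue
            assert hwe_exact_test(*c) == pytest.approx(_hwe_enumeration(*c), rel=1e-9)


def _gm(dosages, **kw):
    n, p = dosages.shape
    variants = pd.DataFrame({
        "id": [f"v{i}" for i in range(p)],
        "chrom": "chr1",
        "pos": np.arange(1, p + 1) * 100,
        "a1": "A",
        "a2": "G",
    })
    return GenotypeMatrix(
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        variants=variants,
        dosages=dosages,
        **kw,
    )


class TestVariantQC:
    def test_low_maf_removed_at_threshold(self, rng):
        # variant 0: MAF 0.04 (below the 5% threshold); variant 1: MAF 0.3
        n = 100
        d0 = np.zeros(n); d0[:8] = 1.0
        d1 = rng.binomial(2, 0.3, size=n).astype(float)
        g = _gm(np.column_stack([d0, d1]))
        out = variant_qc(g, maf_min=0.05, missing_max=1.0, hwe_p_min=0.0)
        assert list(out.variants["id"]) == ["v1"]

    def test_hwe_violator_removed(self):
        d_bad = np.array([0.0] * 50 + [2.0] * 50)  # (50, 0, 50)
        d_ok = np.array([0.0] * 25 + [1.0] * 50 + [2.0] * 25)
        g = _gm(np.column_stack([d_bad, d_ok]))
        out = variant_qc(g, maf_min=0.0, missing_max=1.0, hwe_p_min=1e-3)
        assert list(out.variants["id"]) == ["v1"]

    def test_missingness_filter(self, rng):
        d = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        d[:20, 0] = np.nan  # 20% missing
        g = _gm(d)
        out = variant_qc(g, maf_min=0.0, missing_max=0.05, hwe_p_min=0.0)
        assert list(out.variants["id"]) == ["v1"]

    def test_idempotent(self, rng):
        d = rng.binomial(2, rng.uniform(0.02, 0.5, size=30), size=(200, 30)).astype(float)
        g = _gm(d)
        once = variant_qc(g)
        twice = variant_qc(once)
        pd.testing.assert_frame_equal(once.variants, twice.variants)
        np.testing.assert_array_equal(once.dosages, twice.dosages)

    def test_empty_result_warns(self):
        d = np.zeros((50, 1))
        g = _gm(d)
        with pytest.warns(UserWarning):
            out = variant_qc(g, maf_min=0.05)
        assert out.n_variants == 0


class TestFilterExpressed:
    def _em(self, tpm, counts):
        tpm = np.atleast_2d(tpm)
        counts = np.atleast_2d(counts)
        return ExpressionMatrix(
            feature_ids=np.array([f"f{i}" for i in range(tpm.shape[0])], dtype=object),
            sample_ids=np.array([f"s{i}" for i in range(tpm.shape[1])], dtype=object),
            values=tpm,
            counts=counts,
        )

    def test_passing_everywhere_retained(self):
        e = self._em(np.full((1, 10), 0.2), np.full((1, 10), 6))
        assert filter_expressed(e).n_features == 1

    def test_below_sample_fraction_removed(self):
        # passes in 19 of 100 samples with a 20% requirement
        tpm = np.full((1, 100), 0.01); tpm[0, :19] = 0.5
        cnt = np.full((1, 100), 100)
        e = self._em(tpm, cnt)
        assert filter_expressed(e, sample_frac=0.20).n_features == 0
        assert filter_expressed(e, sample_frac=0.19).n_features == 1

    def test_zero_iqr_removed_in_mirna_mode(self):
        tpm = np.full((1, 20), 5.0)  # constant => IQR 0
        cnt = np.full((1, 20), 50)
        e = self._em(tpm, cnt)
        assert filter_expressed(e, drop_zero_iqr=True).n_features == 0
        assert filter_expressed(e, drop_zero_iqr=False).n_features == 1

    def test_missing_counts_is_error(self):
        e = ExpressionMatrix(
            feature_ids=np.array(["f0"], dtype=object),
            sample_ids=np.array(["s0"], dtype=object),
            values=np.array([[1.0]]),
        )
        with pytest.raises(ValueError, match="count"):
            filter_expressed(e)


class TestNormalization:
    def test_int_blom_closed_form(self):
        n = 11
        x = np.arange(1, n + 1, dtype=float)
        out = inverse_normal_transform(x)[0]
        expected = stats.norm.ppf((np.arange(1, n + 1) - 3 / 8) / (n + 1 / 4))
        np.testing.assert_allclose(out, expected, atol=1e-12)
        np.testing.assert_allclose(out, -out[::-1], atol=1e-12)  # symmetric about 0

    def test_quantile_normalize_equalizes_distributions(self, rng):
        x = rng.gamma(2.0, size=(200, 5)) * np.array([1, 2, 5, 0.5, 10.0])
        qn = quantile_normalize(x)
        sorted_cols = np.sort(qn, axis=0)
        for j in range(1, 5):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-10)

    def test_output_mean_zero_and_normal_quantiles(self, rng):
        vals = rng.gamma(2.0, size=(30, 150))
        e = ExpressionMatrix(
            feature_ids=np.array([f"f{i}" for i in range(30)], dtype=object),
            sample_ids=np.array([f"s{i}" for i in range(150)], dtype=object),
            values=vals,
        )
        out = normalize_expression(e)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-8
        # post-transform rows are close to N(0,1): unit-ish variance and no
        # gross departure by a KS test (quantile-normalization ties make the
        # match approximate, not exact)
        v = out.values.var(axis=1)
        assert np.all((v > 0.7) & (v < 1.2))
        for i in range(0, 30, 7):
            assert stats.kstest(out.values[i], "norm").pvalue > 0.01

    def test_perfect_confound_removed(self, rng):
        cov = rng.standard_normal(80)
        vals = np.exp(np.vstack([cov, 2 * cov]))  # features are functions of the covariate
        e = ExpressionMatrix(
            feature_ids=np.array(["f0", "f1"], dtype=object),
            sample_ids=np.array([f"s{i}" for i in range(80)], dtype=object),
            values=vals,
        )
        out = normalize_expression(e, covariates=pd.DataFrame({"c": cov}))
        # the INT of a monotone transform of the covariate is (nearly) linear
        # in the covariate's own INT, so residuals collapse
        assert np.abs(out.values).max() < np.abs(inverse_normal_transform(vals[0])[0]).max() * 0.5

    def test_constant_feature_zeroed_with_warning(self):
        vals = np.vstack([np.full(50, 3.0), np.arange(50, dtype=float)])
        e = ExpressionMatrix(
            feature_ids=np.array(["f0", "f1"], dtype=object),
            sample_ids=np.array([f"s{i}" for i in range(50)], dtype=object),
            values=vals,
        )
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_expression(e)
        np.testing.assert_array_equal(out.values[0], 0.0)

    def test_already_normal_feature_preserved_in_rank(self, rng):
        x = rng.standard_normal((1, 300))
        e = ExpressionMatrix(
            feature_ids=np.array(["f0"], dtype=object),
            sample_ids=np.array([f"s{i}" for i in range(300)], dtype=object),
            values=np.exp(x),  # strictly positive, same ranks
        )
        out = normalize_expression(e)  # single feature: rank-INT only
        assert np.corrcoef(out.values[0], x[0])[0, 1] > 0.99


class TestHarmonize:
    def _a(self):
        return pd.DataFrame({"id": ["v1"], "a1": ["A"], "a2": ["G"], "beta": [0.2]})

    def test_swapped_alleles_flip_sign(self):
        b = pd.DataFrame({"id": ["v1"], "a1": ["G"], "a2": ["A"], "z": [3.0]})
        out = harmonize_alleles(self._a(), b)
        assert out["z"].iloc[0] == -3.0

    def test_matching_alleles_unchanged(self):
        b = pd.DataFrame({"id": ["v1"], "a1": ["A"], "a2": ["G"], "z": [3.0]})
        out = harmonize_alleles(self._a(), b)
        assert out["z"].iloc[0] == 3.0

    def test_ambiguous_pair_dropped(self):
        a = pd.DataFrame({"id": ["v1"], "a1": ["A"], "a2": ["T"], "beta": [0.2]})
        b = pd.DataFrame({"id": ["v1"], "a1": ["A"], "a2": ["T"], "z": [3.0]})
        with pytest.warns(UserWarning, match="dropped"):
            out = harmonize_alleles(a, b)
        assert len(out) == 0

    def test_allele_mismatch_dropped(self):
        b = pd.DataFrame({"id": ["v1"], "a1": ["A"], "a2": ["C"], "z": [3.0]})
        with pytest.warns(UserWarning, match="dropped"):
            out = harmonize_alleles(self._a(), b)
        assert len(out) == 0

    def test_disjoint_ids_empty_with_warning(self):
        b = pd.DataFrame({"id": ["v9"], "a1": ["A"], "a2": ["G"], "z": [1.0]})
        with pytest.warns(UserWarning, match="no shared"):
            out = harmonize_alleles(self._a(), b)
        assert len(out) == 0

    def test_duplicate_ids_error(self):
        b = pd.DataFrame({"id": ["v1", "v1"], "a1": ["A", "A"], "a2": ["G", "G"], "z": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            harmonize_alleles(self._a(), b)


class TestRoundTrips:
    def test_vcf_round_trip(self, tmp_path, rng):
        pytest.importorskip("cyvcf2")
        from omixtwas.data_io import read_vcf, write_vcf

        d = rng.binomial(2, 0.3, size=(10, 4)).astype(float)
        g = _gm(d)
        path = str(tmp_path / "g.vcf")
        write_vcf(g, path)
        back = read_vcf(path)
        np.testing.assert_allclose(back.dosages, g.dosages, atol=1e-5)
        assert list(back.variants["id"]) == list(g.variants["id"])
        assert list(back.variants["pos"]) == list(g.variants["pos"])

    def test_bed_round_trip(self, tmp_path):
        df = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [0, 100], "end": [50, 200],
                           "name": ["a", "b"]})
        path = str(tmp_path / "x.bed")
        write_bed(df, path)
        back = read_bed(path)
        pd.testing.assert_frame_equal(back, df)

    def test_expression_tsv_round_trip(self, tmp_path, rng):
        e = ExpressionMatrix(
            feature_ids=np.array(["f0", "f1"], dtype=object),
            sample_ids=np.array(["s0", "s1", "s2"], dtype=object),
            values=rng.standard_normal((2, 3)),
        )
        path = str(tmp_path / "e.tsv")
        write_expression_tsv(e, path)
        back = read_expression_tsv(path)
        np.testing.assert_allclose(back.values, e.values)
        assert list(back.sample_ids) == list(e.sample_ids)

    def test_gwas_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "variant_id": ["v1"], "chrom": ["chr1"], "pos": [100], "a1": ["A"], "a2": ["G"],
            "beta": [0.1], "se": [0.02], "z": [5.0], "n": [1000],
        })
        path = str(tmp_path / "g.tsv")
        write_gwas_tsv(df, path)
        back = read_gwas_tsv(path)
        pd.testing.assert_frame_equal(back, df)

    def test_gwas_tsv_missing_column_error(self, tmp_path):
        path = str(tmp_path / "bad.tsv")
        pd.DataFrame({"variant_id": ["v1"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing"):
            read_gwas_tsv(path)
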