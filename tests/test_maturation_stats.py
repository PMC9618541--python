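"""Lateralization, trends, contrasts, Wilcoxon, and the Mahalanobis
maturation distance with its invariances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from slf_maturation import maturation_stats as ms
from slf_maturation import synthetic_data as sd
from slf_maturation.errors import StatsError


def random_reference(rng, k=6, n=40, bundle="SLF_I"):
    A = rng.normal(size=(k, k))
    cov0 = A @ A.T + 0.5 * np.eye(k)
    mean0 = rng.normal(size=k)
    X = rng.multivariate_normal(mean0, cov0, size=n)
    cols = {f"{bundle}_{m}_LR": X[:, i] for i, m in enumerate(ms.METRICS)}
    return ms.build_adult_reference(pd.DataFrame(cols), bundle)


class TestElementary:
    def test_lateralization_examples(self):
        assert ms.lateralization_index(0.5, 0.5) == 0.0
        assert ms.lateralization_index(0.6, 0.4) == pytest.approx(0.2)
        for a, b in ((0.3, 0.7), (1.2, 0.8)):
            assert ms.lateralization_index(a, b) == pytest.approx(
                -ms.lateralization_index(b, a)
            )
        with pytest.raises(StatsError):
            ms.lateralization_index(0.5, -0.5)

    def test_one_sample_t(self):
        t, df, p = ms.one_sample_t([-1.0, 0.0, 1.0])
        assert t == 0.0 and df == 2 and p == pytest.approx(1.0)
        with pytest.raises(StatsError):
            ms.one_sample_t([2.0, 2.0, 2.0])

    def test_pearson_trend_matches_brute_force_identity(self, rng):
        """r computed from raw data by the covariance formula and t from the
        r -> t identity agree with pearson_trend to 1e-10."""
        for _ in range(10):
            n = int(rng.integers(10, 60))
            ages = rng.uniform(37, 44, n)
            values = 0.01 * ages + rng.normal(scale=0.02, size=n)
            res = ms.pearson_trend(values, ages)
            xc = values - values.mean()
            yc = ages - ages.mean()
            r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
            t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
            assert res.r == pytest.approx(r, abs=1e-10)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.df == n - 2
            assert np.sign(res.t) == np.sign(res.r)

    def test_perfect_linearity(self):
        ages = np.arange(10, dtype=float)
        res = ms.pearson_trend(2.0 * ages + 1.0, ages)
        assert res.r == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError):
            ms.pearson_trend(np.ones(10), np.arange(10.0))

    def test_group_contrast_examples(self):
        same = ms.group_contrast([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert same.t == pytest.approx(0.0) and same.d == pytest.approx(0.0)
        res = ms.group_contrast([0.0, 1.0], [1.0, 2.0])
        assert res.d == pytest.approx(-1.4142, abs=1e-4)
        assert res.df == 2
        # means exactly one pooled SD apart -> d = 1
        a = np.array([0.0, 2.0])
        b = a + np.sqrt(2.0)
        assert ms.group_contrast(b, a).d == pytest.approx(1.0)
        with pytest.raises(StatsError):
            ms.group_contrast([1.0, 1.0], [1.0, 1.0])

    def test_contrast_df_is_78_for_forty_vs_forty(self, rng):
        res = ms.group_contrast(rng.normal(size=40), rng.normal(size=40))
        assert res.df == 78

    def test_bonferroni_adjustment_caps_at_one(self, rng):
        res = ms.group_contrast(rng.normal(size=10), rng.normal(size=10), n_tests=6)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p * 6))


class TestWilcoxon:
    def test_matches_exhaustive_enumeration(self, rng):
        """Exact two-sided p equals full 2^n sign-flip enumeration for
        tie-free samples with n <= 10."""
        for n in (6, 8, 10):
            for _ in range(5):
                d = rng.normal(size=n)
                w, p = ms.wilcoxon_signed_rank(d)
                ranks = sps.rankdata(np.abs(d))
                wplus = ranks[d > 0].sum()
                dist = np.array(
                    [
                        sum(r for r, keep in zip(ranks, signs) if keep)
                        for signs in itertools.product((0, 1), repeat=n)
                    ]
                )
                p_enum = min(
                    1.0, 2 * min((dist <= wplus).mean(), (dist >= wplus).mean())
                )
                assert p == pytest.approx(p_enum, abs=1e-12)

    def test_handles_zeros_and_ties(self):
        d = np.array([0.0, 1.0, 1.0, -1.0, 2.0, 3.0, 3.0, -2.0])
        w, p = ms.wilcoxon_signed_rank(d)
        assert 0.0 <= p <= 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            ms.wilcoxon_signed_rank(np.zeros(8))
        with pytest.raises(StatsError):
            ms.wilcoxon_signed_rank(np.array([1.0, 2.0]))


class TestAdultReference:
    def test_identical_adults_refused(self):
        table = pd.DataFrame(
            {f"SLF_I_{m}_LR": np.ones(10) * i for i, m in enumerate(ms.METRICS)}
        )
        with pytest.raises(StatsError):
            ms.build_adult_reference(table, "SLF_I")

    def test_eigen_reconstruction(self, rng):
        ref = random_reference(rng)
        recon = ref.eigenvectors.T @ np.diag(ref.eigenvalues) @ ref.eigenvectors
        np.testing.assert_allclose(recon, ref.cov, atol=1e-10)

    def test_too_few_adults_refused(self, rng):
        cols = {
            f"SLF_I_{m}_LR": rng.normal(size=7) for m in ms.METRICS
        }
        with pytest.raises(StatsError):
            ms.build_adult_reference(pd.DataFrame(cols), "SLF_I")

    def test_collinear_metrics_refused_with_diagnostic(self, rng):
        base = rng.normal(size=40)
        cols = {f"SLF_I_{m}_LR": rng.normal(size=40) for m in ms.METRICS}
        cols["SLF_I_MD_LR"] = base
        cols["SLF_I_RD_LR"] = 2.0 * base  # exact collinearity
        with pytest.raises(StatsError, match="MD and RD"):
            ms.build_adult_reference(pd.DataFrame(cols), "SLF_I")

    def test_sample_covariance_recovers_truth(self, rng):
        """Entries of the n=200 sample covariance lie within 3 standard
        errors of the generating covariance."""
        k = 6
        A = rng.normal(size=(k, k))
        cov0 = A @ A.T + np.eye(k)
        X = rng.multivariate_normal(np.zeros(k), cov0, size=200)
        cols = {f"SLF_I_{m}_LR": X[:, i] for i, m in enumerate(ms.METRICS)}
        ref = ms.build_adult_reference(pd.DataFrame(cols), "SLF_I")
        n = 200
        for i in range(k):
            for j in range(k):
                se = np.sqrt((cov0[i, i] * cov0[j, j] + cov0[i, j] ** 2) / n)
                assert abs(ref.cov[i, j] - cov0[i, j]) < 3 * se


class TestMahalanobis:
    def test_zero_at_the_mean(self, rng):
        ref = random_reference(rng)
        res = ms.mahalanobis_distance(ref.mean, ref)
        assert res.m == pytest.approx(0.0, abs=1e-8)

    def test_one_dimensional_reduction(self):
        """x = 2, mu = 0, sigma^2 = 4 -> M = |x - mu| / sigma = 1, realised
        here as an isotropic 6-D reference with variance 4 per axis."""
        rng = np.random.default_rng(1)
        X = rng.multivariate_normal(np.zeros(6), 4 * np.eye(6), size=4000)
        cols = {f"SLF_I_{m}_LR": X[:, i] for i, m in enumerate(ms.METRICS)}
        ref = ms.build_adult_reference(pd.DataFrame(cols), "SLF_I")
        x = ref.mean.copy()
        x[0] += 2.0 * np.sqrt(ref.cov[0, 0] / 4.0)
        # displacement of 2 along a direction with SD ~2 -> M ~ 1
        assert ms.mahalanobis_distance(x, ref).m == pytest.approx(1.0, abs=0.15)

    def test_euclidean_case(self):
        ref = ms.AdultReference(
            bundle="b", metrics=ms.METRICS, mean=np.zeros(6), cov=np.eye(6),
            eigenvalues=np.ones(6), eigenvectors=np.eye(6), n_adults=40,
            condition_number=1.0,
        )
        x = np.array([3.0, 4.0, 0.0, 0.0, 0.0, 0.0])
        res = ms.mahalanobis_distance(x, ref)
        assert res.m == pytest.approx(5.0)
        assert res.m_direct == pytest.approx(5.0)

    def test_eigen_and_direct_forms_agree(self, rng):
        for _ in range(50):
            ref = random_reference(rng)
            x = ref.mean + rng.normal(size=6)
            res = ms.mahalanobis_distance(x, ref)
            assert res.m == pytest.approx(res.m_direct, rel=1e-8)

    def test_scale_and_affine_invariance(self, rng):
        """Rescaling any metric (or any invertible linear remap) applied to
        both the data and the reference leaves M unchanged."""
        A = rng.normal(size=(6, 6))
        cov0 = A @ A.T + 0.5 * np.eye(6)
        X = rng.multivariate_normal(rng.normal(size=6), cov0, size=60)
        x = X[0] + rng.normal(size=6)

        def build(mat):
            cols = {
                f"SLF_I_{m}_LR": (X @ mat.T)[:, i]
                for i, m in enumerate(ms.METRICS)
            }
            return ms.build_adult_reference(pd.DataFrame(cols), "SLF_I")

        base = ms.mahalanobis_distance(x, build(np.eye(6))).m
        scale = np.diag([1e3, 1.0, 1.0, 1e-4, 1.0, 10.0])
        assert ms.mahalanobis_distance(scale @ x, build(scale)).m == pytest.approx(
            base, rel=1e-8
        )
        remap = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        assert ms.mahalanobis_distance(remap @ x, build(remap)).m == pytest.approx(
            base, rel=1e-8
        )

    def test_monotone_in_whitened_displacement(self, rng):
        ref = random_reference(rng)
        delta = rng.normal(size=6)
        m1 = ms.mahalanobis_distance(ref.mean + delta, ref).m
        for c in (0.0, 0.5, 2.0, 7.0):
            mc = ms.mahalanobis_distance(ref.mean + c * delta, ref).m
            assert mc == pytest.approx(c * m1, rel=1e-8, abs=1e-10)


class TestMaturationAnalysis:
    def test_neonates_at_adult_means_have_zero_distance(self, rng):
        _, adult = sd.simulate_cohort_tables(seed=3)
        refs = {b: ms.build_adult_reference(adult, b) for b in ms.BUNDLES}
        ref_rows = []
        for i in range(10):
            row = {"subject_id": f"n{i}", "group": "neonate", "age": 38.0 + i / 10}
            for b in ms.BUNDLES:
                for m, value in zip(ms.METRICS, refs[b].mean):
                    row[f"{b}_{m}_LR"] = value
            ref_rows.append(row)
        neo = pd.DataFrame(ref_rows)
        report = ms.maturation_analysis(neo, adult)
        for b in ms.BUNDLES:
            np.testing.assert_allclose(report.distances[b], 0.0, atol=1e-8)
        assert all(not v["significant"] for v in report.wilcoxon.values())

    def test_least_mature_branch_identified(self):
        neo, adult = sd.simulate_cohort_tables(seed=11)
        report = ms.maturation_analysis(neo, adult)
        assert report.ranking[0] == "SLF_II"
        assert report.wilcoxon[("SLF_I", "SLF_II")]["significant"]
        assert report.wilcoxon[("SLF_II", "SLF_III")]["significant"]

    def test_distances_shrink_with_age(self):
        """The generator drives neonates toward adult values with age, so M
        correlates negatively with PMA in every branch."""
        neo, adult = sd.simulate_cohort_tables(seed=12)
        report = ms.maturation_analysis(neo, adult)
        for b in ms.BUNDLES:
            assert report.spearman[b]["rho"] < 0

    def test_too_few_neonates_refused(self):
        neo, adult = sd.simulate_cohort_tables(seed=1)
        with pytest.raises(StatsError):
            ms.maturation_analysis(neo.head(4), adult)


class TestReports:
    def test_lateralization_report_is_unbiased_here(self):
        """The generator lateralizes nothing, so LI t-tests should almost
        never all reject; check layout and that mean LI is tiny."""
        neo, _ = sd.simulate_cohort_tables(seed=8)
        rep = ms.lateralization_report(neo)
        assert len(rep) == 18
        assert np.abs(rep["mean_li"]).max() < 0.02

    def test_trend_report_directions(self):
        neo, _ = sd.simulate_cohort_tables(seed=4)
        rep = ms.trend_report(neo).set_index(["metric", "bundle"])
        for b in ms.BUNDLES:
            assert rep.loc[("NDI", b), "r"] > 0
            assert rep.loc[("FA", b), "r"] > 0
            assert rep.loc[("MD", b), "r"] < 0
            assert rep.loc[("RD", b), "r"] < 0
            assert rep.loc[("NDI", b), "significant"]
            assert not rep.loc[("ODI", b), "significant"]

    def test_contrast_report_offsets(self):
        neo, adult = sd.simulate_cohort_tables(seed=6)
        rep = ms.contrast_report(neo, adult).set_index(["metric", "bundle"])
        for b in ms.BUNDLES:
            assert rep.loc[("NDI", b), "d"] > 0  # adults higher
            assert rep.loc[("MD", b), "d"] < 0  # adults lower
            assert rep.loc[("NDI", b), "p_adjusted"] < 1e-4
            # ODI barely differs between the groups
            assert rep.loc[("ODI", b), "abs_d"] < rep.loc[("NDI", b), "abs_d"]
        assert (rep["df"] == 78).all()
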