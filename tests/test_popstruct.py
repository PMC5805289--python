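"""Weir-Cockerham FST, differentiation bins, percentile ranks and PCA."""

import numpy as np
import pytest

from conftest import make_matrix
from cvload.popstruct import (
    FstSummary,
    classify_differentiation,
    fst_enrichment,
    fst_from_counts,
    fst_summary,
    pca,
    percentile_rank,
    wc_fst_site,
    wc_fst_sites,
)
from cvload.variant_store import MISSING, PopulationPanel, allele_counts


def oracle_components(n, p, h):
    """Straight-line transcription of the estimator's component formulas,
    kept deliberately independent of the vectorized implementation."""
    r = len(n)
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


class TestWcFstSite:
    def test_fixed_difference_gives_theta_one(self):
        res = wc_fst_site([20, 20], [0.0, 1.0], [0.0, 0.0])
        assert res.theta == pytest.approx(1.0)
        assert res.b == pytest.approx(0.0) and res.c == 0.0

    def test_monomorphic_site_theta_undefined(self):
        res = wc_fst_site([20, 20], [0.0, 0.0], [0.0, 0.0])
        assert res.theta is None
        assert (res.a, res.b, res.c) == (0.0, 0.0, 0.0)

    def test_agrees_with_arithmetic_oracle(self):
        n, p = [10, 10], [0.3, 0.7]
        h = [2 * x * (1 - x) for x in p]  # Hardy-Weinberg heterozygosity
        res = wc_fst_site(n, p, h)
        a, b, c = oracle_components(n, p, h)
        assert res.a == pytest.approx(a)
        assert res.b == pytest.approx(b)
        assert res.c == pytest.approx(c)
        assert res.theta == pytest.approx(a / (a + b + c))

    def test_agrees_with_oracle_on_random_sites(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            r = rng.integers(2, 5)
            n = rng.integers(2, 80, size=r).astype(float)
            p = rng.uniform(0, 1, size=r)
            h = np.minimum(rng.uniform(0, 1, size=r), 2 * p * (1 - p) + 1e-12)
            res = wc_fst_site(n, p, h)
            a, b, c = oracle_components(list(n), list(p), list(h))
            assert res.a == pytest.approx(a, abs=1e-12)
            assert res.b == pytest.approx(b, abs=1e-12)
            assert res.c == pytest.approx(c, abs=1e-12)

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = [30, 40]
            p = list(rng.uniform(0.05, 0.95, 2))
            h = [2 * x * (1 - x) for x in p]
            t1 = wc_fst_site(n, p, h).theta
            t2 = wc_fst_site(n, [1 - x for x in p], h).theta
            assert t1 == pytest.approx(t2)

    def test_negative_theta_not_clamped(self):
        # nearly identical frequencies with high heterozygosity drive a < 0
        res = wc_fst_site([50, 50], [0.5, 0.5], [0.5, 0.5])
        assert res.theta is not None and res.theta < 0

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            wc_fst_site([10], [0.5], [0.5])

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            wc_fst_site([1, 50], [0.5, 0.5], [0.5, 0.5])

    def test_vectorized_sites_skip_tiny_populations(self):
        df = wc_fst_sites(
            np.array([[1.0, 50.0], [30.0, 50.0]]),
            np.array([[0.5, 0.5], [0.1, 0.9]]),
            np.zeros((2, 2)),
        )
        assert df.skip_reason.tolist() == ["n_i<2", ""]
        assert np.isnan(df.theta[0]) and df.theta[1] > 0


class TestFstSummary:
    def test_single_site(self):
        res = wc_fst_site([10, 10], [0.2, 0.8], [0.2, 0.2])
        s = fst_summary([res])
        assert s.mean_theta == pytest.approx(res.theta)
        assert s.n_sites_used == 1

    def test_undefined_sites_excluded(self):
        sites = [
            wc_fst_site([10, 10], [0.2, 0.8], [0.2, 0.2]),
            wc_fst_site([10, 10], [0.0, 0.0], [0.0, 0.0]),
        ]
        assert fst_summary(sites).n_sites_used == 1

    def test_mean_matches_brute_force_average(self):
        rng = np.random.default_rng(3)
        sites = [
            wc_fst_site([20, 20], list(rng.uniform(0.05, 0.95, 2)), [0.3, 0.3])
            for _ in range(100)
        ]
        s = fst_summary(sites)
        thetas = [x.theta for x in sites if x.theta is not None]
        assert s.mean_theta == pytest.approx(np.mean(thetas))
        num = sum(x.a for x in sites if x.theta is not None)
        den = sum(x.a + x.b + x.c for x in sites if x.theta is not None)
        assert s.weighted_theta == pytest.approx(num / den)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fst_summary([])


class TestEnrichment:
    def test_printed_ratio(self):
        d = FstSummary(mean_theta=0.00638, weighted_theta=0.006, n_sites_used=100)
        b = FstSummary(mean_theta=0.00134, weighted_theta=0.001, n_sites_used=1000)
        assert fst_enrichment(d, b) == pytest.approx(4.76, abs=0.005)

    def test_equal_means_give_unity(self):
        s = FstSummary(0.01, 0.01, 5)
        assert fst_enrichment(s, s) == pytest.approx(1.0)

    def test_zero_background_undefined(self):
        assert fst_enrichment(FstSummary(0.1, 0.1, 5), FstSummary(0.0, 0.0, 5)) is None

    def test_planted_enrichment_recovered(self):
        """Sites drifted at high F vs low-F background: ratio ~ planted."""
        rng = np.random.default_rng(21)

        def simulate(F, m, n=50):
            p_anc = rng.uniform(0.05, 0.95, m)
            out = []
            for p in p_anc:
                ps = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F, size=2)
                geno = rng.binomial(2, ps[:, None], size=(2, n))
                p_obs = geno.sum(axis=1) / (2 * n)
                h_obs = (geno == 1).sum(axis=1) / n
                out.append(wc_fst_site([n, n], list(p_obs), list(h_obs)))
            return fst_summary(out)

        bg = simulate(0.02, 3000)
        fg = simulate(0.10, 3000)
        # the ratio-of-sums estimator recovers the planted drift, so its
        # ratio tracks 0.10/0.02; the mean-theta enrichment is shrunk
        # differently at each F but must still show enrichment
        assert fg.weighted_theta / bg.weighted_theta == pytest.approx(5.0, rel=0.2)
        assert fst_enrichment(fg, bg) > 1.0


class TestDifferentiationBins:
    @pytest.mark.parametrize(
        "theta,label",
        [
            (0.16597, "high"),   # the printed worked example
            (0.049, "less"),
            (0.05, "moderate"),  # left-closed boundary
            (0.1499, "moderate"),
            (0.15, "high"),
            (0.25, "severe"),
            (-0.02, "less"),
            (None, "undefined"),
            (float("nan"), "undefined"),
        ],
    )
    def test_boundaries(self, theta, label):
        assert classify_differentiation(theta) == label

    def test_partition_sums_to_defined_sites(self):
        rng = np.random.default_rng(9)
        thetas = rng.uniform(-0.1, 0.5, 500)
        labels = [classify_differentiation(t) for t in thetas]
        assert len(labels) == 500 and "undefined" not in labels


class TestPercentileRank:
    def test_maximum_is_top_zero(self):
        bg = [0.1, 0.2, 0.3]
        assert percentile_rank(0.3, bg) == 0.0

    def test_median_is_top_fifty_at_odd_sizes(self):
        bg = list(np.linspace(0, 1, 101))
        assert percentile_rank(np.median(bg), bg) == pytest.approx(100 * 50 / 101)

    def test_matches_sort_and_count_oracle(self):
        rng = np.random.default_rng(14)
        bg = rng.normal(size=333)
        for q in rng.choice(bg, 10):
            expected = 100.0 * np.sum(np.sort(bg) > q) / bg.size
            assert percentile_rank(q, bg) == pytest.approx(expected)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank(0.1, [])


class TestPca:
    def test_two_populations_with_fixed_differences_separate_on_pc1(self):
        n_sites, n_per = 40, 10
        d = np.zeros((n_sites, 2 * n_per), dtype=np.int8)
        d[: n_sites // 2, :n_per] = 2  # pop A fixed alt on half the sites
        d[n_sites // 2 :, n_per:] = 2  # pop B fixed alt on the other half
        # a little noise so no site is monomorphic cohort-wide
        m = make_matrix([("1", i + 1, "A", "G") for i in range(n_sites)], d)
        res = pca(m, k=2)
        pc1 = res.coords[:, 0]
        assert np.ptp(np.sign(pc1[:n_per])) == 0 and np.ptp(np.sign(pc1[n_per:])) == 0
        assert np.sign(pc1[0]) != np.sign(pc1[-1])
        between = abs(pc1[:n_per].mean() - pc1[n_per:].mean())
        within = pc1[:n_per].std() + pc1[n_per:].std()
        assert within < 1e-8 * max(between, 1)

    def test_identical_samples_rejected(self):
        m = make_matrix([("1", i + 1, "A", "G") for i in range(5)], np.ones((5, 4)))
        with pytest.raises(ValueError):
            pca(m, k=2)

    def test_eigenvalues_match_dense_covariance_oracle(self):
        """Balding-Nichols cohort vs explicit covariance eigendecomposition."""
        rng = np.random.default_rng(30)
        F, n_per, m_sites = 0.2, 20, 300
        p_anc = rng.uniform(0.05, 0.95, m_sites)
        ps = np.column_stack(
            [rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F) for _ in range(2)]
        )
        d = np.concatenate(
            [rng.binomial(2, ps[:, j][:, None], size=(m_sites, n_per)) for j in range(2)],
            axis=1,
        ).astype(np.int8)
        mat = make_matrix([("1", i + 1, "A", "G") for i in range(m_sites)], d)
        res = pca(mat, k=10)

        # oracle: explicitly form the normalized matrix and its covariance
        X = d.T.astype(float)
        mean = X.mean(axis=0)
        phat = mean / 2
        keep = (phat > 0) & (phat < 1)
        X = (X[:, keep] - mean[keep]) / np.sqrt(phat[keep] * (1 - phat[keep]))
        C = X @ X.T / X.shape[1]
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(res.eigenvalues, evals[:10], atol=1e-8)
        # trace identity: total variance equals the eigenvalue sum
        assert np.trace(C) == pytest.approx(np.sort(np.linalg.eigvalsh(C)).sum())

    def test_eigenvalues_nonnegative_and_sorted(self, cohort):
        res = pca(cohort["matrix"], k=5)
        assert (res.eigenvalues >= -1e-10).all()
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        # orthonormal coordinates
        gram = res.coords.T @ res.coords
        assert np.allclose(gram, np.eye(res.coords.shape[1]), atol=1e-8)

    def test_k_truncated_to_rank(self):
        d = np.array([[0, 1, 2, 1], [2, 1, 0, 1], [1, 1, 1, 0]], dtype=np.int8)
        m = make_matrix([("1", i + 1, "A", "G") for i in range(3)], d)
        res = pca(m, k=10)
        assert res.coords.shape[1] <= 4

    def test_missing_dosages_mean_imputed(self):
        d = np.array([[0, 2, MISSING, 2], [1, 0, 1, MISSING]], dtype=np.int8)
        m = make_matrix([("1", 1, "A", "G"), ("1", 2, "A", "G")], d)
        res = pca(m, k=1)  # runs without error; imputation keeps both sites
        assert len(res.sites_used) == 2


class TestFstFromCounts:
    def test_counts_path_matches_direct_formula(self):
        panel = PopulationPanel.from_mapping(
            {f"A{i}": "A" for i in range(10)} | {f"B{i}": "B" for i in range(10)},
            ["A", "B"],
        )
        rng = np.random.default_rng(17)
        d = rng.choice([0, 1, 2], size=(30, 20)).astype(np.int8)
        m = make_matrix(
            [("1", i + 1, "A", "G") for i in range(30)], d,
            samples=[f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)],
        )
        counts = allele_counts(m, panel)
        df = fst_from_counts(counts)
        for vi in range(30):
            n, p, h = [], [], []
            for cols in (range(10), range(10, 20)):
                vals = d[vi, list(cols)]
                n.append(len(vals))
                p.append(vals.sum() / (2 * len(vals)))
                h.append((vals == 1).sum() / len(vals))
            a, b, c = oracle_components(n, p, h)
            assert df.a[vi] == pytest.approx(a, abs=1e-12)
            denom = a + b + c
            if denom:
                assert df.theta[vi] == pytest.approx(a / denom)

    def test_hwe_imputation_flagged(self, cohort):
        df = fst_from_counts(cohort["counts"], hwe_het=True)
        assert df.hwe_imputed_het.all()
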