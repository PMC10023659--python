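import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from sigconfound.io import CountMatrix
from sigconfound.preprocess import (
    detect_outliers,
    filter_genes,
    log_cpm,
    pca_scores,
    tmm_factors,
    voom_weights,
)


def nb_matrix(n_genes, n_samples, seed=0, mean_scale=50.0):
    rng = np.random.default_rng(seed)
    mu = rng.gamma(2.0, mean_scale, n_genes)
    lam = rng.gamma(5.0, mu[:, None] / 5.0, (n_genes, n_samples))
    counts = rng.poisson(lam)
    return CountMatrix([f"g{i}" for i in range(n_genes)],
                       [f"s{j}" for j in range(n_samples)], counts)


class TestFilterGenes:
    def test_all_zero_gene_removed(self, rng):
        counts = rng.poisson(30, (5, 4))
        counts[2] = 0
        cm = CountMatrix([f"g{i}" for i in range(5)], [f"s{j}" for j in range(4)], counts)
        kept = filter_genes(cm, min_fraction=0.5)
        assert "g2" not in kept.gene_ids

    def test_cpm_arithmetic_boundary(self):
        # libraries of 1e6: counts (2, 0) give CPM 2 > 1 in exactly 1 of 2 samples
        counts = np.zeros((3, 2), dtype=int)
        counts[0] = [2, 0]
        counts[1] = [999996, 999998]
        counts[2] = [2, 2]
        cm = CountMatrix(["g0", "gfill", "g2"], ["s1", "s2"], counts)
        assert cm.library_sizes.tolist() == [10**6, 10**6]
        kept = filter_genes(cm, min_fraction=0.5)
        assert "g0" in kept.gene_ids

    def test_matches_brute_force_oracle(self):
        cm = nb_matrix(500, 20, seed=7)
        kept = set(filter_genes(cm, min_fraction=0.5).gene_ids)
        lib = cm.counts.sum(axis=0)
        oracle = set()
        required = int(np.ceil(0.5 * 20))
        for i, gene in enumerate(cm.gene_ids):
            n_pass = sum(cm.counts[i, j] / lib[j] * 1e6 > 1.0 for j in range(20))
            if n_pass >= required:
                oracle.add(gene)
        assert kept == oracle

    def test_idempotent(self):
        cm = nb_matrix(200, 10, seed=3)
        once = filter_genes(cm, min_fraction=0.5)
        twice = filter_genes(once, min_fraction=0.5)
        assert once.gene_ids == twice.gene_ids

    def test_all_filtered_is_error(self):
        cm = CountMatrix(["g1", "g2"], ["s1", "s2"], np.array([[1, 1], [2, 1]]))
        with pytest.raises(ValueError, match="threshold"):
            filter_genes(cm, cpm_threshold=1e9, min_fraction=0.5)


def tmm_oracle(counts, lib, ref, trim_m=0.3, trim_a=0.05):
    """Step-by-step trimmed-mean-of-M-values, written independently:
    sorts instead of ranks, explicit loops."""
    factors = []
    for s in range(counts.shape[1]):
        ys, yr = counts[:, s].astype(float), counts[:, ref].astype(float)
        ns, nr = lib[s], lib[ref]
        keep = (ys > 0) & (yr > 0)
        m_vals, a_vals, w_vals = [], [], []
        for g in np.where(keep)[0]:
            m_vals.append(np.log2((ys[g] / ns) / (yr[g] / nr)))
            a_vals.append(0.5 * np.log2((ys[g] / ns) * (yr[g] / nr)))
            w_vals.append((ns - ys[g]) / (ns * ys[g]) + (nr - yr[g]) / (nr * yr[g]))
        m_vals, a_vals, w_vals = map(np.array, (m_vals, a_vals, w_vals))
        n = len(m_vals)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm, ra = rankdata(m_vals), rankdata(a_vals)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors.append(2 ** (np.sum(m_vals[sel] / w_vals[sel]) / np.sum(1 / w_vals[sel])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 51)
        cm = CountMatrix([f"g{i}" for i in range(50)], ["s1", "s2"],
                         np.column_stack([col, col]))
        np.testing.assert_allclose(tmm_factors(cm), [1.0, 1.0], atol=1e-12)

    def test_scaled_column_gives_unit_factors(self):
        col = np.arange(1, 51)
        cm = CountMatrix([f"g{i}" for i in range(50)], ["s1", "s2"],
                         np.column_stack([col, 3 * col]))
        np.testing.assert_allclose(tmm_factors(cm), [1.0, 1.0], atol=1e-12)

    def test_matches_independent_oracle(self):
        cm = nb_matrix(200, 4, seed=11)
        lib = cm.counts.sum(axis=0)
        f75 = np.array([np.quantile(cm.counts[:, j] / lib[j], 0.75) for j in range(4)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        np.testing.assert_allclose(tmm_factors(cm), tmm_oracle(cm.counts, lib, ref),
                                   atol=1e-10)

    def test_invariant_to_gene_order(self):
        cm = nb_matrix(150, 4, seed=5)
        perm = np.random.default_rng(0).permutation(150)
        shuffled = CountMatrix([cm.gene_ids[i] for i in perm], cm.sample_ids,
                               cm.counts[perm])
        np.testing.assert_allclose(tmm_factors(cm), tmm_factors(shuffled), atol=1e-12)

    def test_no_shared_nonzero_genes_is_error(self):
        counts = np.array([[5, 0, 5], [7, 0, 6], [0, 3, 9], [0, 4, 2]])
        cm = CountMatrix(["g1", "g2", "g3", "g4"], ["a", "b", "c"], counts)
        with pytest.raises(ValueError, match="nonzero"):
            tmm_factors(cm, ref_sample="a")


class TestLogCPM:
    def test_forced_arithmetic(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[1] = [10**6, 10**6]
        cm = CountMatrix(["gz", "gbig"], ["s1", "s2"], counts)
        norm = log_cpm(cm, factors=np.array([1.0, 1.0]), prior_count=0.5)
        expected = np.log2(0.5 / (1e6 + 1) * 1e6)  # approx -1.0000014
        assert norm.logcpm.loc["gz", "s1"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-1.0000014, abs=1e-6)

    def test_depth_scale_property(self):
        # doubling counts and depth shifts logCPM only via the pseudocount;
        # the residual effect is 0.5/((2c+1) ln 2), i.e. < 1e-3 once c >= 500
        cm = nb_matrix(100, 3, seed=2, mean_scale=2000.0)
        doubled = CountMatrix(cm.gene_ids, cm.sample_ids, cm.counts * 2)
        ones = np.ones(3)
        a = log_cpm(cm, ones).logcpm.to_numpy()
        b = log_cpm(doubled, ones).logcpm.to_numpy()
        high = cm.counts >= 500
        assert high.sum() > 50
        assert np.max(np.abs(a[high] - b[high])) < 1e-3

    def test_matches_hand_computed_table(self):
        counts = np.array([[4, 10], [6, 0]])
        cm = CountMatrix(["g1", "g2"], ["s1", "s2"], counts)
        factors = np.array([1.0, 1.0])
        lib = np.array([10.0, 10.0])
        hand = np.log2((counts + 0.5) / (lib + 1.0)[None, :] * 1e6)
        np.testing.assert_allclose(log_cpm(cm, factors).logcpm.to_numpy(), hand,
                                   atol=1e-12)


class TestPCA:
    def test_single_gene_difference_gives_full_pc1(self):
        expr = pd.DataFrame([[0.0, 5.0], [1.0, 1.0], [2.0, 2.0]],
                            index=["g1", "g2", "g3"], columns=["s1", "s2"])
        res = pca_scores(expr, n_components=1)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_explained_variance_is_proper_fraction(self):
        cm = nb_matrix(100, 12, seed=9)
        res = pca_scores(log_cpm(cm, np.ones(12)).logcpm, n_components=5)
        ev = res.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert 0 < ev.sum() <= 1 + 1e-12

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(100, 30))  # genes x samples
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(100)],
                            columns=[f"s{j}" for j in range(30)])
        res = pca_scores(expr, n_components=5)
        xc = x.T - x.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        oracle_scores = xc @ evecs[:, :5]
        for j in range(5):
            got = res.scores.to_numpy()[:, j]
            want = oracle_scores[:, j]
            agree = min(np.max(np.abs(got - want)), np.max(np.abs(got + want)))
            assert agree < 1e-8
        np.testing.assert_allclose(
            res.explained_variance, evals[:5] / np.sum(xc ** 2), atol=1e-10)

    def test_constant_matrix_is_error(self):
        expr = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValueError, match="constant"):
            pca_scores(expr)


class TestOutliers:
    def test_homogeneous_gaussian_scores_unflagged(self, rng):
        expr = pd.DataFrame(rng.normal(size=(80, 50)))
        res = pca_scores(expr, n_components=20)
        assert detect_outliers(res, sd_threshold=5) == []

    @staticmethod
    def _two_factor_data(rng, displace, n=200):
        """Genes x samples with two latent factors of unequal strength
        (anchoring PC1 and PC2); sample s0 sits `displace` SDs out on one or
        both factors.  Unequal strengths keep the component axes pinned by
        the bulk of the samples rather than by the displaced one."""
        f1 = rng.normal(size=n)
        f2 = rng.normal(size=n)
        f1[0] = displace[0]
        f2[0] = displace[1]
        load1 = np.zeros(100); load1[:50] = 6.0
        load2 = np.zeros(100); load2[50:] = 3.0
        x = np.outer(load1, f1) + np.outer(load2, f2) + rng.normal(0, 0.3, (100, n))
        return pd.DataFrame(x, columns=[f"s{j}" for j in range(n)])

    def test_two_pc_displacement_flagged(self, rng):
        expr = self._two_factor_data(rng, (10.0, 10.0))
        res = pca_scores(expr, n_components=20)
        assert "s0" in detect_outliers(res, sd_threshold=5, min_pcs=2)

    def test_single_pc_displacement_not_flagged(self, rng):
        expr = self._two_factor_data(rng, (10.0, 0.0))
        res = pca_scores(expr, n_components=20)
        assert "s0" not in detect_outliers(res, sd_threshold=5, min_pcs=2)

    def test_infinite_threshold_flags_nothing(self, rng):
        expr = pd.DataFrame(rng.normal(size=(60, 30)))
        res = pca_scores(expr, n_components=10)
        assert detect_outliers(res, sd_threshold=np.inf) == []


class TestVoomWeights:
    def test_flat_mean_variance_gives_constant_weights(self, rng):
        # all genes same mean and dispersion -> trend flat -> weights ~constant
        counts = rng.poisson(200, (200, 20))
        cm = CountMatrix([f"g{i}" for i in range(200)], [f"s{j}" for j in range(20)],
                         counts)
        design = np.ones((20, 1))
        w = voom_weights(cm, np.ones(20), design).to_numpy()
        assert w.std() / w.mean() < 0.05

    def test_weights_increase_with_expression(self):
        cm = nb_matrix(400, 16, seed=21)
        design = np.ones((16, 1))
        w = voom_weights(cm, np.ones(16), design)
        mean_count = cm.counts.mean(axis=1)
        lo = w.to_numpy()[mean_count < np.quantile(mean_count, 0.2)].mean()
        hi = w.to_numpy()[mean_count > np.quantile(mean_count, 0.8)].mean()
        assert hi > lo

    def test_weights_positive_finite(self):
        cm = nb_matrix(100, 10, seed=1)
        w = voom_weights(cm, np.ones(10), np.ones((10, 1))).to_numpy()
        assert np.all(w > 0) and np.all(np.isfinite(w))

    def test_too_few_genes_rejected(self):
        cm = nb_matrix(5, 10, seed=1)
        with pytest.raises(ValueError):
            voom_weights(cm, np.ones(10), np.ones((10, 1)))
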