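import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigconfound.consensus import (
    classify_convergence,
    consensus_tom,
    detect_modules,
    eigengene_association,
    module_eigengenes,
    signed_adjacency,
    topological_overlap,
)
from sigconfound.io import SampleTable
from conftest import make_metadata


def expr_frame(x, prefix="g"):
    return pd.DataFrame(x, index=[f"{prefix}{i}" for i in range(x.shape[0])],
                        columns=[f"s{j}" for j in range(x.shape[1])])


def modular_expression(rng, n_modules=5, module_size=50, n_background=100,
                       n_samples=60, noise=0.3, factors=None):
    """Block-structured expression: module genes load on a shared factor."""
    blocks = []
    labels = []
    for m in range(n_modules):
        f = factors[m] if factors is not None else rng.normal(size=n_samples)
        loads = rng.uniform(0.7, 1.3, module_size)
        signs = np.ones(module_size)
        blocks.append(np.outer(loads * signs, f) + rng.normal(0, noise, (module_size, n_samples)))
        labels += [m + 1] * module_size
    blocks.append(rng.normal(size=(n_background, n_samples)))
    labels += [0] * n_background
    return expr_frame(np.vstack(blocks)), np.array(labels)


class TestSignedAdjacency:
    def test_forced_values(self):
        x = np.array([[1.0, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])  # r=+1, r=-1
        net = signed_adjacency(expr_frame(x), beta_power=12)
        assert net.adjacency[0, 1] == pytest.approx(1.0)
        assert net.adjacency[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_value(self, rng):
        # orthogonal profiles with exactly zero correlation
        x = np.array([[1.0, -1, 1, -1], [1.0, 1, -1, -1], [0.5, 1.5, 0.5, 1.5]])
        net = signed_adjacency(expr_frame(x), beta_power=12)
        assert net.adjacency[0, 1] == pytest.approx(0.5 ** 12, rel=1e-9)
        assert 0.5 ** 12 == pytest.approx(2.441e-4, rel=1e-3)

    def test_constant_gene_named(self):
        x = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="g0"):
            signed_adjacency(expr_frame(x))


class TestTOM:
    def test_two_gene_network_equals_adjacency(self):
        a = np.array([[1.0, 0.37], [0.37, 1.0]])
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx(0.37, abs=1e-12)

    def test_fully_connected_gives_ones(self):
        a = np.ones((3, 3))
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom, np.ones((3, 3)), atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        n = 20
        c = rng.uniform(-1, 1, (n, n))
        a = ((1 + (c + c.T) / 2) / 2) ** 6
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(a)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                want = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(want, abs=1e-12)

    def test_symmetric_unit_interval(self, rng):
        c = rng.uniform(-1, 1, (15, 15))
        a = ((1 + (c + c.T) / 2) / 2) ** 12
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        assert np.all(tom >= 0) and np.all(tom <= 1 + 1e-12)


class TestConsensusTOM:
    def test_equal_inputs_identity(self, rng):
        a = rng.uniform(0, 0.5, (10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(consensus_tom(a, a), a, atol=1e-12)

    def test_scaling_property(self, rng):
        a = rng.uniform(0, 0.4, (10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        cons = consensus_tom(a, 2 * a)
        off = ~np.eye(10, dtype=bool)
        np.testing.assert_allclose(cons[off], a[off], atol=1e-12)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            consensus_tom(np.ones((3, 3)), np.ones((4, 4)))


def adjusted_rand_index(labels_a, labels_b):
    """Pair-counting ARI, written directly from the contingency table."""
    from scipy.special import comb
    a = pd.Series(labels_a).astype(str)
    b = pd.Series(labels_b).astype(str)
    contingency = pd.crosstab(a, b).to_numpy()
    sum_comb = comb(contingency, 2).sum()
    sum_a = comb(contingency.sum(axis=1), 2).sum()
    sum_b = comb(contingency.sum(axis=0), 2).sum()
    n = comb(len(a), 2)
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2
    return (sum_comb - expected) / (max_index - expected)


class TestDetectModules:
    def test_planted_modules_recovered(self, rng):
        expr_a, truth = modular_expression(rng, n_modules=5, module_size=40,
                                           n_background=80, noise=0.3)
        expr_b, _ = modular_expression(np.random.default_rng(77), n_modules=5,
                                       module_size=40, n_background=80, noise=0.3)
        # same modular structure in both datasets (same gene blocks)
        tom_a = topological_overlap(signed_adjacency(expr_a).adjacency)
        tom_b = topological_overlap(signed_adjacency(expr_b).adjacency)
        cons = consensus_tom(tom_a, tom_b)
        assign = detect_modules(cons, expr_a, expr_b, min_size=30)
        detected = assign.labels.to_numpy()
        in_module = truth > 0
        ari = adjusted_rand_index(truth[in_module], detected[in_module])
        assert ari > 0.8
        assert len(assign.module_sizes) >= 4

    def test_shared_factor_modules_merge(self, rng):
        # two gene blocks driven by the SAME factor in both datasets
        f = rng.normal(size=50)
        expr_a, _ = modular_expression(rng, n_modules=2, module_size=40,
                                       n_background=40, n_samples=50,
                                       noise=0.2, factors=[f, f])
        expr_b, _ = modular_expression(np.random.default_rng(5), n_modules=2,
                                       module_size=40, n_background=40,
                                       n_samples=50, noise=0.2, factors=[f, f])
        tom_a = topological_overlap(signed_adjacency(expr_a).adjacency)
        tom_b = topological_overlap(signed_adjacency(expr_b).adjacency)
        cons = consensus_tom(tom_a, tom_b)
        assign = detect_modules(cons, expr_a, expr_b, min_size=30)
        module_genes = assign.labels[assign.labels != "unassigned"]
        first_80 = module_genes.iloc[: len(module_genes)].index[:80]
        labels_80 = set(assign.labels[g] for g in assign.labels.index[:80]
                        if assign.labels[g] != "unassigned")
        assert len(labels_80) == 1  # both planted blocks carry one label

    def test_noise_gene_removed_by_kme_rule(self, rng):
        expr_a, truth = modular_expression(rng, n_modules=2, module_size=40,
                                           n_background=30, noise=0.2)
        expr_b = expr_a.copy()
        tom = topological_overlap(signed_adjacency(expr_a).adjacency)
        cons = consensus_tom(tom, tom)
        assign = detect_modules(cons, expr_a, expr_b, min_size=30, min_kme=0.3)
        noise_genes = assign.labels.index[truth == 0]
        module_noise = [g for g in noise_genes if assign.labels[g] != "unassigned"]
        if module_noise:  # any noise gene kept must clear the kME bar
            for g in module_noise:
                assert assign.kme_a.loc[g, assign.labels[g]] >= 0.3

    def test_gene_order_permutation_invariant(self, rng):
        expr_a, _ = modular_expression(rng, n_modules=3, module_size=35,
                                       n_background=40, noise=0.25)
        expr_b, _ = modular_expression(np.random.default_rng(9), n_modules=3,
                                       module_size=35, n_background=40, noise=0.25)
        tom_a = topological_overlap(signed_adjacency(expr_a).adjacency)
        tom_b = topological_overlap(signed_adjacency(expr_b).adjacency)
        cons = consensus_tom(tom_a, tom_b)
        assign = detect_modules(cons, expr_a, expr_b, min_size=30)
        perm = np.random.default_rng(1).permutation(len(expr_a))
        expr_a_p = expr_a.iloc[perm]
        expr_b_p = expr_b.iloc[perm]
        cons_p = cons[np.ix_(perm, perm)]
        assign_p = detect_modules(cons_p, expr_a_p, expr_b_p, min_size=30)
        # identical partitions up to relabeling
        joined = pd.crosstab(assign.labels.loc[expr_a_p.index], assign_p.labels)
        assert ((joined > 0).sum(axis=1) == 1).all()


class TestEigengenes:
    def test_identical_genes_give_shared_profile(self):
        profile = np.array([1.0, 3, 2, 5, 4])
        x = np.tile(profile, (4, 1))
        labels = pd.Series(["M1"] * 4, index=[f"g{i}" for i in range(4)])
        eig = module_eigengenes(expr_frame(x), labels)
        want = (profile - profile.mean()) / profile.std(ddof=1)
        got = eig.eigengenes.loc["M1"].to_numpy()
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_sign_equivariance(self, rng):
        x = rng.normal(size=(6, 10))
        labels = pd.Series(["M1"] * 6, index=[f"g{i}" for i in range(6)])
        eig = module_eigengenes(expr_frame(x), labels).eigengenes.loc["M1"]
        eig_flipped = module_eigengenes(expr_frame(-x), labels).eigengenes.loc["M1"]
        np.testing.assert_allclose(eig_flipped, -eig, atol=1e-8)

    def test_unit_variance_and_positive_mean_correlation(self, rng):
        x = np.outer(rng.uniform(0.5, 1.5, 50), rng.normal(size=30))
        x += rng.normal(0, 0.4, x.shape)
        labels = pd.Series(["M1"] * 50, index=[f"g{i}" for i in range(50)])
        eig_set = module_eigengenes(expr_frame(x), labels)
        e = eig_set.eigengenes.loc["M1"]
        assert e.std(ddof=1) == pytest.approx(1.0)
        cors = [stats.pearsonr(x[i], e)[0] for i in range(50)]
        assert np.mean(cors) > 0

    def test_pc1_variance_matches_eigendecomposition(self, rng):
        x = rng.normal(size=(50, 25))
        labels = pd.Series(["M1"] * 50, index=[f"g{i}" for i in range(50)])
        eig_set = module_eigengenes(expr_frame(x), labels)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        evals = np.linalg.eigvalsh(z @ z.T)
        assert eig_set.explained["M1"] == pytest.approx(evals[-1] / evals.sum(), abs=1e-8)


class TestAssociationAndConvergence:
    def test_noiseless_indicator_eigengene(self):
        meta = SampleTable(make_metadata(10, diagnosis=["control"] * 5 + ["case"] * 5))
        eig = pd.DataFrame([[0.0] * 5 + [1.0] * 5], index=["M1"],
                           columns=meta.frame["sample_id"])
        assoc = eigengene_association(eig, meta, "diagnosis")
        assert assoc.iloc[0]["p"] < 1e-12

    def test_permuted_labels_calibrated(self):
        ps = []
        for s in range(100):
            rng = np.random.default_rng(s)
            meta = SampleTable(make_metadata(40, seed=s))
            eig = pd.DataFrame(rng.normal(size=(2, 40)), index=["M1", "M2"],
                               columns=meta.frame["sample_id"])
            assoc = eigengene_association(eig, meta, "diagnosis")
            ps.extend(assoc["p"])
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.04

    def test_planted_shift_detected(self):
        power = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            meta = SampleTable(make_metadata(80, seed=s))
            case = (meta.frame["diagnosis"] == "case").to_numpy(dtype=float)
            eig = pd.DataFrame((rng.normal(size=80) + case)[None, :], index=["M1"],
                               columns=meta.frame["sample_id"])
            assoc = eigengene_association(eig, meta, "diagnosis")
            power += assoc.iloc[0]["p"] < 0.05
        assert power >= 19  # ~99% power at +1 SD, n = 40/40

    @pytest.mark.parametrize("ta,tb,want", [
        (3.0, 2.5, "convergent"),
        (3.0, -2.5, "divergent"),
        (3.0, 1.0, "indeterminate"),
        (-3.0, -2.5, "convergent"),
    ])
    def test_classification_rules(self, ta, tb, want):
        assoc_a = pd.DataFrame([{"module": "M1", "level": "case", "t": ta, "p": 0.01}])
        assoc_b = pd.DataFrame([{"module": "M1", "level": "drug", "t": tb, "p": 0.01}])
        out = classify_convergence(assoc_a, assoc_b, t_threshold=2.0)
        assert out.iloc[0]["classification"] == want
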