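import numpy as np
import pandas as pd
import pytest

from pnmine.containers import ExpressionMatrix, MergedExpression, PipelineError
from pnmine.network import (
    ConsensusModuleDetector,
    ModuleAssignment,
    Network,
    adjacency,
    consensus_tom,
    detect_modules,
    eigengene_adjacency,
    module_eigengenes,
    pick_soft_power,
    preservation_zsummary,
    tom,
)
from pnmine.preprocess import intersect_and_merge, standardize_genes
from pnmine.synthetic import SimConfig, generate_expression

from conftest import expr_from_array


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the topological overlap formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    w = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            w[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return w


def random_adjacency(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return Network(pd.Index([f"g{i}" for i in range(n)]), a, "adjacency", 6)


class TestAdjacency:
    def test_power_one_is_absolute_correlation(self):
        rng = np.random.default_rng(3)
        expr = expr_from_array(rng.normal(size=(8, 12)))
        net = adjacency(expr, beta=1)
        cor = np.corrcoef(expr.values.to_numpy())
        assert np.allclose(net.matrix, np.abs(cor), atol=1e-12)

    def test_soft_power_arithmetic(self):
        # two genes engineered so their correlation is exactly 0.5
        x = np.array([1.0, -1.0, 1.0, -1.0, 0.0, 0.0, 2.0, -2.0])
        y = 0.5 * x + np.sqrt(0.75) * np.array([0.0, 0.0, 2.0, -2.0, 1.0, -1.0, -1.0, 1.0])
        r = np.corrcoef(x, y)[0, 1]
        expr = expr_from_array(np.vstack([x, y]))
        net = adjacency(expr, beta=2)
        assert net.matrix[0, 1] == pytest.approx(abs(r) ** 2, abs=1e-12)

    def test_perfect_correlation_saturates(self):
        expr = expr_from_array([[1, 2, 3, 4], [2, 4, 6, 8]])
        for beta in (1, 4, 8):
            assert adjacency(expr, beta).matrix[0, 1] == pytest.approx(1.0)

    def test_zero_variance_gene_warns_and_correlates_zero(self):
        expr = expr_from_array([[5, 5, 5, 5], [1, 2, 3, 4]])
        with pytest.warns(UserWarning, match="zero-variance"):
            net = adjacency(expr, beta=2)
        assert net.matrix[0, 1] == 0.0
        assert net.matrix[0, 0] == 1.0


class TestTom:
    def test_complete_graph_saturates(self):
        net = Network(pd.Index(["a", "b", "c"]), np.ones((3, 3)), "adjacency", 1)
        assert np.allclose(tom(net).matrix, 1.0)

    @pytest.mark.parametrize("a_val", [0.2, 0.5, 0.9])
    def test_isolated_pair_equals_adjacency(self, a_val):
        # a_12 = a, everything else 0: L=0, k1=k2=a, w = a/(a+1-a) = a
        m = np.eye(4)
        m[0, 1] = m[1, 0] = a_val
        net = Network(pd.Index(list("abcd")), m, "adjacency", 1)
        assert tom(net).matrix[0, 1] == pytest.approx(a_val, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        net = random_adjacency(6, seed)
        assert np.allclose(tom(net).matrix, brute_force_tom(net.matrix), atol=1e-12)

    def test_output_bounds_and_symmetry(self):
        net = random_adjacency(12, 5)
        w = tom(net)
        assert w.matrix.min() >= 0 and w.matrix.max() <= 1
        assert np.allclose(w.matrix, w.matrix.T)
        assert np.allclose(np.diag(w.matrix), 1.0)


class TestConsensusTom:
    def test_identity(self):
        t = tom(random_adjacency(8, 0))
        cons = consensus_tom(t, t)
        assert np.allclose(cons.matrix, t.matrix, atol=1e-12)

    def test_absorbing_zero(self):
        t = tom(random_adjacency(8, 1))
        zero = Network(t.node_ids, np.eye(8), "tom", 6)
        cons = consensus_tom(t, zero)
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(cons.matrix[off], 0.0)

    def test_doubled_input_rescales_to_reference(self):
        base = tom(random_adjacency(8, 2))
        half = Network(base.node_ids, np.where(np.eye(8), 1.0, base.matrix * 0.5), "tom", 6)
        cons = consensus_tom(base, half)
        assert np.allclose(cons.matrix, base.matrix, atol=1e-8)

    def test_bounded_by_scaled_inputs(self):
        a, b = tom(random_adjacency(10, 3)), tom(random_adjacency(10, 4))
        cons = consensus_tom(a, b)
        iu = np.triu_indices(10, 1)
        q_a = np.quantile(a.matrix[iu], 0.95)
        q_b = np.quantile(b.matrix[iu], 0.95)
        scaled_b = b.matrix * (q_a / q_b)
        assert np.all(cons.matrix[iu] <= np.minimum(a.matrix, scaled_b)[iu] + 1e-12)

    def test_node_mismatch_raises(self):
        a = tom(random_adjacency(5, 0))
        b = tom(random_adjacency(6, 0))
        with pytest.raises(PipelineError):
            consensus_tom(a, b)


class TestDetectModules:
    @staticmethod
    def _two_block_tom():
        # two noise-free blocks of 50 genes each
        rng = np.random.default_rng(7)
        f1, f2 = rng.normal(size=10), rng.normal(size=10)
        block = np.vstack([np.outer(rng.uniform(0.5, 1, 50), f1),
                           np.outer(rng.uniform(0.5, 1, 50), f2)])
        expr = expr_from_array(block)
        return tom(adjacency(expr, 6)), expr

    def test_noise_free_blocks_recovered_exactly(self):
        consensus, _ = self._two_block_tom()
        modules = detect_modules(consensus, min_module_size=10)
        labels = modules.labels
        assert len(modules.modules) == 2
        first, second = labels.iloc[:50], labels.iloc[50:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_min_size_dominance_makes_everything_grey(self):
        consensus, _ = self._two_block_tom()
        with pytest.warns(UserWarning, match="every gene is grey"):
            modules = detect_modules(consensus, min_module_size=1000)
        assert set(modules.labels) == {"grey"}

    def test_gene_order_invariance(self):
        consensus, _ = self._two_block_tom()
        modules = detect_modules(consensus, min_module_size=10)
        perm = np.random.default_rng(1).permutation(consensus.n_nodes)
        shuffled = Network(
            consensus.node_ids[perm], consensus.matrix[np.ix_(perm, perm)], "tom", 6
        )
        modules_perm = detect_modules(shuffled, min_module_size=10)
        joined = pd.concat(
            [modules.labels.rename("a"), modules_perm.labels.rename("b")], axis=1
        )
        # same partition up to label names
        assert joined.groupby("a")["b"].nunique().max() == 1
        assert joined.groupby("b")["a"].nunique().max() == 1


class TestEigengenes:
    def test_rank_one_block_variance_explained(self):
        profile = np.array([1.0, 3.0, -2.0, 0.5, 4.0])
        expr = expr_from_array(np.vstack([profile, 2 * profile, 0.5 * profile]))
        modules = ModuleAssignment(pd.Series("blue", index=expr.gene_ids, name="module"))
        eig = module_eigengenes(expr, modules)
        assert eig.variance_explained["blue"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(eig.scores.loc["blue"].to_numpy(), z, atol=1e-10)

    def test_sign_convention_follows_gene_orientation(self):
        # the eigengene is oriented so its mean correlation with the module's
        # genes is >= 0; negating every gene therefore negates the oriented
        # eigengene, and both orientations satisfy the rule
        rng = np.random.default_rng(11)
        block = rng.normal(size=(15, 8))
        expr = expr_from_array(block)
        modules = ModuleAssignment(pd.Series("m", index=expr.gene_ids, name="module"))
        eig_pos = module_eigengenes(expr, modules).scores.loc["m"].to_numpy()
        eig_neg = module_eigengenes(expr_from_array(-block), modules).scores.loc["m"].to_numpy()
        assert np.allclose(eig_pos, -eig_neg, atol=1e-10)
        z = standardize_genes(expr.values).to_numpy()
        mean_cor = np.mean([np.corrcoef(row, eig_pos)[0, 1] for row in z])
        assert mean_cor >= 0
        mean_cor_neg = np.mean([np.corrcoef(-row, eig_neg)[0, 1] for row in z])
        assert mean_cor_neg >= 0

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(4)
        block = rng.normal(size=(20, 10))
        expr = expr_from_array(block)
        modules = ModuleAssignment(pd.Series("m", index=expr.gene_ids, name="module"))
        eig = module_eigengenes(expr, modules).scores.loc["m"].to_numpy()
        z = standardize_genes(expr.values).to_numpy()
        evals, evecs = np.linalg.eigh(z.T @ z)
        lead = evecs[:, -1]
        lead = lead / lead.std(ddof=1)
        assert min(
            np.abs(eig - lead).max(), np.abs(eig + lead).max()
        ) == pytest.approx(0.0, abs=1e-8)

    def test_single_gene_module_is_standardized_profile(self):
        expr = expr_from_array([[2.0, 4.0, 6.0, 8.0]])
        modules = ModuleAssignment(pd.Series("solo", index=expr.gene_ids, name="module"))
        eig = module_eigengenes(expr, modules)
        expected = standardize_genes(expr.values).to_numpy()[0]
        assert np.allclose(eig.scores.loc["solo"].to_numpy(), expected)


class TestEigengeneAdjacency:
    def _set(self, rows):
        scores = pd.DataFrame(rows, index=[f"m{i}" for i in range(len(rows))])
        return type("E", (), {"scores": scores, "modules": scores.index})()

    def test_limits(self):
        e = np.array([1.0, -1.0, 2.0, -2.0])
        eig = self._set([e, e, -e, np.array([1.0, 1.0, -1.0, -1.0])])
        adj = eigengene_adjacency(eig)
        assert adj.iloc[0, 1] == pytest.approx(1.0)   # identical -> 1
        assert adj.iloc[0, 2] == pytest.approx(0.0)   # anti-correlated -> 0
        assert adj.iloc[0, 3] == pytest.approx(0.5)   # orthogonal -> 0.5
        assert np.all(adj.to_numpy() >= 0) and np.all(adj.to_numpy() <= 1)


class TestPreservation:
    def test_coherent_module_identical_sets_scores_high(self):
        rng = np.random.default_rng(0)
        factor = rng.normal(size=12)
        module = np.outer(rng.uniform(0.6, 1, 30), factor) + 0.3 * rng.normal(size=(30, 12))
        background = rng.normal(size=(70, 12))
        expr = expr_from_array(np.vstack([module, background]))
        labels = pd.Series("grey", index=expr.gene_ids, name="module")
        labels.iloc[:30] = "blue"
        stats = preservation_zsummary(expr, expr, ModuleAssignment(labels), n_perm=100, seed=1)
        assert stats.table.loc["blue", "z_summary"] > 5

    def test_random_module_scores_near_zero(self):
        rng = np.random.default_rng(5)
        expr = expr_from_array(rng.normal(size=(100, 12)))
        tumor = expr_from_array(rng.normal(size=(100, 12)), tag="tumor")
        hits = 0
        for seed in range(5):
            picks = np.random.default_rng(seed).choice(100, 20, replace=False)
            labels = pd.Series("grey", index=expr.gene_ids, name="module")
            labels.iloc[picks] = "rand"
            stats = preservation_zsummary(
                expr, tumor, ModuleAssignment(labels), n_perm=100, seed=seed
            )
            if abs(stats.table.loc["rand", "z_summary"]) < 2:
                hits += 1
        assert hits >= 4  # |Z| < 2 with probability >= 0.9

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        expr = expr_from_array(rng.normal(size=(60, 10)))
        tumor = expr_from_array(rng.normal(size=(60, 10)), tag="tumor")
        labels = pd.Series("grey", index=expr.gene_ids, name="module")
        labels.iloc[:15] = "m"
        ma = ModuleAssignment(labels)
        a = preservation_zsummary(expr, tumor, ma, n_perm=60, seed=42).table
        b = preservation_zsummary(expr, tumor, ma, n_perm=60, seed=42).table
        pd.testing.assert_frame_equal(a, b)

    def test_tiny_module_reported_missing(self):
        rng = np.random.default_rng(3)
        expr = expr_from_array(rng.normal(size=(50, 8)))
        tumor = expr_from_array(rng.normal(size=(50, 8)), tag="tumor")
        labels = pd.Series("grey", index=expr.gene_ids, name="module")
        labels.iloc[:2] = "tiny"
        stats = preservation_zsummary(expr, tumor, ModuleAssignment(labels), n_perm=50, seed=0)
        assert stats.table.loc["tiny"].isna().all()


class TestSoftPower:
    def test_white_noise_falls_back_to_default(self):
        rng = np.random.default_rng(9)
        cell = expr_from_array(rng.normal(size=(300, 10)))
        tumor = expr_from_array(rng.normal(size=(300, 12)), tag="tumor")
        merged = intersect_and_merge(cell, tumor)
        report = pick_soft_power(merged, candidates=[1, 2], r2_target=0.999)
        assert report.chosen == 8
        assert not report.criterion_met

    def test_too_few_genes_undefined_uses_default(self):
        rng = np.random.default_rng(9)
        sub = expr_from_array(rng.normal(size=(2, 10)))
        tum = expr_from_array(rng.normal(size=(2, 10)), tag="tumor")
        merged = MergedExpression(
            ExpressionMatrix(sub.values, "cell_line"), ExpressionMatrix(tum.values, "tumor")
        )
        report = pick_soft_power(merged, candidates=[2, 4])
        assert report.chosen == 8
        assert all(np.isnan(v) for v in report.r_squared.values())

    def test_choice_stable_across_generator_seeds(self):
        chosen = []
        for seed in (0, 1):
            cfg = SimConfig(
                n_genes=400, n_modules=4, module_sizes=[70, 60, 50, 40],
                preserved_flags=[True] * 4, n_cell_lines=12, n_tumors=12, seed=seed,
            )
            cell, tumor, _ = generate_expression(cfg)
            merged = intersect_and_merge(cell, tumor)
            chosen.append(pick_soft_power(merged, candidates=[2, 4, 6, 8, 10]).chosen)
        assert chosen[0] == chosen[1]


class TestConsensusModuleDetector:
    def test_sklearn_param_interface(self):
        det = ConsensusModuleDetector(power=6, min_module_size=20)
        params = det.get_params()
        assert params["power"] == 6
        det.set_params(min_module_size=25)
        assert det.get_params()["min_module_size"] == 25

    def test_fit_recovers_planted_modules(self):
        cfg = SimConfig(
            n_genes=300, n_modules=3, module_sizes=[60, 50, 40],
            preserved_flags=[True] * 3, n_cell_lines=15, n_tumors=15,
            noise_sd=0.2, seed=6,
        )
        cell, tumor, truth = generate_expression(cfg)
        from pnmine.preprocess import mad_filter

        merged = intersect_and_merge(mad_filter(cell, 1000.0), tumor, min_shared=100)
        det = ConsensusModuleDetector(min_module_size=20).fit(merged)
        from sklearn.metrics import adjusted_rand_score

        true = truth.true_module_of_gene.loc[merged.gene_ids]
        assert adjusted_rand_score(true, det.labels_) > 0.9
        assert set(det.eigengenes_cell_.modules) == set(det.modules_.modules)
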