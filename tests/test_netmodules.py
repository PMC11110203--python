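import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from plaquekg.netmodules import (
    adjacency,
    detect_modules,
    module_trait,
    pick_soft_threshold,
    tom_similarity,
)
from plaquekg.syndata import GeneratorConfig, generate_cohort, generate_expression


def expression_frame(cfg):
    _, truth = generate_cohort(cfg)
    X, genes, labels = generate_expression(cfg, truth)
    return pd.DataFrame(X.T, columns=genes), truth, labels  # samples x genes


class TestAdjacency:
    def test_perfect_correlation_any_power(self):
        m = np.column_stack([np.arange(10.0), 2 * np.arange(10.0) + 1])
        for beta in (1, 5, 9):
            assert adjacency(m, beta)[0, 1] == pytest.approx(1.0)

    def test_half_correlation_ninth_power(self):
        rng = np.random.default_rng(0)
        # construct two columns with |cor| = 0.5 exactly via orthogonal basis
        a = rng.standard_normal(500)
        b = rng.standard_normal(500)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        b /= b.std()
        col2 = -0.5 * a + np.sqrt(0.75) * b
        m = np.column_stack([a, col2])
        assert adjacency(m, 9)[0, 1] == pytest.approx(0.5**9, rel=1e-6)
        assert 0.5**9 == 0.001953125

    def test_beta_one_is_absolute_correlation(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal((30, 4))
        np.testing.assert_allclose(adjacency(m, 1), np.abs(np.corrcoef(m, rowvar=False)),
                                   atol=1e-12)

    def test_zero_variance_column_error(self):
        m = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency(m, 2)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(2)
        a = adjacency(rng.standard_normal((40, 8)), 6)
        np.testing.assert_allclose(a, a.T)
        np.testing.assert_allclose(np.diag(a), 1.0)
        assert a.min() >= 0 and a.max() <= 1 + 1e-12


class TestSoftThreshold:
    def test_default_grid_contains_nine(self):
        from plaquekg.netmodules import DEFAULT_BETAS

        assert 9 in DEFAULT_BETAS

    def test_planted_scale_free_regime_recovered(self):
        """Hub-like factor loadings give scale-free connectivity; the fit
        criterion is reached at some power within the grid."""
        rng = np.random.default_rng(7)
        n_genes, n_samp = 150, 80
        w = np.arange(1, n_genes + 1) ** -0.4
        w = 0.95 * w / w.max()
        f = rng.standard_normal(n_samp)
        cols = [wi * f + np.sqrt(1 - wi**2) * rng.standard_normal(n_samp) for wi in w]
        m = pd.DataFrame(np.column_stack(cols))
        res = pick_soft_threshold(m)
        assert res.beta <= 20
        assert res.r_squared[res.beta] >= 0.8
        assert res.slopes[res.beta] < 0

    def test_block_structure_falls_back_to_recommended_power(self):
        """Planted-module matrices are bimodal, not scale-free; the chooser
        falls back to the sample-size default instead of chasing argmax."""
        cfg = GeneratorConfig(n_genes=150, n_expression_samples=80, seed=7)
        m, _truth, _labels = expression_frame(cfg)
        res = pick_soft_threshold(m)
        assert res.beta == 6
        assert max(res.r_squared.values()) < 0.8

    def test_degenerate_matrix_error(self):
        m = pd.DataFrame(np.ones((10, 5)))
        with pytest.raises(ValueError):
            pick_soft_threshold(m)


class TestTOM:
    def test_symmetric_unit_diagonal_nonnegative(self):
        rng = np.random.default_rng(3)
        a = adjacency(rng.standard_normal((50, 12)), 4)
        tom = tom_similarity(a)
        np.testing.assert_allclose(tom, tom.T)
        np.testing.assert_allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0

    def test_tom_at_least_preserves_block_contrast(self):
        cfg = GeneratorConfig(n_genes=60, n_expression_samples=80, n_planted_modules=2, seed=4)
        m, truth, _ = expression_frame(cfg)
        a = adjacency(m, 6)
        tom = tom_similarity(a)
        mods = np.array([truth.planted_modules[g] for g in m.columns])
        same = (mods[:, None] == mods[None, :]) & ~np.eye(len(mods), dtype=bool)
        assert tom[same].mean() > tom[(mods[:, None] != mods[None, :])].mean()


class TestDetectModules:
    def test_two_exact_blocks_recovered(self):
        t = np.linspace(0, 1, 30)
        rng = np.random.default_rng(5)
        f1, f2 = rng.standard_normal(30), rng.standard_normal(30)
        cols = {}
        for i in range(6):
            cols[f"a{i}"] = f1 * (1 + 0.1 * i)
        for i in range(6):
            cols[f"b{i}"] = f2 * (1 - 0.05 * i)
        m = pd.DataFrame(cols)
        res = detect_modules(m, beta=6, min_size=3)
        labels = [res.labels[g] for g in m.columns]
        truth = [0] * 6 + [1] * 6
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_planted_modules_recovered(self):
        cfg = GeneratorConfig(n_genes=120, n_expression_samples=100, seed=7)
        m, truth, _ = expression_frame(cfg)
        beta = pick_soft_threshold(m).beta
        res = detect_modules(m, beta)
        got = [res.labels[g] for g in m.columns]
        want = [truth.planted_modules[g] for g in m.columns]
        assert adjusted_rand_score(want, got) >= 0.8

    def test_eigengene_of_identical_columns(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(25)
        m = pd.DataFrame({f"g{i}": base for i in range(6)})
        m += rng.standard_normal(m.shape) * 1e-9  # break exact degeneracy of cor
        res = detect_modules(m, beta=2, min_size=3)
        eg = res.eigengenes["ME1"].to_numpy()
        for g in m.columns:
            assert abs(np.corrcoef(eg, m[g])[0, 1]) == pytest.approx(1.0, abs=1e-5)

    def test_labels_invariant_to_gene_order(self):
        cfg = GeneratorConfig(n_genes=60, n_expression_samples=60, n_planted_modules=3, seed=9)
        m, _t, _l = expression_frame(cfg)
        res1 = detect_modules(m, beta=6)
        shuffled = m[list(reversed(m.columns))]
        res2 = detect_modules(shuffled, beta=6)
        assert res1.labels == res2.labels

    def test_noise_only_matrix_is_unstructured(self):
        """Without planted structure, detected partitions do not agree with
        random labelings beyond chance."""
        rng = np.random.default_rng(10)
        aris = []
        for _ in range(10):
            m = pd.DataFrame(rng.standard_normal((40, 50)),
                             columns=[f"g{i}" for i in range(50)])
            res = detect_modules(m, beta=6, min_size=3)
            got = [res.labels[g] for g in m.columns]
            random_labels = rng.integers(0, 4, 50)
            aris.append(adjusted_rand_score(random_labels, got))
        assert abs(np.mean(aris)) < 0.05


class TestModuleTrait:
    @pytest.fixture
    def fitted(self):
        cfg = GeneratorConfig(n_genes=60, n_expression_samples=60, n_planted_modules=2, seed=11)
        m, truth, labels = expression_frame(cfg)
        res = detect_modules(m, beta=6)
        return res, m, labels

    def test_trait_equal_to_eigengene_r_one(self, fitted):
        res, m, _labels = fitted
        traits = pd.DataFrame({"self": res.eigengenes["ME1"]})
        module_trait(res, traits)
        assert res.trait_correlation.loc["ME1", "self"] == pytest.approx(1.0)

    def test_closed_form_t_statistic(self):
        """r=0.5, n=20 -> t = 0.5 sqrt(18/0.75) = 2.449; p from the t CDF."""
        r, n = 0.5, 20
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert t == pytest.approx(2.449, abs=1e-3)
        p = 2 * stats.t.sf(t, n - 2)
        # construct data with exactly this correlation and check pearsonr-based p
        a = np.linspace(-1, 1, n)
        b = a.copy()
        b = b - b.mean()
        noise = np.sin(np.arange(n) * 2.3)
        noise -= noise.mean()
        noise -= b * (b @ noise) / (b @ b)
        y = 0.5 * b / b.std() + np.sqrt(0.75) * noise / noise.std()
        rv, pv = stats.pearsonr(a, y)
        assert rv == pytest.approx(0.5, abs=1e-9)
        assert pv == pytest.approx(p, rel=1e-9)

    def test_constant_trait_reports_null(self, fitted):
        res, m, _labels = fitted
        traits = pd.DataFrame({"flat": np.ones(len(res.eigengenes))},
                              index=res.eigengenes.index)
        module_trait(res, traits)
        assert res.trait_correlation.loc["ME1", "flat"] == 0.0
        assert res.trait_pvalues.loc["ME1", "flat"] == 1.0

    def test_too_few_patients_error(self, fitted):
        res, _m, _labels = fitted
        with pytest.raises(ValueError, match="3"):
            module_trait(res, pd.DataFrame({"x": [1.0, 2.0]}))
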