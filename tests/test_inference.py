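import numpy as np
import pytest

from fetalconn._utils import triu_pairs, upper_vec, vec_to_sym
from fetalconn.inference import (
    EdgeGLM,
    edge_glm,
    nbs,
    node_stats,
    spatial_null_screen,
)


def _null_edges(n_sub, n_regions, seed):
    rng = np.random.default_rng(seed)
    n_edges = n_regions * (n_regions - 1) // 2
    z = rng.standard_normal((n_sub, n_edges))
    ga = rng.uniform(147, 259, n_sub)
    motion = rng.uniform(0.2, 1.2, n_sub)
    return z, ga, motion


class TestEdgeGLM:
    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        z, ga, motion = _null_edges(12, 5, 1)
        glm = EdgeGLM().fit(z, ga, motion)
        for e in range(4):
            full = sm.OLS(z[:, e], sm.add_constant(np.column_stack([motion, ga]))).fit()
            red = sm.OLS(z[:, e], sm.add_constant(motion)).fit()
            f_expect = (red.ssr - full.ssr) / (full.ssr / full.df_resid)
            assert glm.F_[e] == pytest.approx(f_expect, rel=1e-8)
            # F is the squared t of the age coefficient (1-df identity)
            assert glm.F_[e] == pytest.approx(full.tvalues[2] ** 2, rel=1e-8)
            assert glm.coef_ga_[e] == pytest.approx(full.params[2], rel=1e-8)

    def test_perfect_linear_effect_gives_huge_f(self):
        rng = np.random.default_rng(2)
        ga = np.linspace(150, 260, 10)
        motion = rng.uniform(0, 1, 10)
        z = np.outer(ga, np.ones(3)) * 0.01
        glm = EdgeGLM().fit(z, ga, motion)
        assert np.all(glm.F_ > 1e10)

    def test_hand_computed_five_subject_example(self):
        # brute-force normal-equations oracle on a tiny instance
        ga = np.array([150.0, 170.0, 200.0, 230.0, 250.0])
        motion = np.array([0.5, 0.7, 0.4, 0.9, 0.6])
        y = np.array([[0.1], [0.15], [0.3], [0.28], [0.42]])
        x_full = np.column_stack([np.ones(5), motion, ga])
        x_red = x_full[:, :2]
        beta_f = np.linalg.solve(x_full.T @ x_full, x_full.T @ y[:, 0])
        beta_r = np.linalg.solve(x_red.T @ x_red, x_red.T @ y[:, 0])
        sse_f = ((y[:, 0] - x_full @ beta_f) ** 2).sum()
        sse_r = ((y[:, 0] - x_red @ beta_r) ** 2).sum()
        f_expect = (sse_r - sse_f) / (sse_f / 2)
        glm = edge_glm(y, ga, motion)
        assert glm.F_[0] == pytest.approx(f_expect, rel=1e-10)

    def test_null_f_distribution_quantile(self):
        import scipy.stats

        z, ga, motion = _null_edges(32, 64, 3)  # 2016 independent null edges
        glm = EdgeGLM().fit(z, ga, motion)
        emp = np.quantile(glm.F_, 0.95)
        analytic = scipy.stats.f.ppf(0.95, 1, 29)
        assert emp == pytest.approx(analytic, rel=0.15)

    def test_constant_age_rejected(self):
        z, ga, motion = _null_edges(8, 4, 4)
        with pytest.raises(ValueError):
            EdgeGLM().fit(z, np.full(8, 200.0), motion)


class TestSpatialNullScreen:
    def _setup(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        coords = rng.normal(0, 30, (n, 3))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        i, j = triu_pairs(n)
        g = 0.5 * np.exp(-d[i, j] / 40.0)
        return rng, d, g

    def test_on_curve_edges_retained_at_alpha_rate(self):
        rng, d, g = self._setup(0)
        z = g + rng.normal(0, 0.05, (32, g.size))
        retained = spatial_null_screen(z, d, n_sim=500, alpha=0.05, seed=1)
        frac = upper_vec(retained).mean()
        assert 0.005 <= frac <= 0.15

    def test_extreme_edge_always_retained(self):
        rng, d, g = self._setup(1)
        z = g + rng.normal(0, 0.05, (32, g.size))
        z[:, 10] += 10 * 0.05
        retained = spatial_null_screen(z, d, n_sim=500, seed=2)
        assert upper_vec(retained)[10]

    def test_degenerate_zero_noise_retains_nothing(self):
        _, d, g = self._setup(2)
        z = np.tile(g, (16, 1))
        retained = spatial_null_screen(z, d, n_sim=200, seed=3)
        assert not retained.any()


class TestNbs:
    def _three_region_stack(self, seed=0):
        # strong age effect on edges (0,1) and (1,2); edge (0,2) pure noise
        rng = np.random.default_rng(seed)
        n_sub = 16
        ga = np.linspace(150, 260, n_sub)
        motion = rng.uniform(0, 1, n_sub)
        z = rng.normal(0, 0.05, (n_sub, 3))
        trend = (ga - ga.mean()) / np.ptp(ga)
        z[:, 0] += trend  # edge (0,1)
        z[:, 2] += trend  # edge (1,2)
        return z, ga, motion

    def test_component_extraction_direct(self):
        z, ga, motion = self._three_region_stack()
        res = nbs(z, ga, motion, threshold_f=5, n_perm=200, seed=4)
        assert len(res.components) == 1
        assert res.extents[0] == 2

    def test_p_value_add_one_convention(self):
        z, ga, motion = self._three_region_stack()
        res = nbs(z, ga, motion, threshold_f=5, n_perm=200, seed=5)
        if np.all(res.null_max_extent < res.extents[0]):
            assert res.p_values[0] == pytest.approx(1 / 201)
        assert np.all(res.p_values > 0) and np.all(res.p_values <= 1)

    def test_empty_result_without_suprathreshold_edges(self):
        rng = np.random.default_rng(6)
        z = rng.normal(0, 1e-12, (12, 6)) + 5.0
        z += rng.normal(0, 1e-12, (12, 6))
        ga = np.linspace(150, 260, 12)
        motion = rng.uniform(0, 1, 12)
        res = nbs(z, ga, motion, threshold_f=1e12, n_perm=100, seed=0)
        assert len(res.components) == 0
        assert not res.significant_mask.any()

    def test_region_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        n = 8
        i, j = triu_pairs(n)
        z, ga, motion = _null_edges(20, n, 8)
        z[:, :5] += np.linspace(-1, 1, 20)[:, None]
        res = nbs(z, ga, motion, threshold_f=5, n_perm=150, seed=9)
        perm = rng.permutation(n)
        z_mat = np.stack([vec_to_sym(row, n) for row in z])
        z_perm = z_mat[:, perm][:, :, perm]
        res2 = nbs(z_perm, ga, motion, threshold_f=5, n_perm=150, seed=9)
        assert sorted(res.extents) == sorted(res2.extents)
        assert sorted(res.p_values) == pytest.approx(sorted(res2.p_values))

    def test_detected_component_is_mostly_true_effect(self, atlas70, truth70):
        from fetalconn.validation import analyze_cohort

        analysis = analyze_cohort(atlas70, truth70, n_subjects=32, seed=1004, n_perm=300)
        sig = upper_vec(analysis.significant_mask)
        assert sig.any()
        eff = upper_vec(truth70.effect_mask)
        precision = (sig & eff).sum() / sig.sum()
        assert precision >= 0.6


class TestNodeStats:
    def test_uniform_f_gives_uniform_nodes(self):
        f = np.full((5, 5), 3.0)
        np.fill_diagonal(f, 0)
        assert np.allclose(node_stats(f), 3.0)

    def test_single_hot_edge_elevates_both_endpoints(self):
        f = np.zeros((6, 6))
        f[1, 4] = f[4, 1] = 10.0
        stats = node_stats(f)
        assert stats[1] == stats[4] == pytest.approx(2.0)
        assert np.all(stats[[0, 2, 3, 5]] == 0.0)

    def test_hand_enumeration_four_regions(self):
        vec = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])  # edges in triu order
        f = vec_to_sym(vec, 4)
        expect = f.sum(axis=1) / 3
        assert np.allclose(node_stats(f), expect)
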