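"""Sampler correctness: eigen machinery, conjugate oracles, predictions."""

import numpy as np
import pytest

from mkgp.inference import (
    ChainConfig,
    ModelSpec,
    RandomEffectTerm,
    ScaledInvChi2,
    eigendecompose,
    fitted_values,
    gebv,
    gibbs_fit,
    posterior_predict,
)
from mkgp.kernels import KernelMatrix, grm_linear, incidence_matrix, transcriptome_kernel
from mkgp.simulate import SimConfig, simulate_genotypes, simulate_phenotypes


def single_env_model(panel, G, extra_terms=()):
    n = panel.n_lines
    obs = [f"o{i}" for i in range(n)]
    Zg = incidence_matrix(obs, dict(zip(obs, panel.line_ids)), list(panel.line_ids))
    terms = [RandomEffectTerm("g", G, Zg), *extra_terms]
    return ModelSpec(terms=terms, obs_ids=np.array(obs, dtype=object))


@pytest.fixture(scope="module")
def additive_sim():
    cfg = SimConfig(n_lines=50, n_markers=400, n_envs=1, var_additive=1.0,
                    var_residual=1.0, seed=11)
    panel = simulate_genotypes(cfg)
    G = grm_linear(panel)
    sp = simulate_phenotypes(panel, {"g": G}, cfg)
    return panel, G, sp


class TestEigendecompose:
    def test_identity_kernel(self):
        eig = eigendecompose(KernelMatrix(np.eye(5), np.arange(5), "G"))
        np.testing.assert_allclose(eig.eigenvalues, 1.0)
        assert eig.rank == 5

    def test_rank_one_kernel(self, micro_panel):
        eig = eigendecompose(grm_linear(micro_panel))
        assert eig.rank == 1

    def test_trace_preserved(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((20, 12))
        K = A @ A.T
        eig = eigendecompose(K)
        assert eig.eigenvalues.sum() == pytest.approx(np.trace(K), rel=1e-10)
        np.testing.assert_allclose((eig.U * eig.eigenvalues) @ eig.U.T, K, atol=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(np.array([[1.0, 0.3], [0.0, 1.0]]))


class TestChainConfig:
    def test_burn_in_must_be_smaller(self):
        with pytest.raises(ValueError):
            ChainConfig(iterations=100, burn_in=100)

    def test_draw_count(self):
        assert ChainConfig(1200, 200, 5).n_draws == 200


class TestGibbsOracle:
    def test_fixed_variances_match_closed_form_blup(self, additive_sim):
        # with variances pinned at truth the posterior mean effect must match
        # u* = K (K + lambda I)^-1 (y - mu), the mixed-model solution
        panel, G, sp = additive_sim
        y = sp.phenotypes["trait"].to_numpy()
        model = single_env_model(panel, G)
        s = gibbs_fit(y, model, ChainConfig(2500, 500, 2, seed=3),
                      fixed_variances={"g": 1.0, "residual": 1.0})
        u_hat = s.effects["g"].mean(axis=0)
        u_star = G.entries @ np.linalg.solve(G.entries + np.eye(50), y - y.mean())
        assert np.corrcoef(u_hat, u_star)[0, 1] > 0.99

    def test_huge_shrinkage_prior_collapses_to_intercept(self, additive_sim):
        panel, G, sp = additive_sim
        y = sp.phenotypes["trait"].to_numpy()
        model = single_env_model(panel, G)
        model.terms[0].prior = ScaledInvChi2(df=1e9, scale=1e-9)
        s = gibbs_fit(y, model, ChainConfig(600, 200, 2, seed=4))
        pred = posterior_predict(s, model)
        np.testing.assert_allclose(pred, s.intercepts.mean(), atol=0.02)

    def test_identical_seed_identical_draws(self, additive_sim):
        panel, G, sp = additive_sim
        y = sp.phenotypes["trait"].to_numpy()
        model = single_env_model(panel, G)
        a = gibbs_fit(y, model, ChainConfig(300, 100, 2, seed=5))
        b = gibbs_fit(y, model, ChainConfig(300, 100, 2, seed=5))
        np.testing.assert_array_equal(a.variances["g"], b.variances["g"])
        np.testing.assert_array_equal(a.effects["g"], b.effects["g"])

    def test_masked_values_never_enter_the_chain(self, additive_sim):
        # two phenotype vectors identical on the training half, arbitrary on
        # the masked half, give bitwise-identical posteriors
        panel, G, sp = additive_sim
        y = sp.phenotypes["trait"].to_numpy()
        model = single_env_model(panel, G)
        y1, y2 = y.copy(), y.copy()
        y1[:20] = np.nan
        y2[:20] = np.nan
        a = gibbs_fit(y1, model, ChainConfig(300, 100, 2, seed=6))
        b = gibbs_fit(y2, model, ChainConfig(300, 100, 2, seed=6))
        np.testing.assert_array_equal(a.effects["g"], b.effects["g"])


class TestPrediction:
    def test_in_sample_prediction_equals_fitted(self, additive_sim):
        panel, G, sp = additive_sim
        y = sp.phenotypes["trait"].to_numpy()
        model = single_env_model(panel, G)
        s = gibbs_fit(y, model, ChainConfig(400, 100, 2, seed=7))
        np.testing.assert_allclose(
            posterior_predict(s, model, model.obs_ids), fitted_values(s, model)
        )

    def test_unknown_target_raises(self, additive_sim):
        panel, G, sp = additive_sim
        model = single_env_model(panel, G)
        s = gibbs_fit(sp.phenotypes["trait"].to_numpy(), model, ChainConfig(200, 100, 2, seed=8))
        with pytest.raises(KeyError, match="nope"):
            posterior_predict(s, model, ["nope"])

    def test_duplicate_line_predicted_like_its_twin(self):
        # a masked line genetically identical to a training line inherits its
        # fitted genetic value under whole-kernel conditioning
        cfg = SimConfig(n_lines=40, n_markers=300, n_envs=1, var_additive=2.0,
                        var_residual=0.05, seed=12)
        panel = simulate_genotypes(cfg)
        panel.codes[1] = panel.codes[0]  # line 1 duplicates line 0
        G = grm_linear(panel)
        sp = simulate_phenotypes(panel, {"g": G}, cfg)
        y = sp.phenotypes["trait"].to_numpy()
        y[1] = y[0]
        model = single_env_model(panel, G)
        y_masked = y.copy()
        y_masked[1] = np.nan
        s = gibbs_fit(y_masked, model, ChainConfig(1500, 500, 2, seed=9))
        pred = posterior_predict(s, model)
        assert pred[1] == pytest.approx(pred[0], abs=1e-6)
        keep = np.ones(40, dtype=bool)
        keep[1] = False
        assert np.corrcoef(pred[keep], y[keep])[0, 1] > 0.9


class TestGEBV:
    def test_recovery_improves_with_chain_length(self, additive_sim):
        panel, G, sp = additive_sim
        y = sp.phenotypes["trait"].to_numpy()
        true_g = sp.true_effects["trait"]["effects"]["g"]
        model = single_env_model(panel, G)
        short = gebv(gibbs_fit(y, model, ChainConfig(60, 10, 1, seed=10)), model)
        long = gebv(gibbs_fit(y, model, ChainConfig(2500, 500, 2, seed=10)), model)
        r_short = np.corrcoef(short.to_numpy(), true_g)[0, 1]
        r_long = np.corrcoef(long.to_numpy(), true_g)[0, 1]
        assert r_long > 0.6
        assert r_long >= r_short - 0.05

    def test_permuting_lines_permutes_gebv(self, additive_sim):
        panel, G, sp = additive_sim
        y = sp.phenotypes["trait"].to_numpy()
        model = single_env_model(panel, G)
        g1 = gebv(gibbs_fit(y, model, ChainConfig(400, 100, 2, seed=11)), model)

        perm = np.random.default_rng(1).permutation(panel.n_lines)
        from mkgp.kernels import GenotypePanel

        panel2 = GenotypePanel(panel.line_ids[perm], panel.codes[perm])
        model2 = single_env_model(panel2, grm_linear(panel2))
        g2 = gebv(gibbs_fit(y[perm], model2, ChainConfig(400, 100, 2, seed=11)), model2)
        # same line -> same breeding value, independent of ordering
        joined = g1.to_frame("a").join(g2.to_frame("b"))
        assert np.corrcoef(joined["a"], joined["b"])[0, 1] > 0.99

    def test_transcriptome_term_excluded(self, additive_sim):
        panel, G, sp = additive_sim
        rng = np.random.default_rng(2)
        T = transcriptome_kernel(rng.standard_normal((50, 30)), panel.line_ids)
        obs = [f"o{i}" for i in range(50)]
        Zg = incidence_matrix(obs, dict(zip(obs, panel.line_ids)), list(panel.line_ids))
        model = ModelSpec(
            terms=[RandomEffectTerm("g", G, Zg), RandomEffectTerm("t", T, Zg)],
            obs_ids=np.array(obs, dtype=object),
        )
        y = sp.phenotypes["trait"].to_numpy()
        s = gibbs_fit(y, model, ChainConfig(300, 100, 2, seed=12))
        bv = gebv(s, model)
        manual = s.effects["g"].mean(axis=0)  # one obs per line, same order
        np.testing.assert_allclose(bv.to_numpy(), manual)

    def test_no_genetic_term_errors(self, additive_sim):
        panel, G, sp = additive_sim
        rng = np.random.default_rng(3)
        T = transcriptome_kernel(rng.standard_normal((50, 30)), panel.line_ids)
        obs = [f"o{i}" for i in range(50)]
        Zg = incidence_matrix(obs, dict(zip(obs, panel.line_ids)), list(panel.line_ids))
        model = ModelSpec(terms=[RandomEffectTerm("t", T, Zg)], obs_ids=np.array(obs, dtype=object))
        s = gibbs_fit(sp.phenotypes["trait"].to_numpy(), model, ChainConfig(200, 100, 2, seed=13))
        with pytest.raises(ValueError, match="genetic"):
            gebv(s, model)
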