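"""Kernel construction: hand-checked examples and structural invariants."""

import numpy as np
import pytest

from mkgp._util import MkgpWarning
from mkgp.kernels import (
    GenotypePanel,
    KernelMatrix,
    center_genotypes,
    dominance_kernel,
    epistasis_kernel,
    gaussian_kernel,
    grm_linear,
    gxe_block_kernel,
    incidence_matrix,
    median_bandwidth,
    transcriptome_kernel,
)


def panel_from(codes, ids=None):
    codes = np.asarray(codes, dtype=float)
    ids = ids or [f"l{i}" for i in range(codes.shape[0])]
    return GenotypePanel(np.array(ids, dtype=object), codes)


class TestCentering:
    def test_hand_example_column_012(self, micro_panel):
        W, keep = center_genotypes(micro_panel)
        assert keep.all()
        np.testing.assert_allclose(W[:, 0], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(micro_panel.allele_freq, [0.5])

    def test_column_means_zero(self):
        rng = np.random.default_rng(0)
        panel = panel_from(rng.integers(0, 3, size=(25, 40)))
        W, _ = center_genotypes(panel)
        np.testing.assert_allclose(W.mean(axis=0), 0.0, atol=1e-12)

    def test_monomorphic_column_dropped_with_warning(self):
        panel = panel_from([[0, 0], [1, 0], [2, 0]])
        with pytest.warns(MkgpWarning, match="MONOMORPHIC"):
            W, keep = center_genotypes(panel)
        assert keep.tolist() == [True, False]
        assert W.shape == (3, 1)

    def test_minus_one_zero_one_dialect_equivalent(self):
        a = panel_from([[0, 2], [1, 1], [2, 0]])
        b = panel_from([[-1, 1], [0, 0], [1, -1]])
        np.testing.assert_allclose(a.codes, b.codes)

    def test_ambiguous_dialect_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            panel_from([[0, 1], [1, 0], [0, 0]])


class TestGRM:
    def test_hand_example_single_marker(self, micro_panel):
        G = grm_linear(micro_panel)
        expect = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        np.testing.assert_allclose(G.entries, expect)

    def test_duplicated_line_shares_diagonal(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, size=(10, 60)).astype(float)
        codes[3] = codes[0]
        G = grm_linear(panel_from(codes))
        assert G.entries[0, 3] == pytest.approx(G.entries[0, 0])

    def test_invariant_to_marker_and_line_order(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, size=(12, 80)).astype(float)
        ids = [f"l{i}" for i in range(12)]
        G = grm_linear(panel_from(codes, ids))
        perm_m = rng.permutation(80)
        G2 = grm_linear(panel_from(codes[:, perm_m], ids))
        np.testing.assert_allclose(G.entries, G2.entries, atol=1e-10)
        perm_l = rng.permutation(12)
        G3 = grm_linear(panel_from(codes[perm_l], [ids[i] for i in perm_l]))
        np.testing.assert_allclose(G.entries[np.ix_(perm_l, perm_l)], G3.entries, atol=1e-10)

    def test_all_monomorphic_errors(self):
        with pytest.warns(MkgpWarning):
            with pytest.raises(ValueError, match="monomorphic"):
                grm_linear(panel_from([[0, 2], [0, 2], [0, 2]]))


class TestEpistasis:
    def test_hand_example(self, micro_panel):
        E = epistasis_kernel(grm_linear(micro_panel))
        expect = np.array([[4.0, 0.0, 4.0], [0.0, 0.0, 0.0], [4.0, 0.0, 4.0]])
        np.testing.assert_allclose(E.entries, expect)
        assert E.kind == "EPI"

    def test_identity_fixed_point(self):
        K = KernelMatrix(np.eye(4), np.arange(4), "G")
        np.testing.assert_allclose(epistasis_kernel(K).entries, np.eye(4))

    @pytest.mark.parametrize("seed", range(4))
    def test_hadamard_square_of_psd_is_psd(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((15, 8))
        K = KernelMatrix(A @ A.T, np.arange(15), "G")
        E = epistasis_kernel(K)
        w = np.linalg.eigvalsh(E.entries)
        assert w.min() >= -1e-8 * w.max()


class TestDominance:
    def test_recoding_homozygotes_one_heterozygote_zero(self, micro_panel):
        # codes [0,1,2] -> dominance design [1,0,1]: the two homozygous
        # lines end up identical and maximally related
        A = dominance_kernel(micro_panel)
        assert A.entries[0, 2] == pytest.approx(A.entries[0, 0])
        assert A.entries[0, 1] < A.entries[0, 0]
        assert A.mean_diag() == pytest.approx(1.0)

    def test_identical_heterozygosity_patterns_maximal(self):
        codes = [[1, 0, 1], [1, 0, 1], [0, 2, 2]]
        A = dominance_kernel(panel_from(codes))
        assert A.entries[0, 1] == pytest.approx(max(A.entries[0]))

    def test_fully_inbred_panel_errors(self):
        with pytest.raises(ValueError, match="heterozygous"):
            dominance_kernel(panel_from([[0, 2], [2, 0], [2, 2]]))


class TestTranscriptome:
    def test_identical_profiles_share_diagonal(self):
        rng = np.random.default_rng(3)
        ab = rng.standard_normal((6, 30))
        ab[2] = ab[0]
        T = transcriptome_kernel(ab, [f"l{i}" for i in range(6)])
        assert T.entries[0, 2] == pytest.approx(T.entries[0, 0])
        assert T.mean_diag() == pytest.approx(1.0)

    def test_matches_grm_when_abundances_are_markers(self):
        # feeding standardised marker dosages reproduces the correlation-scaled GRM
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 3, size=(20, 150)).astype(float)
        panel = panel_from(codes)
        W, _ = center_genotypes(panel)
        Z = W / W.std(axis=0)
        T = transcriptome_kernel(codes, panel.line_ids)
        np.testing.assert_allclose(T.entries, (Z @ Z.T) / Z.shape[1], atol=1e-10)

    def test_single_gene_rank_one(self):
        T = transcriptome_kernel(np.array([[-1.0], [0.0], [1.0]]), ["a", "b", "c"])
        w = np.linalg.eigvalsh(T.entries)
        assert np.sum(w > 1e-10) == 1

    def test_all_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            transcriptome_kernel(np.ones((4, 3)), list("abcd"))


class TestGaussian:
    def test_hand_example_d2_25(self):
        K = gaussian_kernel(np.array([[0.0, 0.0], [3.0, 4.0]]), h=25.0)
        assert K.entries[0, 1] == pytest.approx(np.exp(-1.0))
        np.testing.assert_allclose(np.diag(K.entries), 1.0)

    def test_large_bandwidth_limit(self):
        X = np.random.default_rng(5).standard_normal((6, 4))
        K = gaussian_kernel(X, h=1e12)
        np.testing.assert_allclose(K.entries, 1.0, atol=1e-9)

    def test_monotone_in_distance_and_bandwidth(self):
        X = np.array([[0.0], [1.0], [3.0]])
        K = gaussian_kernel(X, h=2.0)
        assert K.entries[0, 1] > K.entries[0, 2]
        K2 = gaussian_kernel(X, h=4.0)
        assert (K2.entries >= K.entries - 1e-12).all()

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.zeros((3, 2)), h=0.0)

    def test_median_heuristic_positive(self):
        X = np.random.default_rng(6).standard_normal((10, 5))
        assert median_bandwidth(X) > 0


class TestIncidence:
    def test_printed_3x10_worked_example(self):
        # 10 observations: 5 from line 1, 3 from line 2, 2 from line 3
        obs = [f"o{i}" for i in range(10)]
        line_of = {o: ("L1" if i < 5 else "L2" if i < 8 else "L3") for i, o in enumerate(obs)}
        Z = incidence_matrix(obs, line_of, ["L1", "L2", "L3"])
        expect_T = np.array(
            [
                [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
                [0, 0, 0, 0, 0, 1, 1, 1, 0, 0],
                [0, 0, 0, 0, 0, 0, 0, 0, 1, 1],
            ],
            dtype=float,
        )
        np.testing.assert_array_equal(Z.entries.T, expect_T)
        assert Z.entries.sum() == 10
        np.testing.assert_array_equal(Z.replicate_counts, [5, 3, 2])

    def test_one_obs_per_line_is_identity(self):
        Z = incidence_matrix(["a", "b"], {"a": "a", "b": "b"}, ["a", "b"])
        np.testing.assert_array_equal(Z.entries, np.eye(2))

    def test_unmapped_observation_named_in_error(self):
        with pytest.raises(KeyError, match="o1"):
            incidence_matrix(["o0", "o1"], {"o0": "L"}, ["L"])


class TestGxE:
    @staticmethod
    def _setup(n_lines=4, n_envs=2, seed=0):
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 3, size=(n_lines, 50)).astype(float)
        panel = panel_from(codes)
        G = grm_linear(panel)
        obs, line_of, env_of = [], {}, {}
        for e in range(n_envs):
            for l in panel.line_ids:
                o = f"{l}@e{e}"
                obs.append(o)
                line_of[o], env_of[o] = l, f"e{e}"
        Zg = incidence_matrix(obs, line_of, list(panel.line_ids))
        Ze = incidence_matrix(obs, env_of, [f"e{e}" for e in range(n_envs)])
        return G, Zg, Ze

    def test_block_diagonal_structure(self):
        G, Zg, Ze = self._setup()
        K = gxe_block_kernel(G, Zg, Ze)
        n = G.n
        np.testing.assert_allclose(K.entries[:n, :n], G.entries)
        np.testing.assert_allclose(K.entries[n:, n:], G.entries)
        np.testing.assert_allclose(K.entries[:n, n:], 0.0)

    def test_single_environment_reduces_to_expanded_grm(self):
        G, Zg, Ze = self._setup(n_envs=1)
        K = gxe_block_kernel(G, Zg, Ze)
        np.testing.assert_allclose(K.entries, Zg.entries @ G.entries @ Zg.entries.T)

    def test_ordering_mismatch_rejected(self):
        G, Zg, Ze = self._setup()
        from mkgp.kernels import IncidenceMatrix

        Ze_bad = IncidenceMatrix(Ze.entries, Ze.row_ids[::-1].copy(), Ze.col_ids)
        with pytest.raises(ValueError, match="observation"):
            gxe_block_kernel(G, Zg, Ze_bad)


class TestKernelMatrix:
    def test_asymmetric_rejected(self):
        M = np.array([[1.0, 0.5], [0.1, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            KernelMatrix(M, ["a", "b"], "G")

    def test_repair_clips_float_noise(self):
        w = np.array([1.0, 0.5, -1e-12])
        U = np.linalg.qr(np.random.default_rng(7).standard_normal((3, 3)))[0]
        K = KernelMatrix((U * w) @ U.T, list("abc"), "G")
        with pytest.warns(MkgpWarning, match="PSD_REPAIR"):
            R = K.repaired()
        assert np.linalg.eigvalsh(R.entries).min() >= -1e-15

    def test_materially_negative_not_repaired(self):
        M = np.diag([1.0, -0.5])
        K = KernelMatrix(M, ["a", "b"], "G")
        with pytest.raises(ValueError):
            K.repaired()
        with pytest.raises(ValueError, match="not PSD"):
            K.validate_psd()
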