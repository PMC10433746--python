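"""O2PLS decomposition against its SVD oracle and structural invariants."""

import numpy as np
import pandas as pd
import pytest

import triomics as tm


def _random_blocks(rng, n=6, p=20, q=15):
    return rng.normal(size=(n, p)), rng.normal(size=(n, q))


def _leading_svd(X, Y):
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
    return U[:, 0], Vt[0]


class TestFitAgainstSvdOracle:
    def test_self_paired_block_recovers_principal_axis(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 10))
        model = tm.fit_o2pls(X, X, n_joint=1)
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        v = Vt[0]
        w = model.W.to_numpy()[:, 0]
        c = model.C.to_numpy()[:, 0]
        assert abs(np.dot(w, v)) == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(w, c, atol=1e-10)
        rho = np.corrcoef(model.T[:, 0], model.U[:, 0])[0, 1]
        assert rho == pytest.approx(1.0, abs=1e-10)

    def test_loadings_match_cross_covariance_svd(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            X, Y = _random_blocks(rng)
            model = tm.fit_o2pls(X, Y, n_joint=1)
            w_ref, c_ref = _leading_svd(X, Y)
            assert abs(np.dot(model.W.to_numpy()[:, 0], w_ref)) > 1 - 1e-8
            assert abs(np.dot(model.C.to_numpy()[:, 0], c_ref)) > 1 - 1e-8

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(5)
        X, Y = _random_blocks(rng)
        m1 = tm.fit_o2pls(X, Y, n_joint=2)
        m2 = tm.fit_o2pls(X, Y, n_joint=2)
        pd.testing.assert_frame_equal(m1.W, m2.W)
        for j in range(2):
            col = m1.W.to_numpy()[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_joint_columns_unit_norm_and_orthogonal(self):
        rng = np.random.default_rng(7)
        X, Y = _random_blocks(rng, n=8)
        m = tm.fit_o2pls(X, Y, n_joint=2)
        W = m.W.to_numpy()
        assert np.allclose(W.T @ W, np.eye(2), atol=1e-10)
        C = m.C.to_numpy()
        assert np.allclose(C.T @ C, np.eye(2), atol=1e-10)

    def test_fit_invariant_to_joint_sample_reordering(self):
        rng = np.random.default_rng(9)
        X, Y = _random_blocks(rng)
        perm = rng.permutation(6)
        m1 = tm.fit_o2pls(X, Y, n_joint=1)
        m2 = tm.fit_o2pls(X[perm], Y[perm], n_joint=1)
        assert np.allclose(m1.W.to_numpy(), m2.W.to_numpy(), atol=1e-10)
        assert np.allclose(m1.C.to_numpy(), m2.C.to_numpy(), atol=1e-10)

    def test_orthogonal_scores_decoupled_from_joint_structure(self):
        rng = np.random.default_rng(21)
        X, Y = _random_blocks(rng, n=8, p=12, q=9)
        m = tm.fit_o2pls(X, Y, n_joint=1, n_orth_x=1, n_orth_y=1)
        # orthogonal scores have zero covariance with the opposite block's
        # joint scores at extraction (recorded diagnostic) ...
        assert max(m.metadata["orth_cross_joint_cov"]) < 1e-8
        # ... and are exactly orthogonal to their own block's refit joint
        # scores (deflation removes them from the block's column space)
        assert abs(m.T_orth[:, 0] @ m.T[:, 0]) < 1e-8 * np.linalg.norm(
            m.T_orth[:, 0]) * np.linalg.norm(m.T[:, 0])
        assert abs(m.U_orth[:, 0] @ m.U[:, 0]) < 1e-8 * np.linalg.norm(
            m.U_orth[:, 0]) * np.linalg.norm(m.U[:, 0])

    def test_errors_on_bad_shapes_and_ranks(self):
        rng = np.random.default_rng(0)
        X, Y = _random_blocks(rng)
        with pytest.raises(tm.AlignmentError):
            tm.fit_o2pls(X[:5], Y)
        with pytest.raises(tm.RankError):
            tm.fit_o2pls(X, Y, n_joint=6)
        with pytest.raises(tm.DomainError):
            tm.fit_o2pls(np.zeros((6, 4)), Y)


class TestTopJointLoadings:
    def test_k_beyond_feature_count_returns_full_ranking(self):
        rng = np.random.default_rng(2)
        X, Y = _random_blocks(rng, p=7, q=5)
        top = tm.top_joint_loadings(tm.fit_o2pls(X, Y), k=100)
        assert len(top["genes"]) == 7
        assert len(top["proteins"]) == 5
        assert top["genes"]["abs_loading"].is_monotonic_decreasing

    def test_k1_selects_strongest_feature_of_self_paired_block(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 10))
        model = tm.fit_o2pls(X, X)
        top = tm.top_joint_loadings(model, k=1)
        best = model.W.iloc[:, 0].abs().idxmax()
        assert top["genes"]["feature"].iloc[0] == best

    def test_latent_pairs_dominate_loadings_across_seeds(self):
        # with no planted group effect the shared latent factor is the only
        # cross-omics structure, so the strongest joint loading must sit on
        # a planted-pair feature in (nearly) every replicate
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = tm.SimConfig(seed=seed, gene_effect_log2=0.0,
                               protein_effect_log2=0.0)
            res = tm.generate_paired_omics(cfg)
            model = tm.fit_o2pls(res.genes.log2().T, res.proteins.log2().T)
            pair_genes = {g for g, _, _ in res.truth.planted_pairs}
            pair_prots = {p for _, p, _ in res.truth.planted_pairs}
            top_g = model.W.iloc[:, 0].abs().idxmax()
            top_p = model.C.iloc[:, 0].abs().idxmax()
            hits += (top_g in pair_genes) and (top_p in pair_prots)
        assert hits >= 0.9 * n_seeds

    def test_candidate_in_both_top25_on_default_fixture(self, default_sim):
        res = default_sim
        model = tm.fit_o2pls(res.genes.log2().T, res.proteins.log2().T)
        top = tm.top_joint_loadings(model, k=25)
        cand = res.truth.consensus_candidate
        cand_prot = res.id_map.proteins_for(cand)[0]
        assert cand in set(top["genes"]["feature"])
        assert cand_prot in set(top["proteins"]["feature"])


class TestVarianceExplained:
    def test_full_rank_self_pair_explains_everything(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(6, 4))  # centered rank 4 (>n_joint)
        m = tm.fit_o2pls(X, X, n_joint=4)
        ve = tm.variance_explained(m, X, X)
        assert ve.loc["genes", "r2_joint"] == pytest.approx(1.0, abs=1e-8)

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(13)
        for n_orth in (0, 1):
            X, Y = _random_blocks(rng, n=8)
            m = tm.fit_o2pls(X, Y, n_joint=1, n_orth_x=n_orth, n_orth_y=n_orth)
            ve = tm.variance_explained(m, X, Y)
            assert np.allclose(ve.sum(axis=1), 1.0, atol=1e-8)
            assert ((ve >= -1e-12) & (ve <= 1 + 1e-12)).all().all()

    def test_variance_free_block_rejected(self):
        rng = np.random.default_rng(1)
        X, Y = _random_blocks(rng)
        m = tm.fit_o2pls(X, Y)
        flat = np.tile(m.x_mean.to_numpy(), (6, 1))  # centers to all-zero
        with pytest.raises(tm.DomainError):
            tm.variance_explained(m, flat, Y)
        with pytest.raises(tm.DomainError):  # and at fit time too
            tm.fit_o2pls(np.zeros_like(X), Y)


class TestJointScoresBeatRawPairs:
    def test_joint_correlation_at_least_best_feature_pair(self):
        # on a latent-driven fixture the joint scores pool many noisy copies
        # of the latent factor, so their cross-block correlation must beat
        # any single gene-protein pair
        for seed in range(5):
            cfg = tm.SimConfig(seed=seed, n_genes=20, n_proteins=15,
                               n_shared_ids=15, n_de_genes=2, n_de_proteins=2,
                               gene_effect_log2=0.0, protein_effect_log2=0.0,
                               n_planted_pairs=8, pathway_size=6,
                               n_per_group=25)
            res = tm.generate_paired_omics(cfg)
            X = res.genes.log2().T.to_numpy()
            Y = res.proteins.log2().T.to_numpy()
            m = tm.fit_o2pls(X, Y)
            joint = abs(np.corrcoef(m.T[:, 0], m.U[:, 0])[0, 1])
            best = max(
                abs(np.corrcoef(X[:, i], Y[:, j])[0, 1])
                for i in range(X.shape[1]) for j in range(Y.shape[1]))
            assert joint >= best - 1e-9, seed
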