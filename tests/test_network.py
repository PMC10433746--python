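"""Bipartite Pearson network construction and phenotype correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triomics as tm


def _em(rows: dict, samples=None) -> tm.ExpressionMatrix:
    samples = samples or ["f1", "f2", "f3", "p1", "p2", "p3"]
    groups = {s: ("FS" if s.startswith("f") else "PS") for s in samples}
    return tm.ExpressionMatrix(pd.DataFrame(rows, index=samples).T,
                               pd.Series(groups))


class TestPearson:
    def test_exact_linearity(self):
        rho, p = tm.pearson([1, 2, 3], [2, 4, 6])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_exact_antilinearity(self):
        rho, _ = tm.pearson([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_instance(self):
        # covariance sum 15.5 against variance sums 17.5 each
        rho, _ = tm.pearson([1, 2, 3, 4, 5, 6], [1, 3, 2, 5, 4, 6])
        assert rho == pytest.approx(15.5 / 17.5)

    def test_symmetric(self):
        x = [0.3, 1.7, 2.2, 0.9, 3.4]
        y = [1.1, 0.2, 2.8, 2.0, 0.7]
        assert tm.pearson(x, y) == tm.pearson(y, x)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(tm.DomainError):
            tm.pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(tm.DomainError):
            tm.pearson([1, 2], [1, 2])


class TestBuildNetwork:
    def test_planted_pairs_form_edges(self):
        # more samples per group than the default design for a sharp check:
        # empirical rho concentrates near the 0.95 target
        res = tm.generate_paired_omics(tm.SimConfig(seed=2, n_per_group=10))
        pair_genes = [g for g, _, _ in res.truth.planted_pairs]
        pair_prots = [p for _, p, _ in res.truth.planted_pairs]
        net = tm.build_network(res.genes.subset(pair_genes),
                               res.proteins.subset(pair_prots))
        found = set(zip(net.edges["gene"], net.edges["protein"]))
        planted = set(zip(pair_genes, pair_prots))
        assert len(planted & found) >= 9  # of the 10 planted pairs

    def test_null_edge_rate_matches_theory(self):
        # independent features at n=6: the gate reduces to the stricter of
        # |rho|>0.8 and the p<.05 critical correlation (0.811), so the
        # expected edge rate is the closed-form tail probability
        rng = np.random.default_rng(8)
        samples = ["f1", "f2", "f3", "p1", "p2", "p3"]
        G = _em({f"g{i}": rng.lognormal(3, 1, 6) for i in range(200)}, samples)
        P = _em({f"p{i}": rng.lognormal(3, 1, 6) for i in range(50)}, samples)
        net = tm.build_network(G, P)
        t_crit = stats.t.ppf(0.975, 4)
        r_crit = max(0.8, t_crit / np.sqrt(t_crit**2 + 4))
        expected = 2 * stats.t.sf(r_crit * np.sqrt(4 / (1 - r_crit**2)), 4)
        rate = len(net.edges) / (200 * 50)
        assert rate == pytest.approx(expected, abs=0.015)

    def test_collinearity_only_at_threshold_one(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        G = _em({"g_exact": base, "g_noisy": [1, 2.1, 2.9, 4.2, 4.8, 6.1]})
        P = _em({"prot": [2 * v for v in base]})
        net = tm.build_network(G, P, rho_threshold=1.0, log_scale=False)
        assert net.edges.empty  # strict > 1.0 excludes even exact collinearity

    def test_tightening_gates_never_adds_edges(self):
        res = tm.generate_paired_omics(tm.SimConfig(seed=4))
        pair_genes = [g for g, _, _ in res.truth.planted_pairs]
        pair_prots = [p for _, p, _ in res.truth.planted_pairs]
        g, p = res.genes.subset(pair_genes), res.proteins.subset(pair_prots)
        loose = tm.build_network(g, p, rho_threshold=0.7, alpha=0.1)
        tight_rho = tm.build_network(g, p, rho_threshold=0.9, alpha=0.1)
        tight_alpha = tm.build_network(g, p, rho_threshold=0.7, alpha=0.01)
        def keys(net):
            return set(zip(net.edges["gene"], net.edges["protein"]))
        assert keys(tight_rho) <= keys(loose)
        assert keys(tight_alpha) <= keys(loose)

    def test_edges_invariant_under_joint_sample_permutation(self):
        res = tm.generate_paired_omics(tm.SimConfig(seed=6, n_per_group=5))
        pair_genes = [g for g, _, _ in res.truth.planted_pairs]
        pair_prots = [p for _, p, _ in res.truth.planted_pairs]
        g, p = res.genes.subset(pair_genes), res.proteins.subset(pair_prots)
        order = list(np.random.default_rng(0).permutation(g.sample_ids))
        g2 = tm.ExpressionMatrix(g.data[order], g.groups)
        p2 = tm.ExpressionMatrix(p.data[order], p.groups)
        e1 = tm.build_network(g, p).edges
        e2 = tm.build_network(g2, p2).edges
        pd.testing.assert_frame_equal(e1, e2, atol=1e-12)

    def test_sample_mismatch_is_alignment_error(self):
        g = _em({"g": [1, 2, 3, 4, 5, 6]})
        p = _em({"p": [1, 2, 3, 4, 5, 6]},
                ["f1", "f2", "f3", "p1", "p2", "px"])
        with pytest.raises(tm.AlignmentError):
            tm.build_network(g, p)

    def test_zero_variance_features_dropped_with_reason(self):
        g = _em({"flat": [2, 2, 2, 2, 2, 2], "ok": [1, 2, 3, 4, 5, 6]})
        p = _em({"prot": [2, 4, 6, 8, 10, 12]})
        net = tm.build_network(g, p, log_scale=False)
        assert ("flat", "*", "zero variance gene") in net.dropped
        assert set(net.edges["gene"]) == {"ok"}


class TestDegreeRanking:
    def test_empty_network_gives_empty_ranking(self):
        g = _em({"g": [1, 5, 3, 2, 6, 4]})
        p = _em({"p": [6, 1, 4, 5, 2, 3]})
        net = tm.build_network(g, p, rho_threshold=0.99, log_scale=False)
        assert tm.degree_ranking(net).empty

    def test_orders_by_degree_then_name(self):
        edges = pd.DataFrame({"gene": ["gA", "gA", "gA", "gB"],
                              "protein": ["p1", "p2", "p3", "p1"],
                              "rho": [0.9] * 4, "p": [0.01] * 4})
        net = tm.BipartiteNetwork(["gA", "gB"], ["p1", "p2", "p3"], edges)
        ranked = tm.degree_ranking(net, top_n=5)
        assert list(ranked["gene"]) == ["gA", "gB"]
        assert list(ranked["degree"]) == [3, 1]

    def test_planted_hub_ranks_first(self):
        # hub gene tracks five proteins exactly; decoy gene tracks one
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        other = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        G = _em({"hub": base, "loner": other})
        P = _em({f"hp{i}": base * (i + 1) for i in range(5)} | {"lp": other})
        ranked = tm.degree_ranking(tm.build_network(G, P, log_scale=False))
        assert ranked["gene"].iloc[0] == "hub"
        assert ranked["degree"].iloc[0] >= 5


class TestPhenotypeCorrelation:
    def test_exact_linear_phenotype(self):
        x = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
        rho, p = tm.phenotype_correlation(x, 3 * x + 2)
        assert rho == pytest.approx(1.0)

    def test_candidate_tracks_motility_across_seeds(self):
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = tm.SimConfig(seed=seed)
            res = tm.generate_paired_omics(cfg)
            cand = res.truth.consensus_candidate
            abundance = np.log2(res.genes.data.loc[cand])
            rho, _ = tm.phenotype_correlation(
                abundance, res.phenotype.column("motility"))
            ok += rho > 0.9
        assert ok >= 0.9 * n_seeds

    def test_shuffled_pairing_decorrelates(self):
        res = tm.generate_paired_omics(tm.SimConfig(seed=9))
        cand = res.truth.consensus_candidate
        x = np.log2(res.genes.data.loc[cand]).to_numpy()
        y = res.phenotype.column("motility").to_numpy()
        rng = np.random.default_rng(0)
        rhos = [tm.pearson(x, rng.permutation(y))[0] for _ in range(200)]
        assert abs(np.mean(rhos)) < 0.15

    def test_too_few_shared_samples_rejected(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(tm.DomainError):
            tm.phenotype_correlation(x, x * 2)
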