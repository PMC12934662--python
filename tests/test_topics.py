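import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from amgrn.core import CountMatrix
from amgrn import topics
from amgrn.topics import (
    TopicLFC,
    _nmf_em,
    annotate_populations,
    fit_topic_model,
    gom_lfc,
    hypergeometric_enrichment,
    pseudobulk,
    top_genes,
)


def _cm(X, genes=None, cells=None, meta=None):
    X = np.asarray(X)
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    cells = cells or [f"c{j}" for j in range(X.shape[1])]
    return CountMatrix(sp.csr_matrix(X), genes, cells, meta)


class TestFitTopicModel:
    def test_rank_one_matrix_recovered_exactly(self):
        a = np.array([4.0, 1.0, 2.0, 8.0, 3.0, 2.0])
        b = np.array([10.0, 30.0, 40.0, 20.0])
        X = np.outer(b, a)  # genes x cells
        fit = fit_topic_model(_cm(X), K=1, n_iter_main=60, n_iter_refine=60, seed=0)
        F = fit.F.iloc[:, 0].to_numpy()
        assert np.allclose(F, b / b.sum(), atol=1e-6)
        assert np.allclose(fit.L.to_numpy(), 1.0)

    def test_loglik_trace_non_decreasing(self, small_counts):
        fit = fit_topic_model(small_counts, K=3, n_iter_main=30,
                              n_iter_refine=30, seed=1, n_starts=2)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-6).all()

    def test_two_disjoint_blocks_recovered_against_long_run_oracle(self):
        # genes 0-2 active only in cells 0-1, genes 3-5 only in cells 2-3
        X = np.array([
            [9, 7, 0, 0],
            [3, 5, 0, 0],
            [6, 6, 0, 0],
            [0, 0, 8, 6],
            [0, 0, 2, 4],
            [0, 0, 5, 5],
        ], dtype=float)
        cm = _cm(X)
        fit = fit_topic_model(cm, K=2, n_iter_main=200, n_iter_refine=200, seed=0)
        truth = np.stack([
            X[:, :2].sum(axis=1) / X[:, :2].sum(),
            X[:, 2:].sum(axis=1) / X[:, 2:].sum(),
        ], axis=1)
        F = fit.F.to_numpy()
        sims = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                sims[i, j] = truth[:, i] @ F[:, j] / (
                    np.linalg.norm(truth[:, i]) * np.linalg.norm(F[:, j]))
        best = max(sims[0, 0] + sims[1, 1], sims[0, 1] + sims[1, 0]) / 2
        assert best >= 0.99
        # independent long-run multiplicative-update oracle from a fresh start
        rng = np.random.default_rng(42)
        W = rng.uniform(0.5, 1.5, (4, 2))
        H = rng.uniform(0.5, 1.5, (2, 6))
        _, H, _ = _nmf_em(X.T, W, H, 3000, 1e-12)
        Fo = (H / H.sum(axis=1, keepdims=True)).T
        tn = truth / np.linalg.norm(truth, axis=0, keepdims=True)
        fn = Fo / np.linalg.norm(Fo, axis=0, keepdims=True)
        sims_o = tn.T @ fn
        assert max(sims_o[0, 0] + sims_o[1, 1], sims_o[0, 1] + sims_o[1, 0]) / 2 > 0.98

    def test_zero_count_gene_keeps_zero_mass(self):
        X = np.array([[5, 3], [0, 0], [2, 4]], dtype=float)
        fit = fit_topic_model(_cm(X), K=1, n_iter_main=30, n_iter_refine=10, seed=0)
        assert fit.F.iloc[1, 0] == 0.0

    def test_invalid_k_rejected(self, small_counts):
        with pytest.raises(ValueError):
            fit_topic_model(small_counts, K=0)
        with pytest.raises(ValueError):
            fit_topic_model(_cm(np.ones((3, 2))), K=5, n_iter_main=1, n_iter_refine=1)

    def test_stochasticity_of_L_and_F(self, small_counts):
        fit = fit_topic_model(small_counts, K=2, n_iter_main=20,
                              n_iter_refine=10, seed=0, n_starts=1)
        assert np.allclose(fit.L.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(fit.F.sum(axis=0), 1.0, atol=1e-8)


class TestGomLfc:
    def _fit(self, F, L):
        genes = [f"g{i}" for i in range(F.shape[0])]
        cells = [f"c{i}" for i in range(L.shape[0])]
        return topics.TopicModelFit(
            L=pd.DataFrame(L, index=cells, columns=["k1", "k2"][: L.shape[1]]),
            F=pd.DataFrame(F, index=genes, columns=["k1", "k2"][: F.shape[1]]),
            loglik_trace=np.array([0.0]),
            seed=0,
        )

    def test_identical_topics_give_zero_lfc(self):
        F = np.tile(np.array([[0.5, 0.3, 0.2]]).T, (1, 2))
        L = np.array([[0.4, 0.6], [0.7, 0.3]])
        lfc = gom_lfc(self._fit(F, L))
        assert np.allclose(lfc.lfc.to_numpy(), 0.0, atol=1e-9)

    def test_double_baseline_gives_lfc_one(self):
        # gene0: F = 0.4 in k1, 0.2 in k2 with equal mean loadings ->
        # baseline 0.3; pick values so F_k1 = 2 * baseline for gene1
        F = np.array([[0.6, 0.2], [0.4, 0.8]])
        L = np.array([[0.5, 0.5]])
        lfc = gom_lfc(self._fit(F, L))
        # baselines: 0.4 and 0.6
        assert lfc.lfc.loc["g0", "k1"] == pytest.approx(np.log2(0.6 / 0.4), abs=1e-6)

    def test_hand_computed_table(self):
        """5-gene, 2-topic example checked against a hand spreadsheet."""
        F = np.array([
            [0.10, 0.30],
            [0.20, 0.20],
            [0.40, 0.10],
            [0.05, 0.25],
            [0.25, 0.15],
        ])
        L = np.array([[0.8, 0.2], [0.6, 0.4], [0.7, 0.3]])
        w = L.mean(axis=0)  # (0.7, 0.3)
        lfc = gom_lfc(self._fit(F, L))
        expected = np.log2((F + 1e-8) / ((F @ w)[:, None] + 1e-8))
        assert np.allclose(lfc.lfc.to_numpy(), expected, atol=1e-12)

    def test_all_zero_gene_is_na(self):
        F = np.array([[0.0, 0.0], [1.0, 1.0]])
        L = np.array([[0.5, 0.5]])
        lfc = gom_lfc(self._fit(F, L))
        assert lfc.lfc.loc["g0"].isna().all()
        assert np.isnan(lfc.baseline.loc["g0"])

    def test_topic_out_of_range(self):
        F = np.array([[1.0, 1.0]])
        L = np.array([[0.5, 0.5]])
        with pytest.raises(IndexError):
            gom_lfc(self._fit(F, L), topic=5)


class TestTopGenes:
    def _lfc(self, values, baseline=None, genes=None):
        genes = genes or [f"g{i}" for i in range(len(values))]
        s = pd.DataFrame({"k1": values}, index=pd.Index(genes, name="gene"))
        b = pd.Series(baseline if baseline is not None else np.ones(len(values)),
                      index=s.index)
        return TopicLFC(lfc=s, baseline=b, pseudocount=1e-8)

    def test_truncates_to_gene_count(self):
        out = top_genes(self._lfc([3.0, 1.0, 2.0]), 0, n=100)
        assert out == ["g0", "g2", "g1"]

    def test_tie_break_deterministic(self):
        # equal LFC, tie broken by descending F (= baseline here) then id
        out = top_genes(self._lfc([1.0, 1.0, 1.0], baseline=[1.0, 3.0, 1.0]), 0, n=3)
        assert out == ["g1", "g0", "g2"]
        assert out == top_genes(self._lfc([1.0, 1.0, 1.0],
                                          baseline=[1.0, 3.0, 1.0]), 0, n=3)

    def test_planted_topic_genes_dominate_top_list(self):
        from amgrn import syndata
        from amgrn.evaluate import match_topics

        cfg = syndata.SyntheticConfig(n_cells_per_population=500, seed=7)
        truth = syndata.generate_ground_truth(cfg)
        cm = syndata.simulate_counts(truth, cfg)
        fit = fit_topic_model(cm, K=3, n_iter_main=150, n_iter_refine=150, seed=0)
        mapping, _ = match_topics(truth.topic_gene_dists, fit.F)
        lfc = gom_lfc(fit)
        top = top_genes(lfc, mapping["homeostasis"], n=50)
        planted = set(truth.topic_signature_genes["homeostasis"])
        assert np.mean([g in planted for g in top]) >= 0.8


class TestEnrichment:
    def test_closed_form_extreme(self):
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}
        table = hypergeometric_enrichment(query, {"s": set(query)}, universe)
        from math import comb

        assert table.loc[0, "p_value"] == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_disjoint_set_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        table = hypergeometric_enrichment(
            {"g0", "g1"}, {"s": {"g10", "g11"}}, universe)
        assert table.loc[0, "overlap"] == 0
        assert table.loc[0, "p_value"] == 1.0

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"x"}, {"s": {"g1"}}, {"g1", "g2"})
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {"s": set()}, set())

    def test_null_p_values_uniform(self):
        """Random query sets give uniform enrichment p-values (KS test)."""
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        gene_set = {f"g{i}" for i in range(40)}
        ps = []
        for _ in range(1000):
            query = set(rng.choice(universe, size=30, replace=False))
            t = hypergeometric_enrichment(query, {"s": gene_set}, set(universe))
            # randomized p-value to de-discretize the hypergeometric tail
            k = t.loc[0, "overlap"]
            M, n, N = 200, 40, 30
            p_ge = stats.hypergeom.sf(k - 1, M, n, N)
            p_gt = stats.hypergeom.sf(k, M, n, N)
            ps.append(p_gt + rng.uniform() * (p_ge - p_gt))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bh_adjustment_bounded_and_monotone(self):
        universe = {f"g{i}" for i in range(50)}
        sets = {f"s{i}": set(np.random.default_rng(i).choice(sorted(universe), 10,
                                                             replace=False))
                for i in range(5)}
        t = hypergeometric_enrichment({"g0", "g1", "g2"}, sets, universe)
        assert ((t["p_adjusted"] >= t["p_value"] - 1e-12)
                & (t["p_adjusted"] <= 1.0)).all()


class TestAnnotatePopulations:
    def test_recovers_planted_populations(self, small_counts, small_truth):
        labels = annotate_populations(
            small_counts,
            marker_sets={
                "resident-like": small_truth.marker_genes["resident-like"],
                "recruited-like": small_truth.marker_genes["recruited-like"],
            },
            k_clusters=2,
            seed=0,
        )
        agreement = (labels.loc[small_truth.population_labels.index]
                     == small_truth.population_labels).mean()
        assert agreement >= 0.99

    def test_invariant_to_cell_order(self, small_counts, small_truth):
        marker_sets = {
            "resident-like": small_truth.marker_genes["resident-like"],
            "recruited-like": small_truth.marker_genes["recruited-like"],
        }
        labels = annotate_populations(small_counts, marker_sets, k_clusters=2, seed=0)
        rng = np.random.default_rng(1)
        perm = rng.permutation(small_counts.n_cells)
        shuffled = small_counts.subset_cells(
            np.array(small_counts.cell_ids, dtype=object)[perm])
        labels2 = annotate_populations(shuffled, marker_sets, k_clusters=2, seed=0)
        assert (labels.sort_index() == labels2.sort_index()).all()

    def test_missing_marker_genes_named_in_error(self, small_counts):
        with pytest.raises(ValueError, match="NOT_A_GENE"):
            annotate_populations(small_counts,
                                 {"a": ["NOT_A_GENE"], "b": ["TF00"]},
                                 k_clusters=2)

    def test_too_few_cells(self):
        cm = _cm(np.ones((4, 3)))
        with pytest.raises(ValueError):
            annotate_populations(cm, {"a": ["g0"], "b": ["g1"]}, k_clusters=5)


class TestPseudobulk:
    def test_identical_cells_mean_equals_member(self):
        X = np.tile([[4], [2], [6]], (1, 5))
        meta = pd.DataFrame({"population": ["p"] * 5, "timepoint": ["t"] * 5},
                            index=[f"c{j}" for j in range(5)])
        cm = _cm(X, meta=meta)
        pb = pseudobulk(cm, ["population"])
        from amgrn.core import normalize_log1p

        expected = normalize_log1p(cm).iloc[0]
        assert np.allclose(pb.iloc[0].to_numpy(), expected.to_numpy())

    def test_singleton_groups_equal_normalized_rows(self):
        X = np.array([[4, 1], [2, 3], [6, 5]])
        meta = pd.DataFrame({"population": ["a", "b"], "timepoint": ["t", "t"]},
                            index=["c0", "c1"])
        cm = _cm(X, meta=meta)
        pb = pseudobulk(cm, ["population"])
        from amgrn.core import normalize_log1p

        norm = normalize_log1p(cm)
        assert np.allclose(pb.loc["a"].to_numpy(), norm.loc["c0"].to_numpy())
        assert np.allclose(pb.loc["b"].to_numpy(), norm.loc["c1"].to_numpy())

    def test_missing_key_rejected(self, small_counts):
        with pytest.raises(KeyError):
            pseudobulk(small_counts, ["nonsense"])

    def test_planted_population_shift_recovered(self, small_counts, small_truth):
        """Marker genes planted ~6x higher in their own population show a
        clear pseudobulk difference in the right direction."""
        pb = pseudobulk(small_counts, ["population"])
        res_markers = small_truth.marker_genes["resident-like"]
        diff = pb.loc["resident-like", res_markers] - pb.loc["recruited-like", res_markers]
        assert (diff > 0.5).all()
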