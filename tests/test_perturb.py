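import numpy as np
import pandas as pd
import pytest

from amgrn.grn import InferredGRN
from amgrn.perturb import (
    EmbeddingVectorField,
    GridSpec,
    KnockoutShift,
    perturbation_score,
    project_shift,
    simulate_ko,
    smooth_to_grid,
    topic_gradient,
)
from amgrn.topics import TopicModelFit


def _grn(edges, genes):
    df = pd.DataFrame(edges, columns=["regulator", "target", "coef"])
    df["coef_std"] = df["coef"]
    df["se"] = 0.0
    df["sign_stability"] = 1.0
    df["retained"] = True
    return InferredGRN(context="toy", edges=df, fitted_genes=genes)


def _imputed(values, genes):
    values = np.atleast_2d(values)
    return pd.DataFrame(values, columns=genes,
                        index=[f"c{i}" for i in range(values.shape[0])])


class TestSimulateKo:
    def test_tf_without_targets_only_moves_itself(self):
        genes = ["tf", "g1"]
        imp = _imputed([[2.0, 5.0], [1.0, 4.0]], genes)
        shift = simulate_ko(imp, _grn([], genes), "tf")
        assert np.allclose(shift.delta["tf"], [-2.0, -1.0])
        assert np.allclose(shift.delta["g1"], 0.0)

    def test_single_chain_hand_computed(self):
        genes = ["tf", "g1"]
        imp = _imputed([[2.0, 5.0]], genes)
        grn = _grn([("tf", "g1", 0.5)], genes)
        for steps, expected in ((1, -1.0), (2, -1.0), (3, -1.0)):
            shift = simulate_ko(imp, grn, "tf", n_propagation=steps)
            assert shift.delta.loc["c0", "g1"] == pytest.approx(expected)

    def test_two_step_chain_matrix_power(self):
        genes = ["tf", "g1", "g2"]
        imp = _imputed([[2.0, 5.0, 5.0]], genes)
        grn = _grn([("tf", "g1", 0.5), ("g1", "g2", 0.4)], genes)
        shift = simulate_ko(imp, grn, "tf", n_propagation=2)
        assert shift.delta.loc["c0", "g1"] == pytest.approx(-1.0)
        assert shift.delta.loc["c0", "g2"] == pytest.approx(-0.4)

    def test_matches_closed_form_on_dag(self):
        """Oracle equivalence: total shift equals sum_t dX0 W^t on a DAG
        when clamping never activates."""
        rng = np.random.default_rng(0)
        n_genes, n_cells = 12, 7
        genes = [f"g{i}" for i in range(n_genes)]
        # random DAG: edges only from lower to higher index, small weights
        edges = [(genes[i], genes[j], float(rng.normal() * 0.2))
                 for i in range(n_genes) for j in range(i + 1, n_genes)
                 if rng.random() < 0.4]
        # large positive expression so deltas never hit the zero clamp
        X = rng.uniform(50, 100, size=(n_cells, n_genes))
        imp = _imputed(X, genes)
        grn = _grn(edges, genes)
        n_prop = 3
        shift = simulate_ko(imp, grn, "g0", n_propagation=n_prop)
        W = grn.weight_matrix(genes).to_numpy()
        dx0 = np.zeros_like(X)
        dx0[:, 0] = -X[:, 0]
        total = dx0.copy()
        cur = dx0.copy()
        for _ in range(n_prop):
            cur = cur @ W
            total += cur
        total[:, 0] = -X[:, 0]
        assert np.abs(shift.delta.to_numpy() - total).max() < 1e-10

    def test_clamp_keeps_expression_non_negative(self):
        genes = ["tf", "g1"]
        imp = _imputed([[10.0, 0.5]], genes)
        grn = _grn([("tf", "g1", 0.5)], genes)  # raw delta would be -5
        shift = simulate_ko(imp, grn, "tf")
        assert shift.delta.loc["c0", "g1"] == pytest.approx(-0.5)

    def test_unknown_tf_lists_available(self):
        genes = ["tf", "g1"]
        imp = _imputed([[1.0, 1.0]], genes)
        with pytest.raises(ValueError, match="tf"):
            simulate_ko(imp, _grn([("tf", "g1", 0.5)], genes), "nope")


def _toy_geometry(n=40, seed=0):
    """Cells on a line in both expression and embedding space."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n)
    genes = [f"g{i}" for i in range(6)]
    X = np.outer(t, rng.uniform(1, 3, 6)) + rng.normal(0, 0.01, (n, 6)) + 5
    imp = pd.DataFrame(X, columns=genes, index=[f"c{i:03d}" for i in range(n)])
    emb = pd.DataFrame({"x": t * 10, "y": np.zeros(n)}, index=imp.index)
    return imp, emb


class TestProjectShift:
    def test_zero_delta_gives_zero_vectors(self):
        imp, emb = _toy_geometry()
        shift = KnockoutShift("tf", imp * 0.0, 3)
        field = project_shift(shift, imp, emb, k_neighbors=5)
        assert np.allclose(field.vectors.to_numpy(), 0.0)

    def test_delta_toward_neighbor_points_toward_it(self):
        imp, emb = _toy_geometry()
        # delta equal to the expression difference toward higher-t cells
        delta = imp.shift(-1) - imp
        delta.iloc[-1] = 0.0
        shift = KnockoutShift("tf", delta, 3)
        field = project_shift(shift, imp, emb, k_neighbors=4)
        # interior cells should move in +x (toward increasing t)
        assert (field.vectors["dx"].iloc[5:-5] > 0).mean() > 0.9

    def test_constant_delta_warns_and_zeroes(self):
        imp, emb = _toy_geometry()
        shift = KnockoutShift("tf", imp * 0.0 + 1.0, 3)
        with pytest.warns(UserWarning, match="constant"):
            field = project_shift(shift, imp, emb, k_neighbors=4)
        assert np.allclose(field.vectors.to_numpy(), 0.0)

    def test_k_neighbors_validated(self):
        imp, emb = _toy_geometry()
        shift = KnockoutShift("tf", imp * 0.0, 3)
        from amgrn.perturb import ProjectionContext

        with pytest.raises(ValueError):
            ProjectionContext(imp, emb, k_neighbors=1)


class TestTopicGradient:
    def _fit(self, loadings, cells):
        K = loadings.shape[1]
        L = pd.DataFrame(loadings, index=cells,
                         columns=[f"k{k+1}" for k in range(K)])
        F = pd.DataFrame(np.ones((3, K)) / 3, columns=L.columns)
        return TopicModelFit(L=L, F=F, loglik_trace=np.array([0.0]), seed=0)

    def test_constant_loadings_zero_gradient(self):
        rng = np.random.default_rng(0)
        emb = pd.DataFrame(rng.uniform(0, 10, (100, 2)), columns=["x", "y"],
                           index=[f"c{i}" for i in range(100)])
        fit = self._fit(np.full((100, 1), 0.4), emb.index)
        grad = topic_gradient(fit, 0, emb, grid_size=12)
        assert np.allclose(grad.gradients[grad.mask], 0.0, atol=1e-12)

    def test_linear_field_gradient_matches_analytic(self):
        # dense uniform cells: loadings equal to x / 10 have gradient (0.1, 0)
        g = np.linspace(0, 10, 60)
        gx_mesh, gy_mesh = np.meshgrid(g, g)
        emb = pd.DataFrame({"x": gx_mesh.ravel(), "y": gy_mesh.ravel()},
                           index=[f"c{i}" for i in range(3600)])
        fit = self._fit(emb[["x"]].to_numpy() / 10.0, emb.index)
        grad = topic_gradient(fit, 0, emb, grid_size=20, bandwidth=0.3)
        S = 20
        M = grad.mask.reshape(S, S)
        G = grad.gradients.reshape(S, S, 2)
        interior = np.zeros_like(M)
        interior[3:-3, 3:-3] = True
        gx = G[M & interior, 0]
        assert np.abs(gx - 0.1).max() / 0.1 < 0.05
        assert np.abs(G[M & interior, 1]).max() < 0.005

    def test_masked_nodes_zero(self):
        emb = pd.DataFrame({"x": [0.0, 10.0], "y": [0.0, 10.0]},
                           index=["a", "b"])
        fit = self._fit(np.array([[0.2], [0.9]]), emb.index)
        grad = topic_gradient(fit, 0, emb, grid_size=10, bandwidth=0.3)
        assert (~grad.mask).any()
        assert np.allclose(grad.gradients[~grad.mask], 0.0)

    def test_bad_bandwidth(self):
        emb = pd.DataFrame({"x": [0.0, 1.0], "y": [0.0, 1.0]}, index=["a", "b"])
        fit = self._fit(np.array([[0.2], [0.9]]), emb.index)
        with pytest.raises(ValueError):
            topic_gradient(fit, 0, emb, bandwidth=-1.0)


def _field_from(grid, vec, mask, tf="tf"):
    return EmbeddingVectorField(tf=tf, vectors=pd.DataFrame(),
                                grid=grid, grid_vectors=vec, mask=mask)


class TestPerturbationScore:
    def _grad(self, grid, gradients, mask, topic="k1"):
        from amgrn.perturb import TopicGradientField

        return TopicGradientField(topic=topic, grid=grid,
                                  values=np.zeros(len(gradients)),
                                  gradients=gradients, mask=mask)

    def setup_method(self):
        self.grid = GridSpec(0, 1, 0, 1, size=4, bandwidth=0.2)
        rng = np.random.default_rng(0)
        self.g = rng.normal(size=(16, 2))
        self.mask = np.ones(16, dtype=bool)

    def test_self_inner_product_is_mean_squared_magnitude(self):
        score = perturbation_score(_field_from(self.grid, self.g, self.mask),
                                   self._grad(self.grid, self.g, self.mask))
        assert score == pytest.approx((self.g ** 2).sum(axis=1).mean())
        assert score > 0

    def test_orthogonal_fields_score_zero(self):
        perp = np.stack([-self.g[:, 1], self.g[:, 0]], axis=1)
        score = perturbation_score(_field_from(self.grid, perp, self.mask),
                                   self._grad(self.grid, self.g, self.mask))
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_exact(self):
        s1 = perturbation_score(_field_from(self.grid, self.g, self.mask),
                                self._grad(self.grid, self.g, self.mask))
        s2 = perturbation_score(_field_from(self.grid, -self.g, self.mask),
                                self._grad(self.grid, self.g, self.mask))
        assert s2 == -s1

    def test_geometry_mismatch_rejected(self):
        other = GridSpec(0, 2, 0, 1, size=4, bandwidth=0.2)
        with pytest.raises(ValueError, match="geometry"):
            perturbation_score(_field_from(other, self.g, self.mask),
                               self._grad(self.grid, self.g, self.mask))

    def test_disjoint_masks_rejected(self):
        m1 = np.zeros(16, dtype=bool); m1[:8] = True
        m2 = ~m1
        with pytest.raises(ValueError, match="occupied"):
            perturbation_score(_field_from(self.grid, self.g, m1),
                               self._grad(self.grid, self.g, m2))

    def test_score_monotone_in_delta_scale(self):
        """Scaling the perturbation field scales the score linearly."""
        scores = [perturbation_score(
            _field_from(self.grid, c * self.g, self.mask),
            self._grad(self.grid, self.g, self.mask)) for c in (0.5, 1.0, 2.0)]
        assert scores[0] < scores[1] < scores[2]


class TestSmoothToGrid:
    def test_constant_values_preserved(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (50, 2))
        grid = GridSpec(0, 1, 0, 1, size=5, bandwidth=0.3)
        vals, mask = smooth_to_grid(pts, np.full(50, 2.5), grid)
        assert np.allclose(vals[mask], 2.5)

    def test_far_nodes_masked(self):
        pts = np.array([[0.0, 0.0]])
        grid = GridSpec(0, 10, 0, 10, size=6, bandwidth=0.5)
        vals, mask = smooth_to_grid(pts, np.array([1.0]), grid)
        assert mask.sum() == 1
        assert np.allclose(vals[~mask], 0.0)
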