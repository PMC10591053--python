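"""Network forward pass: locality, EdgeConv, branches, invariances."""

import numpy as np
import pytest

from mesograph.autodiff import Tensor
from mesograph.graphs import build_cell_graph
from mesograph.model import (MLPParams, ModelConfig, branch_score,
                             edgeconv_layer, forward, forward_tensors,
                             init_params, local_embed, mlp_apply)


def toy_graph(n=20, d=10, seed=0, radius=30.0, labels=(1, 1)):
    rng = np.random.default_rng(seed)
    return build_cell_graph(rng.normal(size=(n, d)),
                            rng.uniform(0, 80, (n, 2)), radius=radius,
                            core_id="toy", y_s_task=labels[0],
                            y_e_task=labels[1])


def fixed_mlp(d_in, d_hidden, d_out, scale=0.1, seed=0):
    rng = np.random.default_rng(seed)
    return MLPParams(
        w1=Tensor(rng.normal(0, scale, (d_in, d_hidden))),
        b1=Tensor(rng.normal(0, scale, (1, d_hidden))),
        w2=Tensor(rng.normal(0, scale, (d_hidden, d_out))),
        b2=Tensor(rng.normal(0, scale, (1, d_out))),
    )


class TestLocalEmbed:
    def test_identical_inputs_identical_outputs(self):
        mlp = fixed_mlp(4, 5, 3)
        x = np.vstack([np.arange(4.0), np.arange(4.0)])
        h = local_embed(x, mlp).data
        assert np.array_equal(h[0], h[1])

    def test_independent_of_edges(self):
        g = toy_graph(n=6, d=4)
        mlp = fixed_mlp(4, 5, 3)
        h_with = local_embed(g.node_features, mlp).data
        # the local layer never sees the edge list, by construction
        h_without = local_embed(g.node_features[:, :], mlp).data
        assert np.array_equal(h_with, h_without)

    def test_zero_input_follows_bias_path(self):
        mlp = fixed_mlp(3, 2, 2, seed=1)
        h = local_embed(np.zeros((1, 3)), mlp).data
        hidden = np.maximum(0.0, mlp.b1.data)
        expected = hidden @ mlp.w2.data + mlp.b2.data
        assert np.allclose(h, expected)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            local_embed(np.zeros((2, 5)), fixed_mlp(3, 2, 2))


class TestEdgeConvLayer:
    def test_two_node_hand_case(self):
        # scalar reps (2, 5), f(x || y) = x + y:
        # node 0: f(2 || 2-5) = -1; node 1: f(5 || 5-2) = 8
        h = np.array([[2.0], [5.0]])
        edges = np.array([[0, 1]])
        f = lambda pair: pair @ Tensor(np.array([[1.0], [1.0]]))
        out = edgeconv_layer(h, edges, f)
        assert np.allclose(out.data, [[-1.0], [8.0]])

    def test_isolated_node_self_pair(self):
        h = np.array([[3.0], [100.0], [200.0]])
        edges = np.array([[1, 2]])
        f = lambda pair: pair @ Tensor(np.array([[1.0], [1.0]]))
        out = edgeconv_layer(h, edges, f)
        assert out.data[0, 0] == pytest.approx(3.0)  # f(h || 0) = h

    def test_matches_per_node_loop_oracle(self):
        rng = np.random.default_rng(3)
        n, d = 20, 10
        h = rng.normal(size=(n, d))
        g = toy_graph(n=n, d=d, seed=3)
        mlp = fixed_mlp(2 * d, d, d, seed=3)

        def f_np(pair):
            hidden = np.maximum(0.0, pair @ mlp.w1.data + mlp.b1.data)
            return hidden @ mlp.w2.data + mlp.b2.data

        expected = np.zeros((n, d))
        neighbors = {i: [] for i in range(n)}
        for u, v in g.edges:
            neighbors[u].append(v)
            neighbors[v].append(u)
        for v in range(n):
            nbrs = neighbors[v] or [v]
            msgs = []
            for u in nbrs:
                diff = h[v] - h[u]
                msgs.append(f_np(np.concatenate([h[v], diff])[None, :]))
            expected[v] = np.mean(msgs, axis=0)
        out = edgeconv_layer(h, g.edges, mlp)
        assert np.abs(out.data - expected).max() < 1e-6

    def test_edge_index_out_of_range(self):
        with pytest.raises(ValueError):
            edgeconv_layer(np.zeros((2, 1)), np.array([[0, 5]]),
                           fixed_mlp(2, 2, 1))


class TestBranchScore:
    def _parts(self, n=4, jk=6, d0=3):
        rng = np.random.default_rng(0)
        return (Tensor(rng.normal(size=(n, jk))),
                Tensor(rng.normal(size=(1, d0))))

    def test_identity_modulation_at_zero_logit(self):
        jk, xbar = self._parts()
        branch = fixed_mlp(6, 4, 1, scale=0.0)  # all-zero branch output
        alpha = fixed_mlp(3, 2, 1, scale=0.0)
        beta = fixed_mlp(3, 2, 1, scale=0.0)
        z = branch_score(jk, xbar, branch, alpha, beta)
        assert np.allclose(z.data, 0.5)  # sigmoid(alpha*0 + 0)

    def test_vanishing_gain_collapses_to_constant(self):
        jk, xbar = self._parts()
        branch = fixed_mlp(6, 4, 1, seed=2)
        alpha = fixed_mlp(3, 2, 1, scale=0.0)
        alpha.b2.data[:] = -60.0  # softplus(-60) ~ 0: gain vanishes
        beta = fixed_mlp(3, 2, 1, seed=3)
        z = branch_score(jk, xbar, branch, alpha, beta).data
        assert np.allclose(z, z[0])

    def test_gain_is_strictly_positive(self):
        # polarity of the shared cell score is never inverted per core
        jk, xbar = self._parts()
        branch = fixed_mlp(6, 4, 1, seed=2)
        alpha = fixed_mlp(3, 2, 1, scale=0.0)
        alpha.b2.data[:] = -5.0  # raw gain logit very negative
        beta = fixed_mlp(3, 2, 1, scale=0.0)
        z = branch_score(jk, xbar, branch, alpha, beta).data

        def np_mlp(m, x):
            return np.maximum(0, x @ m.w1.data + m.b1.data) @ m.w2.data \
                + m.b2.data

        f = np_mlp(branch, jk.data)
        # cells keep the ranking of the shared branch output
        assert (np.argsort(z.ravel()) == np.argsort(f.ravel())).all()

    def test_hand_computed_sigmoid(self):
        jk, xbar = self._parts()
        branch = fixed_mlp(6, 4, 1, seed=4)
        alpha = fixed_mlp(3, 2, 1, seed=5)
        beta = fixed_mlp(3, 2, 1, seed=6)
        z = branch_score(jk, xbar, branch, alpha, beta).data

        def np_mlp(m, x):
            return np.maximum(0, x @ m.w1.data + m.b1.data) @ m.w2.data \
                + m.b2.data

        a = np.logaddexp(0.0, np_mlp(alpha, xbar.data))  # softplus gain
        b = np_mlp(beta, xbar.data)
        f = np_mlp(branch, jk.data)
        expected = 1.0 / (1.0 + np.exp(-(a * f + b)))
        assert np.abs(z - expected).max() < 1e-12

    def test_scores_strictly_inside_unit_interval(self):
        g = toy_graph(n=15, d=8, seed=1)
        params = init_params(ModelConfig(input_dim=8), seed=1)
        z_s, z_e = forward_tensors(g, params)
        for z in (z_s.data, z_e.data):
            assert (z > 0).all() and (z < 1).all()


class TestForward:
    def test_permutation_equivariance_and_invariance(self):
        g = toy_graph(n=25, d=6, seed=2)
        params = init_params(ModelConfig(input_dim=6), seed=2)
        base = forward(g, params)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(g.n_cells)
            gp = build_cell_graph(g.node_features[perm],
                                  g.centroids[perm], radius=30.0,
                                  core_id="toy", y_s_task=1, y_e_task=1)
            out = forward(gp, params)
            assert np.abs(out.z_s - base.z_s[perm]).max() < 1e-6
            assert abs(out.Z - base.Z) < 1e-6

    def test_scoreset_identity_and_bounds(self):
        g = toy_graph(n=30, d=5, seed=4)
        params = init_params(ModelConfig(input_dim=5), seed=4)
        ss = forward(g, params)
        assert abs(ss.Z - (ss.Z_s - ss.Z_e)) < 1e-6
        assert -1 < ss.Z < 1
        assert np.allclose(ss.cell_score, ss.z_s - ss.z_e)

    def test_single_cell_core(self):
        g = build_cell_graph(np.ones((1, 4)), np.zeros((1, 2)),
                             core_id="solo", y_s_task=0, y_e_task=2)
        params = init_params(ModelConfig(input_dim=4), seed=0)
        ss = forward(g, params)
        assert ss.Z == pytest.approx(float(ss.z_s[0] - ss.z_e[0]))

    def test_jk_width_bookkeeping(self):
        cfg = ModelConfig(input_dim=7)
        assert cfg.jk_dim == 50  # 5 layers x width 10
        params = init_params(cfg, seed=0)
        assert params.branch_s.w1.shape[0] == 50

    def test_schema_mismatch_rejected(self):
        g = toy_graph(n=5, d=6)
        params = init_params(ModelConfig(input_dim=7), seed=0)
        with pytest.raises(ValueError):
            forward(g, params)

    def test_gradients_match_finite_differences(self):
        # 5-node toy graph, full model + dual ranking loss
        from mesograph.training import dual_task_loss
        rng = np.random.default_rng(0)
        n, d = 5, 4
        g = build_cell_graph(rng.normal(size=(n, d)),
                             rng.uniform(0, 50, (n, 2)), radius=30.0,
                             core_id="a", y_s_task=2, y_e_task=0)
        g2 = build_cell_graph(rng.normal(size=(n, d)),
                              rng.uniform(0, 50, (n, 2)), radius=30.0,
                              core_id="b", y_s_task=0, y_e_task=2)
        cfg = ModelConfig(input_dim=d, n_layers=3, layer_dim=4,
                          branch_hidden=5, modulation_hidden=5)
        params = init_params(cfg, seed=1)

        def loss_value():
            zs_a, ze_a = forward_tensors(g, params)
            zs_b, ze_b = forward_tensors(g2, params)
            return dual_task_loss(
                [zs_a.mean(), zs_b.mean()], [ze_a.mean(), ze_b.mean()],
                np.array([2, 0]), np.array([0, 2]))

        loss = loss_value()
        loss.backward()
        eps = 1e-6
        worst = 0.0
        for t in params.tensors():
            grad = t.grad
            it = np.nditer(t.data, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = t.data[idx]
                t.data[idx] = old + eps
                lp = float(loss_value().data)
                t.data[idx] = old - eps
                lm = float(loss_value().data)
                t.data[idx] = old
                fd = (lp - lm) / (2 * eps)
                an = 0.0 if grad is None else grad[idx]
                worst = max(worst, abs(fd - an)
                            / max(1e-8, abs(fd) + abs(an), 1.0))
        assert worst < 1e-4
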