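"""Featurization and network numerics, checked against hand-written oracles.

The numeric oracles below recompute each layer with explicit Python loops,
independent of the vectorized implementation.
"""

import math

import numpy as np
import pytest

import atommap as am
from atommap.features import FeatureConfig, featurize
from atommap.nn.autograd import Tensor, gather_pairs, softmax
from atommap.nn.layers import (
    classifier_scores,
    cross_attention_block,
    init_parameters,
    mpnn_encode,
)


class TestFeaturize:
    def test_methane(self):
        record = am.parse_reaction("C.O>>C")
        rg, pg = featurize(record)
        assert pg.n_atoms == 1
        assert pg.n_directed_bonds == 0

    def test_ethanol(self):
        record = am.parse_reaction("CCO>>CCO")
        rg, _ = featurize(record)
        assert rg.n_atoms == 3
        assert rg.n_directed_bonds == 4  # 2 bonds, both directions

    def test_two_reactants_merged_without_cross_bonds(self):
        record = am.parse_reaction("CC(=O)OC.O>>CC(=O)O")
        rg, _ = featurize(record)
        assert rg.n_atoms == 6  # 5 + 1
        assert rg.n_directed_bonds == 8  # 4 + 0 bonds, doubled
        # no bond touches the water atom (global index 5)
        assert 5 not in set(rg.src) | set(rg.dst)

    def test_unknown_element_uses_unknown_slot(self):
        record = am.parse_reaction("[Se]>>[Se]")
        cfg = FeatureConfig()
        rg, _ = featurize(record, cfg)
        n_el = len(cfg.elements)
        assert rg.atom_features[0, n_el] == 1.0
        assert rg.atom_features[0, :n_el].sum() == 0.0

    def test_feature_dimensions_match_config(self):
        record = am.parse_reaction("c1ccccc1Br>>c1ccccc1I")
        cfg = FeatureConfig()
        rg, pg = featurize(record, cfg)
        assert rg.atom_features.shape[1] == cfg.atom_dim
        assert rg.bond_features.shape[1] == cfg.bond_dim


def tiny_params(rng, atom_dim, bond_dim, d, blocks=1, layers=1):
    return init_parameters(rng, atom_dim, bond_dim, d, layers, blocks)


class TestMpnnOracle:
    def test_two_atom_path_matches_hand_computation(self):
        """One MPNN layer on a 2-atom path with fixed weights."""
        rng = np.random.default_rng(0)
        atom_dim, bond_dim, d = 3, 2, 4
        params = tiny_params(rng, atom_dim, bond_dim, d)
        h = np.array([[0.1, -0.2, 0.3], [0.5, 0.4, -0.1]])
        e = np.array([[1.0, 0.5]])
        src = np.array([0, 1])
        dst = np.array([1, 0])
        bonds = np.vstack([e, e])

        out = mpnn_encode(params, h, src, dst, bonds, mpnn_layers=1).data

        Wm = params["mpnn0_Wmsg"].data
        bm = params["mpnn0_bmsg"].data[0]
        Ws = params["mpnn0_Wself"].data
        bs = params["mpnn0_bself"].data[0]
        expected = np.zeros((2, d))
        for u in range(2):
            own = h[u] @ Ws + bs
            v = 1 - u
            msg = np.concatenate([h[v], e[0]]) @ Wm + bm
            expected[u] = np.maximum(own + msg, 0.0)
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_isolated_atom_independent_of_other_molecules(self):
        cfg = FeatureConfig()
        rec_a = am.parse_reaction("C.O>>C")
        rec_b = am.parse_reaction("C.CCCBr>>C")
        rng = np.random.default_rng(1)
        params = tiny_params(rng, cfg.atom_dim, cfg.bond_dim, 8, layers=3)
        outs = []
        for rec in (rec_a, rec_b):
            rg, _ = featurize(rec, cfg)
            h = mpnn_encode(
                params, rg.atom_features, rg.src, rg.dst, rg.bond_features, 3
            )
            outs.append(h.data[0])  # the lone methane carbon
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-10)

    def test_permutation_equivariance(self):
        cfg = FeatureConfig()
        rng = np.random.default_rng(2)
        params = tiny_params(rng, cfg.atom_dim, cfg.bond_dim, 8, layers=3)
        record = am.parse_reaction("CC(=O)OCC>>CC(=O)O")
        rg, _ = featurize(record, cfg)
        base = mpnn_encode(
            params, rg.atom_features, rg.src, rg.dst, rg.bond_features, 3
        ).data
        for seed in range(5):
            prng = np.random.default_rng(seed)
            perm = prng.permutation(rg.n_atoms)
            inv = np.argsort(perm)
            permuted = mpnn_encode(
                params,
                rg.atom_features[perm],
                inv[rg.src],
                inv[rg.dst],
                rg.bond_features,
                3,
            ).data
            np.testing.assert_allclose(permuted[inv], base, atol=1e-8)


class TestAttentionOracle:
    def test_single_head_on_2x3_toy_matches_hand_computation(self):
        """Full attention block (1 head) on 2 product x 3 reactant atoms."""
        rng = np.random.default_rng(3)
        d = 4
        params = init_parameters(rng, d, 2, d, 1, 1)
        hp = np.array([[0.2, -0.1, 0.4, 0.05], [0.3, 0.2, -0.2, 0.1]])
        hr = np.array(
            [[0.1, 0.1, 0.0, -0.3], [0.5, -0.2, 0.2, 0.2], [0.0, 0.4, -0.1, 0.1]]
        )
        out = cross_attention_block(
            params, 0, Tensor(hp), Tensor(hr), n_heads=1, training=False
        ).data

        def p(name):
            return params[f"att0_{name}"].data

        Q, K, V = hp @ p("Wq"), hr @ p("Wk"), hr @ p("Wv")
        expected = np.zeros_like(hp)
        for u in range(2):
            scores = np.array(
                [Q[u] @ K[v] / math.sqrt(d) for v in range(3)]
            )
            w = np.exp(scores - scores.max())
            w /= w.sum()
            m = sum(w[v] * V[v] for v in range(3))
            gate = 1.0 / (1.0 + np.exp(-(m @ p("Wg") + p("bg")[0])))
            a = hp[u] + gate * m
            mu, var = a.mean(), ((a - a.mean()) ** 2).mean()
            a = (a - mu) / math.sqrt(var + 1e-5) * p("ln1_g")[0] + p("ln1_b")[0]
            f = np.maximum(a @ p("Wf1") + p("bf1")[0], 0.0) @ p("Wf2") + p("bf2")[0]
            y = a + f
            mu, var = y.mean(), ((y - y.mean()) ** 2).mean()
            expected[u] = (y - mu) / math.sqrt(var + 1e-5) * p("ln2_g")[0] + p(
                "ln2_b"
            )[0]
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_singleton_attention_weight_is_one(self):
        # with a single reactant atom the softmax weight is exactly 1, so
        # the attended message is exactly V regardless of the scores
        rng = np.random.default_rng(4)
        d = 8
        params = init_parameters(rng, d, 2, d, 1, 1)
        hp = rng.standard_normal((1, d))
        hr = rng.standard_normal((1, d))
        out = cross_attention_block(
            params, 0, Tensor(hp), Tensor(hr), n_heads=2, training=False
        ).data

        def p(name):
            return params[f"att0_{name}"].data

        m = hr @ p("Wv")  # weight-1 message, heads concatenate back to V
        gate = 1.0 / (1.0 + np.exp(-(m @ p("Wg") + p("bg"))))
        a = hp + gate * m
        a = (a - a.mean()) / np.sqrt(((a - a.mean()) ** 2).mean() + 1e-5)
        a = a * p("ln1_g") + p("ln1_b")
        f = np.maximum(a @ p("Wf1") + p("bf1"), 0.0) @ p("Wf2") + p("bf2")
        y = a + f
        y = (y - y.mean()) / np.sqrt(((y - y.mean()) ** 2).mean() + 1e-5)
        expected = y * p("ln2_g") + p("ln2_b")
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_duplicate_reactant_atoms_get_identical_weights(self):
        rng = np.random.default_rng(5)
        d = 8
        params = init_parameters(rng, d, 2, d, 1, 1)
        hp = Tensor(rng.standard_normal((2, d)))
        hr_single = rng.standard_normal((1, d))
        hr = Tensor(np.vstack([hr_single, hr_single, hr_single]))
        P = classifier_scores(params, hr, hp).data
        np.testing.assert_allclose(P[:, 0], P[:, 1], atol=1e-12)
        np.testing.assert_allclose(P[:, 1], P[:, 2], atol=1e-12)

    def test_dimension_mismatch_errors(self):
        rng = np.random.default_rng(6)
        params = init_parameters(rng, 4, 2, 4, 1, 1)
        with pytest.raises(ValueError):
            cross_attention_block(
                params, 0,
                Tensor(np.zeros((2, 4))), Tensor(np.zeros((3, 6))),
                n_heads=1,
            )


class TestClassifier:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        d = 16
        params = init_parameters(rng, d, 2, d, 1, 1)
        P = classifier_scores(
            params,
            Tensor(rng.standard_normal((5, d))),
            Tensor(rng.standard_normal((3, d))),
        ).data
        np.testing.assert_allclose(P.sum(axis=1), np.ones(3), atol=1e-6)

    def test_one_by_one_system(self):
        rng = np.random.default_rng(8)
        d = 8
        params = init_parameters(rng, d, 2, d, 1, 1)
        P = classifier_scores(
            params,
            Tensor(rng.standard_normal((1, d))),
            Tensor(rng.standard_normal((1, d))),
        ).data
        np.testing.assert_allclose(P, [[1.0]], atol=1e-12)

    def test_2x2_matches_hand_computed_softmax(self):
        rng = np.random.default_rng(9)
        d = 4
        params = init_parameters(rng, d, 2, d, 1, 1)
        hr = rng.standard_normal((2, d))
        hp = rng.standard_normal((2, d))
        P = classifier_scores(params, Tensor(hr), Tensor(hp)).data
        Qr = hr @ params["clf_Wq"].data
        Kp = hp @ params["clf_Wk"].data
        for u in range(2):
            scores = np.array([Kp[u] @ Qr[v] / math.sqrt(d) for v in range(2)])
            e = np.exp(scores - scores.max())
            np.testing.assert_allclose(P[u], e / e.sum(), atol=1e-5)

    def test_empty_reactants_error(self):
        rng = np.random.default_rng(10)
        params = init_parameters(rng, 4, 2, 4, 1, 1)
        with pytest.raises(ValueError):
            classifier_scores(
                params, Tensor(np.zeros((0, 4))), Tensor(np.zeros((2, 4)))
            )


class TestAutogradNumerics:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(11)
        W = Tensor(rng.standard_normal((3, 3)), requires_grad=True)
        x = rng.standard_normal((2, 3))

        def loss_value(Wdata):
            Wt = Tensor(Wdata, requires_grad=True)
            z = softmax((Tensor(x) @ Wt).sigmoid(), axis=-1)
            return float(
                (-(gather_pairs(z, np.array([0, 1]), np.array([1, 2]))
                   + 1e-12).log().mean()).data
            ), Wt

        base, Wt = loss_value(W.data)
        z = softmax((Tensor(x) @ Wt).sigmoid(), axis=-1)
        loss = -((gather_pairs(z, np.array([0, 1]), np.array([1, 2])) + 1e-12)
                 .log().mean())
        loss.backward()
        eps = 1e-6
        for i in range(3):
            for j in range(3):
                Wp = W.data.copy()
                Wp[i, j] += eps
                up, _ = loss_value(Wp)
                Wm = W.data.copy()
                Wm[i, j] -= eps
                down, _ = loss_value(Wm)
                numeric = (up - down) / (2 * eps)
                assert Wt.grad[i, j] == pytest.approx(numeric, abs=1e-5)
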