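import numpy as np
import pytest

from motcs.autograd import Tensor, as_tensor
from motcs.encoder import EncoderConfig
from motcs.io import MotcsError
from motcs.model import (MLPParams, MOTCSConfig, MOTCSModel, VCDNParams,
                         build_cross_omics_tensor, concat_view_embeddings,
                         cross_omics_vectorized, mlp_view_classify,
                         total_loss, vcdn_classify, vcdn_loss,
                         view_cross_entropy)
from motcs.preprocess import ViewFeatureSet


def tensor_oracle(rows):
    """Triple-nested-loop construction of the cross-omics tensor."""
    c = len(rows[0])
    t = np.zeros((c,) * len(rows))
    for idx in np.ndindex(*t.shape):
        v = 1.0
        for m, i in enumerate(idx):
            v *= rows[m][i]
        t[idx] = v
    return t


class TestConcatViews:
    def test_shapes(self):
        z = concat_view_embeddings(np.zeros((2, 3)), np.zeros((2, 5)))
        assert z.data.shape == (2, 8)

    def test_disabled_driver_branch_passthrough(self):
        svc = np.arange(6.0).reshape(2, 3)
        assert np.array_equal(concat_view_embeddings(None, svc).data, svc)

    def test_both_absent_errors(self):
        with pytest.raises(MotcsError):
            concat_view_embeddings(None, None)


class TestMLPClassify:
    def _zero_mlp(self, d_in, hidden, c):
        return MLPParams(Tensor(np.zeros((d_in, hidden))),
                         Tensor(np.zeros(hidden)),
                         Tensor(np.zeros((hidden, c))), Tensor(np.zeros(c)))

    def test_zero_weights_uniform(self):
        p = self._zero_mlp(4, 3, 5)
        out = mlp_view_classify(np.ones((2, 4)), p).data
        assert np.allclose(out, 0.2)

    def test_saturated_logits(self):
        p = self._zero_mlp(1, 1, 2)
        p.b2 = Tensor(np.array([10.0, -10.0]))
        out = mlp_view_classify(np.zeros((1, 1)), p).data
        assert out[0, 0] > 0.999 and out[0, 1] < 0.001

    def test_hand_computed_softmax(self):
        p = self._zero_mlp(1, 1, 2)
        p.W1 = Tensor(np.array([[1.0]]))
        p.W2 = Tensor(np.array([[1.0, -1.0]]))
        out = mlp_view_classify(np.array([[2.0]]), p).data
        e = np.exp([2.0, -2.0])
        assert np.allclose(out, e / e.sum())

    def test_single_class_rejected(self):
        with pytest.raises(MotcsError):
            mlp_view_classify(np.ones((1, 2)), self._zero_mlp(2, 2, 1))


class TestCrossEntropy:
    def test_perfect_onehot_zero_loss(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert float(view_cross_entropy(probs, [0, 1, 2], eps=0.0).data) \
            == pytest.approx(0.0)

    def test_uniform_equals_log_c(self):
        for c in (3, 5):
            probs = np.full((4, c), 1.0 / c)
            loss = float(view_cross_entropy(probs, [0] * 4, eps=0.0).data)
            assert loss == pytest.approx(np.log(c), rel=1e-12)

    def test_epsilon_floors_zero_probability(self):
        probs = np.array([[0.0, 1.0]])
        loss = float(view_cross_entropy(probs, [0], eps=1e-8).data)
        assert loss == pytest.approx(-np.log(1e-8))

    def test_vcdn_loss_shares_kernel(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(5, 3))
        probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        y = [0, 1, 2, 0, 1]
        assert float(vcdn_loss(probs, y).data) == \
            float(view_cross_entropy(probs, y).data)


class TestCrossOmicsTensor:
    def test_onehot_rows_give_onehot_tensor(self):
        row = np.eye(3)[1]
        t, vec = build_cross_omics_tensor([row, row, row])
        assert t[1, 1, 1] == 1.0 and t.sum() == 1.0
        assert vec[1 * 9 + 1 * 3 + 1] == 1.0

    def test_uniform_c2_all_eighth(self):
        row = np.array([0.5, 0.5])
        t, _ = build_cross_omics_tensor([row, row, row])
        assert np.allclose(t, 1 / 8)

    def test_hand_evaluated_products(self):
        rows = [np.array([0.5, 0.5]), np.array([0.8, 0.2]),
                np.array([1.0, 0.0])]
        t, vec = build_cross_omics_tensor(rows)
        assert t[0, 0, 0] == pytest.approx(0.4)
        assert t[1, 1, 0] == pytest.approx(0.1)
        assert t.sum() == pytest.approx(1.0)
        # row-major vectorisation: first view's index slowest
        assert vec[0] == t[0, 0, 0] and vec[4] == t[1, 0, 0]

    def test_unnormalised_row_rejected(self):
        with pytest.raises(MotcsError):
            build_cross_omics_tensor([np.array([0.7, 0.7])] * 3)

    @pytest.mark.parametrize("c", [2, 3, 5])
    def test_matches_triple_loop_oracle(self, c):
        rng = np.random.default_rng(c)
        rows = [rng.dirichlet(np.ones(c)) for _ in range(3)]
        t, vec = build_cross_omics_tensor(rows)
        expected = tensor_oracle(rows)
        assert np.allclose(t, expected, atol=1e-12)
        assert np.allclose(vec, expected.reshape(-1))

    def test_batched_vectorisation_matches_per_sample(self):
        rng = np.random.default_rng(9)
        c, n = 4, 6
        view_probs = [as_tensor(rng.dirichlet(np.ones(c), size=n))
                      for _ in range(3)]
        batched = cross_omics_vectorized(view_probs).data
        for j in range(n):
            _, vec = build_cross_omics_tensor(
                [vp.data[j] for vp in view_probs])
            assert np.allclose(batched[j], vec, atol=1e-12)


class TestVCDN:
    def _zero_vcdn(self, c, V=3):
        d = c**V
        return VCDNParams(Tensor(np.zeros((d, d))), Tensor(np.zeros(d)),
                          Tensor(np.zeros((d, c))), Tensor(np.zeros(c)))

    def test_zero_weights_uniform_output(self):
        out = vcdn_classify(np.ones((2, 27)), self._zero_vcdn(3)).data
        assert np.allclose(out, 1 / 3)

    def test_identical_inputs_identical_rows(self):
        rng = np.random.default_rng(1)
        p = VCDNParams(Tensor(rng.normal(size=(8, 8))), Tensor(np.zeros(8)),
                       Tensor(rng.normal(size=(8, 2))), Tensor(np.zeros(2)))
        vec = np.tile(rng.random(8), (2, 1))
        out = vcdn_classify(vec, p).data
        assert np.array_equal(out[0], out[1])

    def test_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(2)
        c = 2
        p = VCDNParams(Tensor(rng.normal(size=(8, 8))),
                       Tensor(rng.normal(size=8)),
                       Tensor(rng.normal(size=(8, c))),
                       Tensor(rng.normal(size=c)))
        vec = rng.random((3, 8))
        h = vec @ p.W1.data + p.b1.data
        h = np.where(h > 0, h, 0.01 * h)
        logits = h @ p.W2.data + p.b2.data
        e = np.exp(logits - logits.max(1, keepdims=True))
        expected = e / e.sum(1, keepdims=True)
        assert np.allclose(vcdn_classify(vec, p).data, expected, atol=1e-12)


class TestTotalLoss:
    def test_sum(self):
        ls = [as_tensor(x) for x in (1.0, 2.0, 3.0)]
        assert float(total_loss(ls, as_tensor(4.0)).data) == 10.0

    def test_zeros(self):
        assert float(total_loss([as_tensor(0.0)] * 3,
                                as_tensor(0.0)).data) == 0.0

    def test_single_view_no_vcdn_term(self):
        assert float(total_loss([as_tensor(1.5)], None).data) == 1.5

    def test_view_permutation_invariant(self):
        a = [as_tensor(x) for x in (0.3, 1.1, 0.6)]
        assert float(total_loss(a, None).data) == \
            pytest.approx(float(total_loss(a[::-1], None).data))


def _tiny_model(views=("mRNA", "miRNA", "methylation"), c=3, seed=0,
                driver=True):
    enc = EncoderConfig(embed_dim=4, num_heads=2, num_layers=1,
                        dropout_rate=0.0)
    cfg = MOTCSConfig(views=list(views), num_classes=c, encoder_driver=enc,
                      encoder_nondriver=enc, mlp_hidden=5,
                      driver_branch_enabled=driver)
    fsets = {v: ViewFeatureSet(v, ["d1", "d2"] if driver else [],
                               ["n1", "n2", "n3"]) for v in views}
    rng = np.random.default_rng(seed)
    model = MOTCSModel(cfg, fsets, rng)
    X = {v: rng.normal(size=(4, len(fsets[v].all_features))) for v in views}
    return model, X


class TestFullModel:
    def test_probability_rows_normalised(self):
        model, X = _tiny_model()
        view_probs, final = model.forward(X)
        for t in list(view_probs.values()) + [final]:
            assert np.allclose(t.data.sum(axis=1), 1.0, atol=1e-6)
            assert (t.data >= 0).all()

    def test_single_view_has_no_vcdn(self):
        model, X = _tiny_model(views=("mRNA",))
        assert model.vcdn is None
        _, final = model.forward(X)
        assert final is None
        y, probs = model.predict_final(X)
        assert y.shape == (4,) and probs.shape == (4, 3)

    def test_predict_argmax_and_tie_rule(self):
        model, X = _tiny_model(views=("mRNA",), c=2)
        # zero the head -> uniform probabilities -> tie broken to class 0
        br = model.branches["mRNA"]
        for p in br.mlp.parameters():
            p.data[...] = 0.0
        y, probs = model.predict_final(X)
        assert np.allclose(probs, 0.5)
        assert (y == 0).all()

    def test_loss_gradients_match_finite_differences(self):
        model, X = _tiny_model(c=3, seed=4)
        y = np.array([0, 1, 2, 1])
        params = model.parameters()
        loss = model.loss(X, y)
        loss.backward()
        rng = np.random.default_rng(0)
        checked = 0
        for p in rng.choice(len(params), size=6, replace=False):
            t = params[p]
            flat = rng.integers(t.data.size)
            i = np.unravel_index(flat, t.data.shape)
            eps = 1e-6
            t.data[i] += eps
            lp = float(model.loss(X, y).data)
            t.data[i] -= 2 * eps
            lm = float(model.loss(X, y).data)
            t.data[i] += eps
            fd = (lp - lm) / (2 * eps)
            assert fd == pytest.approx(t.grad[i], rel=1e-4, abs=1e-8)
            checked += 1
        assert checked == 6

    def test_column_count_mismatch_rejected(self):
        model, X = _tiny_model()
        X["mRNA"] = X["mRNA"][:, :2]
        with pytest.raises(MotcsError):
            model.forward(X)
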