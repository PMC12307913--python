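"""Attribution contracts: rollout oracle, closed forms, completeness, conservation."""

import numpy as np
import pytest

from careinsight import nn
from careinsight.attribution import (
    TokenAttributionMap,
    _eps_div,
    _lrp_linear,
    attention_attribution,
    attention_rollout,
    attribute,
    gradient_x_activation,
    integrated_gradients,
    lrp,
)
from careinsight.transformer import segment


class TestAttentionRollout:
    def test_matches_hand_multiplied_matrices(self):
        """2-layer, 1-head toy attentions composed by explicit matrix product."""
        rng = np.random.default_rng(0)
        W = 4
        A1 = rng.dirichlet(np.ones(W), size=W)[None, None]  # (S=1, H=1, W, W)
        A2 = rng.dirichlet(np.ones(W), size=W)[None, None]
        mask = np.ones((1, W))
        got = attention_rollout([A1, A2], mask)
        eye = np.eye(W)
        R1 = 0.5 * A1[0, 0] + 0.5 * eye
        R1 /= R1.sum(axis=-1, keepdims=True)
        R2 = 0.5 * A2[0, 0] + 0.5 * eye
        R2 /= R2.sum(axis=-1, keepdims=True)
        expected = (R2 @ R1).mean(axis=0)
        np.testing.assert_allclose(got[0], expected)

    def test_uniform_attention_gives_uniform_scores(self):
        W = 6
        A = np.full((1, 2, W, W), 1.0 / W)
        got = attention_rollout([A, A], np.ones((1, W)))
        np.testing.assert_allclose(got[0], np.full(W, 1.0 / W))

    def test_single_token_total_mass(self, fixture_model):
        model, _ = fixture_model
        ids = model.tokenizer.encode(["ab"]).ids[:1]
        amap = attention_attribution(model, ids)
        assert len(amap.scores) == 1
        assert amap.scores[0] == pytest.approx(1.0)
        assert amap.task is None and amap.explained_class is None


class _LinearToyModel:
    """Purely linear scorer over summed embeddings, exposing the same
    forward/embed surface the gradient-based explainers consume."""

    def __init__(self, vocab=10, dim=4, n_classes=3, window=8, seed=0):
        rng = np.random.default_rng(seed)
        self.emb = nn.Tensor(rng.normal(size=(vocab, dim)))
        self.coef = nn.Tensor(rng.normal(size=(dim, n_classes)))
        self.window = window

    class _Cfg:
        truncate = False
        window = 8
        effective_stride = 8

    cfg = _Cfg()

    def embed(self, seg_ids):
        return nn.gather(self.emb, seg_ids)

    def _encode(self, X0, mask, cache):
        summed = (X0 * mask[:, :, None]).sum(axis=1).sum(axis=0)
        return {"care_need": summed @ self.coef}

    def forward(self, ids, cache=None, X0=None):
        seg_ids, mask, starts = segment(ids, self.window, self.window)
        if X0 is None:
            X0 = self.embed(seg_ids)
        return self._encode(X0, mask, cache), X0, (seg_ids, mask, starts)


class TestClosedFormsOnLinearModel:
    def test_gxa_equals_coefficient_times_embedding(self):
        model = _LinearToyModel()
        ids = [1, 3, 5]
        amap = gradient_x_activation(model, ids, "care_need", 2)
        expected = (model.emb.data[ids] * model.coef.data[:, 2]).sum(axis=1)
        np.testing.assert_allclose(amap.scores, expected, atol=1e-12)

    @pytest.mark.parametrize("steps", [1, 4, 32])
    def test_ig_exact_for_any_step_count(self, steps):
        """On a linear model IG equals gradient × (input − baseline) exactly."""
        model = _LinearToyModel()
        ids = [2, 4, 7, 1]
        amap, total, delta = integrated_gradients(
            model, ids, "care_need", 1, steps=steps, baseline="zero",
            return_completeness=True,
        )
        expected = (model.emb.data[ids] * model.coef.data[:, 1]).sum(axis=1)
        np.testing.assert_allclose(amap.scores, expected, atol=1e-10)
        assert total == pytest.approx(delta, abs=1e-10)


class TestGradientXActivation:
    def test_finite_difference_agreement(self, fixture_model):
        model, ids = fixture_model
        amap = gradient_x_activation(model, ids, "care_need", 1)
        logits, X0, (seg_ids, mask, _) = model.forward(ids)
        # finite-difference dlogit/dX0 at a few positions, times activation
        eps = 1e-6
        rng = np.random.default_rng(3)
        for _ in range(5):
            pos = int(rng.integers(0, len(ids)))
            fd_sum = 0.0
            for d in range(model.cfg.dim):
                base = X0.data.copy()
                bumped = base.copy()
                bumped[0, pos, d] += eps
                lp = model._encode(nn.Tensor(bumped), mask, None)["care_need"].data[1]
                bumped[0, pos, d] -= 2 * eps
                lm = model._encode(nn.Tensor(bumped), mask, None)["care_need"].data[1]
                fd_sum += (lp - lm) / (2 * eps) * base[0, pos, d]
            assert amap.scores[pos] == pytest.approx(fd_sum, rel=1e-4, abs=1e-8)

    def test_padding_positions_carry_no_score(self, fixture_model):
        model, _ = fixture_model
        ids = model.tokenizer.encode(["ab", "cd"]).ids  # shorter than the window
        amap = gradient_x_activation(model, ids, "care_need", 0)
        assert len(amap.scores) == len(ids)  # padding dropped in stitching


class TestIntegratedGradients:
    def test_input_equal_baseline_is_zero(self, fixture_model):
        model, _ = fixture_model
        from careinsight.tokenize import PAD_ID

        ids = [PAD_ID] * 4
        amap = integrated_gradients(model, ids, "care_need", 0, steps=8, baseline="pad")
        np.testing.assert_allclose(amap.scores, 0.0, atol=1e-12)

    def test_completeness_at_512_steps(self, fixture_model):
        """Attribution total matches logit(input) − logit(baseline) to <1%
        of the logit range."""
        model, ids = fixture_model
        amap, total, delta = integrated_gradients(
            model, ids, "care_need", 1, steps=512, return_completeness=True
        )
        logits = model.forward(ids)[0]["care_need"].data
        logit_range = logits.max() - logits.min()
        assert abs(total - delta) < 0.01 * logit_range

    def test_step_validation(self, fixture_model):
        model, ids = fixture_model
        with pytest.raises(ValueError, match="steps"):
            integrated_gradients(model, ids, "care_need", 0, steps=0)


class TestLrp:
    def test_single_linear_layer_one_hot_selects_weight(self):
        """Relevance of a one-hot input through one linear layer is the
        selected weight."""
        W = np.array([[1.5, -2.0], [0.5, 3.0], [2.5, 1.0]])
        x = np.array([0.0, 1.0, 0.0])
        z = x @ W
        R_out = np.array([z[0], 0.0])  # explain class 0
        R_in = _lrp_linear(x, W, z, R_out, eps=1e-9)
        np.testing.assert_allclose(R_in, [0.0, W[1, 0], 0.0], rtol=1e-6)

    def test_positive_homogeneity_of_epsilon_rule(self):
        rng = np.random.default_rng(5)
        W = np.abs(rng.normal(size=(4, 3)))
        x = np.abs(rng.normal(size=4))
        z = x @ W
        R1 = _lrp_linear(x, W, z, z.copy(), eps=1e-9)
        R2 = _lrp_linear(2 * x, W, 2 * z, 2 * z.copy(), eps=1e-9)
        np.testing.assert_allclose(R2, 2 * R1, rtol=1e-6)

    def test_conservation_on_fixture(self, fixture_model):
        """|Σ relevance − logit| / |logit| < 5% on the zero-bias model."""
        model, ids = fixture_model
        for cls in range(3):
            amap, total, logit = lrp(model, ids, "care_need", cls,
                                     return_conservation=True)
            assert abs(total - logit) / max(abs(logit), 1e-9) < 0.05

    def test_scores_align_with_subtokens(self, fixture_model):
        model, ids = fixture_model
        amap = lrp(model, ids, "m1_mobility", 2)
        assert isinstance(amap, TokenAttributionMap)
        assert len(amap.scores) == len(ids)


class TestDispatchContract:
    def test_all_methods_same_shape(self, fixture_model):
        model, ids = fixture_model
        maps = [
            attribute(model, ids, "attention"),
            attribute(model, ids, "lgxa", task="care_need", cls=0),
            attribute(model, ids, "ig", task="care_need", cls=0, steps=4),
            attribute(model, ids, "lrp", task="care_need", cls=0),
        ]
        assert all(len(m.scores) == len(ids) for m in maps)
        assert [m.method for m in maps] == ["attention", "lgxa", "ig", "lrp"]

    def test_classful_method_requires_task(self, fixture_model):
        model, ids = fixture_model
        with pytest.raises(ValueError, match="task"):
            attribute(model, ids, "lrp")
        with pytest.raises(KeyError, match="unknown attribution"):
            attribute(model, ids, "lime", task="care_need", cls=0)


def test_eps_div_handles_zero_denominator():
    out = _eps_div(np.array([1.0, 1.0]), np.array([0.0, 2.0]), eps=1e-6)
    assert np.isfinite(out).all()
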