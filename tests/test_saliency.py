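"""Saliency baselines: gradients, integrated gradients, attention readouts,
rollout, LIME surrogate and the shuffled-score null."""

import numpy as np
import pytest

from attnzyme.aggregation import attn_agg
from attnzyme.encoder import AttentionCapture, tokenize
from attnzyme.importance import ImportanceVector
from attnzyme.model import TransformerECClassifier
from attnzyme.saliency import (
    SaliencyConfig,
    attention_last_layer,
    attention_rollout,
    grad_saliency,
    grad_x_input,
    integrated_gradients,
    lime_saliency,
    shuffled_baseline,
)
from attnzyme.synthetic import gen_attention_tensor


class LinearStub:
    """Differentiable toy scorer: logits = A @ x0.ravel() + b."""

    def __init__(self, n_tokens, dim, n_classes=2, seed=0, embeddings=None):
        rng = np.random.default_rng(seed)
        self.A = rng.normal(size=(n_classes, n_tokens * dim))
        self.b = rng.normal(size=n_classes)
        self._emb = embeddings if embeddings is not None else rng.normal(size=(n_tokens, dim))
        self.classes_ = np.array([str(i) for i in range(n_classes)], dtype=object)

    def embeddings(self, tokens):
        return self._emb.copy()

    def logits_from_embeddings(self, x0):
        return self.A @ x0.ravel() + self.b

    def input_gradient(self, x0, target):
        return self.logits_from_embeddings(x0), self.A[target].reshape(x0.shape)


SEQ = "MKVLATGRE"


class TestGradientFamily:
    def test_zero_head_weights_give_zero_saliency(self):
        est = TransformerECClassifier(
            n_layers=1, n_heads=2, embed_dim=8, ff_dim=12, n_epochs=0, random_state=0
        )
        est.fit([SEQ, SEQ[::-1]], ["1", "2"])
        est.params_["wc"][:] = 0.0
        iv = grad_saliency(est, SEQ)
        np.testing.assert_allclose(iv.scores, 0.0, atol=1e-12)
        assert len(iv) == len(SEQ)

    def test_grad_scores_match_finite_differences(self, micro_model):
        cfg = micro_model.config_
        tokens = tokenize(SEQ, cfg)
        iv = grad_saliency(micro_model, tokens, SaliencyConfig(target_rule="given", target_class="1"))
        target = int(np.flatnonzero(micro_model.classes_ == "1")[0])
        x0 = micro_model.embeddings(tokens)
        eps = 1e-5
        fd = np.zeros_like(x0)
        for i in range(x0.shape[0]):
            for j in range(x0.shape[1]):
                x0[i, j] += eps
                up = micro_model.logits_from_embeddings(x0)[target]
                x0[i, j] -= 2 * eps
                dn = micro_model.logits_from_embeddings(x0)[target]
                x0[i, j] += eps
                fd[i, j] = (up - dn) / (2 * eps)
        kept = np.flatnonzero(~tokens.special_mask)
        expected = np.linalg.norm(fd, axis=1)[kept]
        np.testing.assert_allclose(iv.scores, expected, rtol=1e-3)

    def test_grad_x_input_equals_grad_for_unit_embeddings(self):
        tokens = tokenize("MKV")
        stub = LinearStub(tokens.length, 4, embeddings=np.ones((tokens.length, 4)))
        a = grad_saliency(stub, tokens)
        b = grad_x_input(stub, tokens)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_grad_x_input_zero_embedding_zero_score(self):
        tokens = tokenize("MKV")
        emb = np.random.default_rng(0).normal(size=(tokens.length, 4))
        emb[1] = 0.0
        stub = LinearStub(tokens.length, 4, embeddings=emb)
        iv = grad_x_input(stub, tokens)
        assert iv.scores[0] == pytest.approx(0.0, abs=1e-12)


class TestIntegratedGradients:
    def test_linear_model_exactness(self):
        tokens = tokenize("MKVL")
        stub = LinearStub(tokens.length, 3, seed=4)
        iv, raw = integrated_gradients(stub, tokens, SaliencyConfig(ig_steps=5), return_raw=True)
        x0 = stub.embeddings(tokens)
        _, g = stub.input_gradient(x0, int(np.argmax(stub.logits_from_embeddings(x0))))
        np.testing.assert_allclose(raw, x0 * g, atol=1e-12)

    def test_completeness_axiom(self, micro_model):
        tokens = tokenize(SEQ, micro_model.config_)
        _, raw = integrated_gradients(
            micro_model, tokens, SaliencyConfig(ig_steps=200), return_raw=True
        )
        x0 = micro_model.embeddings(tokens)
        base = micro_model.embedding_baseline(tokens)
        target = int(np.argmax(micro_model.logits_from_embeddings(x0)))
        diff = (
            micro_model.logits_from_embeddings(x0)[target]
            - micro_model.logits_from_embeddings(base)[target]
        )
        assert raw.sum() == pytest.approx(diff, rel=0.01)

    def test_single_step_is_midpoint_gradient(self, micro_model):
        tokens = tokenize("ACDEFG", micro_model.config_)
        x0 = micro_model.embeddings(tokens)
        base = micro_model.embedding_baseline(tokens)
        target = int(np.argmax(micro_model.logits_from_embeddings(x0)))
        _, raw = integrated_gradients(
            micro_model, tokens,
            SaliencyConfig(ig_steps=1, target_rule="given", target_class=micro_model.classes_[target]),
            return_raw=True,
        )
        _, g = micro_model.input_gradient(base + 0.5 * (x0 - base), target)
        np.testing.assert_allclose(raw, (x0 - base) * g, atol=1e-12)


class TestAttentionReadouts:
    def test_last_layer_equals_attnagg_on_final_subtensor(self):
        cap = gen_attention_tensor(6, 2, 3, seed=5)
        sub = AttentionCapture(
            tensor=cap.tensor[-3:], special_mask=cap.special_mask,
            n_layers=1, n_heads=3, residue_map=cap.residue_map,
        )
        a = attention_last_layer(cap)
        b = attn_agg(sub, "AttnAgg1A1A")
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_single_layer_single_head_coincides_with_family(self):
        cap = gen_attention_tensor(5, 1, 1, seed=6)
        np.testing.assert_allclose(
            attention_last_layer(cap).scores, attn_agg(cap, "AttnAgg1A1A").scores, atol=1e-12
        )

    def test_rollout_matches_hand_built_product(self):
        a1 = np.array([[0.6, 0.2, 0.2], [0.1, 0.8, 0.1], [0.3, 0.3, 0.4]])
        a2 = np.array([[0.5, 0.25, 0.25], [0.2, 0.6, 0.2], [0.1, 0.2, 0.7]])
        cap = AttentionCapture(
            tensor=np.stack([a1, a2]),
            special_mask=np.array([True, False, False]),
            n_layers=2, n_heads=1, residue_map={1: 1, 2: 2},
        )
        eye = np.eye(3)
        m1, m2 = 0.5 * a1 + 0.5 * eye, 0.5 * a2 + 0.5 * eye
        product = m2 @ m1
        assert np.allclose(product.sum(axis=1), 1.0, atol=1e-9)  # stochasticity kept
        iv = attention_rollout(cap)
        np.testing.assert_allclose(iv.scores, product[0, 1:], atol=1e-12)

    def test_rollout_identity_attention(self):
        eye = np.eye(4)
        cap = AttentionCapture(
            tensor=np.stack([eye]), special_mask=np.array([True, False, False, False]),
            n_layers=1, n_heads=1, residue_map={1: 1, 2: 2, 3: 3},
        )
        iv = attention_rollout(cap)
        np.testing.assert_allclose(iv.scores, 0.0, atol=1e-12)  # CLS keeps all mass

    def test_rollout_deterministic(self, micro_model):
        _, cap = micro_model.forward_with_attention(SEQ)
        _, cap2 = micro_model.forward_with_attention(SEQ)
        np.testing.assert_array_equal(
            attention_rollout(cap).scores, attention_rollout(cap2).scores
        )

    def test_rollout_requires_cls_readout(self):
        cap = gen_attention_tensor(7, 3, 2, seed=8)  # no special tokens
        with pytest.raises(ValueError, match="CLS"):
            attention_rollout(cap)

    def test_invalid_capture_rejected(self):
        with pytest.raises(ValueError):
            AttentionCapture(
                tensor=np.zeros((1, 3, 3)), special_mask=np.zeros(3, dtype=bool),
                n_layers=1, n_heads=1,
            )


class TestLime:
    @staticmethod
    def additive_model(coefs):
        # class 0 stays the argmax at the unperturbed input, so the
        # surrogate explains the positive-score class
        def f(seq):
            score = sum(c for i, c in enumerate(coefs) if seq[i] != "X")
            return np.array([0.6 + score, 0.4 - score])
        return f

    def test_exact_recovery_of_linear_scorer(self):
        coefs = np.array([0.05, -0.02, 0.07])
        iv = lime_saliency(
            self.additive_model(coefs), "MKV",
            SaliencyConfig(lime_samples=50, seed=0),
        )
        np.testing.assert_allclose(iv.scores, coefs, atol=1e-8)

    def test_planted_feature_dominates(self):
        w = 0.3
        coefs = np.zeros(12)
        coefs[4] = w
        iv = lime_saliency(
            self.additive_model(coefs), "MKVLATGREFYD",
            SaliencyConfig(lime_samples=5000, seed=1),
        )
        assert iv.scores[4] == pytest.approx(w, abs=0.01)
        others = np.delete(np.abs(iv.scores), 4)
        assert (others < 0.1 * w).all()

    def test_top_feature_recovery_rate(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            coefs = rng.uniform(0.0, 0.02, size=10)
            planted = int(rng.integers(10))
            coefs[planted] = 0.2
            iv = lime_saliency(
                self.additive_model(coefs), "MKVLATGREF",
                SaliencyConfig(lime_samples=500, seed=seed),
            )
            hits += int(np.argmax(iv.scores) == planted)
        assert hits >= 19

    def test_no_nan_for_heavy_masking(self):
        iv = lime_saliency(
            self.additive_model(np.zeros(5)), "MKVLA",
            SaliencyConfig(lime_samples=200, lime_mask_rate=0.9, seed=2),
        )
        assert np.all(np.isfinite(iv.scores))


class TestShuffledBaseline:
    def test_multiset_preserved_per_sequence(self):
        ivs = [ImportanceVector("a", np.arange(10.0), "m")]
        reps = shuffled_baseline(ivs, SaliencyConfig(shuffle_reps=5, seed=0))
        assert len(reps) == 5
        for rep in reps:
            np.testing.assert_allclose(np.sort(rep[0].scores), np.arange(10.0))

    def test_length_one_shuffle_is_identity(self):
        ivs = [ImportanceVector("a", [3.0], "m")]
        reps = shuffled_baseline(ivs, SaliencyConfig(shuffle_reps=3, seed=0))
        assert all(rep[0].scores[0] == 3.0 for rep in reps)

    def test_seeded_reproducibility(self):
        ivs = [ImportanceVector("a", np.arange(8.0), "m")]
        a = shuffled_baseline(ivs, SaliencyConfig(shuffle_reps=2, seed=5))
        b = shuffled_baseline(ivs, SaliencyConfig(shuffle_reps=2, seed=5))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra[0].scores, rb[0].scores)
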