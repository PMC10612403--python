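"""Scikit-learn style classifier wrapping the numpy self-attention encoder.

:class:`TransformerECClassifier` is the package's central estimator: it is
trained from random initialisation with cross-entropy on flat (independent)
class labels, Adam with an exponentially decaying learning rate, gradient
accumulation, dropout on the CLS embedding only, and optional inverse-
frequency balanced sampling. Attention maps of any input can be captured for
the interpretability modules, and gradients with respect to the input
embeddings are exposed for the saliency baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import encoder as enc
from .encoder import (
    AttentionCapture,
    EncoderConfig,
    TokenizedSequence,
    tokenize,
)

__all__ = [
    "TrainConfig",
    "ClassifierOutput",
    "TransformerECClassifier",
    "class_weights",
    "train_classifier",
    "predict",
]


@dataclass(frozen=True)
class TrainConfig:
    """Fine-tuning hyper-parameters.

    Defaults mirror the reference recipe: dropout 0.2 on the CLS embedding,
    batch size 2 with 16 accumulation steps (effective batch 32), Adam with
    lr0 = 1e-5, betas (0.9, 0.999), and the per-epoch schedule
    lr(e) = lr0 * lr_decay**e with decay 0.8.
    """

    dropout_cls: float = 0.2
    batch_size: int = 2
    accumulation_steps: int = 16
    lr0: float = 1.0e-5
    beta1: float = 0.9
    beta2: float = 0.999
    lr_decay: float = 0.8
    n_epochs: int = 15
    balance_sampling: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_cls < 1.0:
            raise ValueError("dropout_cls must be in [0, 1)")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.batch_size < 1 or self.accumulation_steps < 1 or self.n_epochs < 0:
            raise ValueError("batch_size and accumulation_steps must be >= 1, n_epochs >= 0")


@dataclass
class ClassifierOutput:
    """Logits, softmax probabilities and the argmax class for one sequence."""

    logits: np.ndarray
    probabilities: np.ndarray
    predicted_class: object


def class_weights(labels) -> np.ndarray:
    """Per-example weights equal to the inverse of the class occurrence count.

    Used for balanced sampling with replacement, so that every class has the
    same expected share of draws.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("class_weights requires at least one labelled example")
    values, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    count_of = dict(zip(values, counts))
    return np.array([1.0 / count_of[lab] for lab in labels], dtype=float)


class TransformerECClassifier(ClassifierMixin, BaseEstimator):
    """Self-attention encoder with a CLS classification head.

    Parameters follow the fine-tuning recipe of the EC-prediction task:
    ``learning_rate`` decays by ``lr_decay`` each epoch (lr(e) = lr0*decay^e),
    gradients are averaged over an effective batch of
    ``batch_size * accumulation_steps`` examples per optimizer step, dropout
    is applied to the CLS embedding only, and ``balance_sampling`` draws
    training examples with replacement with probability inversely
    proportional to their class frequency. A single ``random_state`` integer
    controls initialisation, sampling and dropout.

    Attributes (after :meth:`fit`)
    ------------------------------
    classes_ : ndarray of class labels.
    params_ : dict of weight arrays.
    config_ : the :class:`EncoderConfig` actually used.
    history_ : list of per-epoch dicts (epoch, lr, train_loss, valid_accuracy).
    """

    def __init__(
        self,
        *,
        n_layers: int = 2,
        n_heads: int = 4,
        embed_dim: int = 64,
        ff_dim: int = 128,
        max_len: int = 1024,
        dropout_cls: float = 0.2,
        batch_size: int = 2,
        accumulation_steps: int = 16,
        learning_rate: float = 1.0e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        lr_decay: float = 0.8,
        n_epochs: int = 15,
        balance_sampling: bool = False,
        init_scale: float = 0.02,
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.embed_dim = embed_dim
        self.ff_dim = ff_dim
        self.max_len = max_len
        self.dropout_cls = dropout_cls
        self.batch_size = batch_size
        self.accumulation_steps = accumulation_steps
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.lr_decay = lr_decay
        self.n_epochs = n_epochs
        self.balance_sampling = balance_sampling
        self.init_scale = init_scale
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, validation_data=None):
        """Train from random initialisation on sequences ``X`` and labels ``y``.

        ``validation_data`` is an optional ``(X_valid, y_valid)`` pair whose
        accuracy is recorded per epoch (classes present only in the
        validation set trigger a warning, not an error).
        """
        if not 0.0 <= self.dropout_cls < 1.0:
            raise ValueError("dropout_cls must be in [0, 1)")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if min(self.batch_size, self.accumulation_steps) < 1:
            raise ValueError("batch_size and accumulation_steps must be >= 1")
        X = list(X)
        y = np.asarray(y, dtype=object)
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training requires at least two classes")
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_to_idx[v] for v in y], dtype=np.int64)

        self.config_ = EncoderConfig(
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            embed_dim=self.embed_dim,
            ff_dim=self.ff_dim,
            max_len=self.max_len,
        )
        rng = np.random.default_rng(self.random_state)
        self.params_ = enc.init_params(self.config_, len(self.classes_), rng, self.init_scale)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params_.items()}
        self._adam_t = 0
        self.history_ = []

        tokenized = [tokenize(s, self.config_) for s in X]
        valid = None
        if validation_data is not None:
            Xv, yv = validation_data
            unseen = sorted(set(map(str, yv)) - set(map(str, y)))
            if unseen:
                warnings.warn(
                    f"validation classes absent from training set: {unseen}", UserWarning
                )
            valid = (list(Xv), np.asarray(yv, dtype=object))

        weights = class_weights(y) if self.balance_sampling else None
        n = len(X)
        eff_batch = self.batch_size * self.accumulation_steps
        for epoch in range(self.n_epochs):
            lr = self.learning_rate * self.lr_decay**epoch
            if weights is not None:
                order = rng.choice(n, size=n, replace=True, p=weights / weights.sum())
            else:
                order = rng.permutation(n)
            losses = []
            for start in range(0, n, eff_batch):
                chunk = order[start : start + eff_batch]
                grads_sum = None
                for i in chunk:
                    mask = self._dropout_mask(rng)
                    logits, _, cache = enc.forward_tokens(
                        self.params_, self.config_, tokenized[i],
                        dropout_mask=mask, want_cache=True,
                    )
                    loss, dlogits = enc.cross_entropy(logits, y_idx[i])
                    losses.append(loss)
                    g, dx0 = enc.backward(self.params_, self.config_, cache, dlogits)
                    enc.accumulate_embedding_grad(
                        g, self.config_, tokenized[i].token_ids, dx0
                    )
                    if grads_sum is None:
                        grads_sum = g
                    else:
                        for k in grads_sum:
                            grads_sum[k] += g[k]
                for k in grads_sum:
                    grads_sum[k] /= len(chunk)
                self._adam_step(grads_sum, lr)
            entry = {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(losses)) if losses else None,
                "valid_accuracy": None,
            }
            if valid is not None:
                entry["valid_accuracy"] = float(np.mean(self.predict(valid[0]) == valid[1]))
            self.history_.append(entry)
        return self

    def _dropout_mask(self, rng: np.random.Generator):
        if self.dropout_cls <= 0.0:
            return None
        keep = rng.random(self.config_.embed_dim) >= self.dropout_cls
        return keep.astype(float) / (1.0 - self.dropout_cls)

    def _adam_step(self, grads: dict, lr: float) -> None:
        self._adam_t += 1
        t = self._adam_t
        b1, b2, eps = self.beta1, self.beta2, 1e-8
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params_[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -------------------------------------------------------------- predict

    def _as_tokens(self, seq) -> TokenizedSequence:
        if isinstance(seq, TokenizedSequence):
            return seq
        return tokenize(seq, self.config_)

    def classify(self, seq) -> ClassifierOutput:
        """Evaluation-mode forward pass for one sequence."""
        check_is_fitted(self, "params_")
        tokens = self._as_tokens(seq)
        logits, _, _ = enc.forward_tokens(self.params_, self.config_, tokens)
        probs = enc.softmax(logits)
        return ClassifierOutput(logits, probs, self.classes_[int(np.argmax(logits))])

    def forward_with_attention(self, seq):
        """Forward pass returning ``(ClassifierOutput, AttentionCapture)``."""
        check_is_fitted(self, "params_")
        tokens = self._as_tokens(seq)
        logits, attn, _ = enc.forward_tokens(
            self.params_, self.config_, tokens, want_attention=True
        )
        probs = enc.softmax(logits)
        out = ClassifierOutput(logits, probs, self.classes_[int(np.argmax(logits))])
        lh = attn.reshape(-1, tokens.length, tokens.length)
        capture = AttentionCapture(
            tensor=lh,
            special_mask=tokens.special_mask,
            n_layers=self.config_.n_layers,
            n_heads=self.config_.n_heads,
            residue_map=dict(tokens.residue_map),
        )
        return out, capture

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        return np.vstack([self.classify(s).probabilities for s in X])

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    # ---------------------------------------------------- saliency plumbing

    def embeddings(self, seq) -> np.ndarray:
        """Input embeddings (token embedding + positional encoding), (T, d)."""
        check_is_fitted(self, "params_")
        tokens = self._as_tokens(seq)
        return enc.embed_tokens(self.params_, self.config_, tokens.token_ids)

    def embedding_baseline(self, seq) -> np.ndarray:
        """Zero-information input: positional encoding with no token signal.

        Used as the integration baseline by integrated gradients; keeping
        the fixed positional part avoids the scale-invariance pathology of
        layer-normalised encoders at the origin.
        """
        check_is_fitted(self, "params_")
        tokens = self._as_tokens(seq)
        return enc.sinusoidal_encoding(tokens.length, self.config_.embed_dim)

    def logits_from_embeddings(self, x0: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "params_")
        logits, _, _ = enc.forward_from_embeddings(self.params_, self.config_, x0)
        return logits

    def input_gradient(self, x0: np.ndarray, target_idx: int):
        """Gradient of the target-class logit w.r.t. the input embeddings."""
        check_is_fitted(self, "params_")
        logits, _, cache = enc.forward_from_embeddings(
            self.params_, self.config_, x0, want_cache=True
        )
        dlogits = np.zeros_like(logits)
        dlogits[target_idx] = 1.0
        _, dx0 = enc.backward(self.params_, self.config_, cache, dlogits)
        return logits, dx0


# ----------------------------------------------------------------- wrappers

def train_classifier(train, valid, econf: EncoderConfig, tconf: TrainConfig):
    """Functional training entry point.

    ``train`` and ``valid`` are ``(sequences, labels)`` pairs. Returns the
    fitted :class:`TransformerECClassifier` and its per-epoch log.
    """
    est = TransformerECClassifier(
        n_layers=econf.n_layers,
        n_heads=econf.n_heads,
        embed_dim=econf.embed_dim,
        ff_dim=econf.ff_dim,
        max_len=econf.max_len,
        dropout_cls=tconf.dropout_cls,
        batch_size=tconf.batch_size,
        accumulation_steps=tconf.accumulation_steps,
        learning_rate=tconf.lr0,
        beta1=tconf.beta1,
        beta2=tconf.beta2,
        lr_decay=tconf.lr_decay,
        n_epochs=tconf.n_epochs,
        balance_sampling=tconf.balance_sampling,
        random_state=tconf.seed,
    )
    validation = None if valid is None else (valid[0], valid[1])
    est.fit(train[0], train[1], validation_data=validation)
    return est, est.history_


def predict(model: TransformerECClassifier, sequence) -> ClassifierOutput:
    """Evaluation-mode prediction for a single sequence."""
    return model.classify(sequence)
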