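"""Classical interpretability baselines under the importance-vector contract.

All methods score residues of one sequence and emit an
:class:`~attnzyme.importance.ImportanceVector` with special tokens stripped,
so they are directly comparable with the attention-aggregation family:

* gradient saliency and gradient-times-input (per-position Euclidean norm),
* integrated gradients (midpoint Riemann sum from an all-zero embedding
  baseline, satisfying the completeness axiom),
* attention last layer (head-averaged final map, column-mean readout),
* attention rollout (residual-mixed maps multiplied across layers, CLS row),
* a LIME-style perturbation surrogate (wildcard masking, exponential
  locality kernel on Hamming distance, weighted least squares),
* the score-shuffling null baseline.

Gradient-family methods need a differentiable model exposing
``embeddings(seq)``, ``logits_from_embeddings(x0)`` and
``input_gradient(x0, target_idx)``; the LIME baseline only needs
per-class probabilities and is model-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoder import AttentionCapture, TokenizedSequence, tokenize, WILDCARD
from .importance import ImportanceVector

__all__ = [
    "SaliencyConfig",
    "grad_saliency",
    "grad_x_input",
    "integrated_gradients",
    "attention_last_layer",
    "attention_rollout",
    "lime_saliency",
    "shuffled_baseline",
]


@dataclass(frozen=True)
class SaliencyConfig:
    """Shared knobs of the baseline methods.

    ``target_rule`` is ``"predicted"`` (explain the argmax class; gradient
    methods behave nearly class-agnostically anyway) or ``"given"`` with
    ``target_class`` set. ``lime_samples`` defaults to 5000 perturbed
    sequences per protein — the cost that makes LIME ~5000x slower than a
    plain prediction. ``lime_kernel_width_frac`` scales the exponential
    locality kernel width as a fraction of the sequence length.
    """

    target_rule: str = "predicted"
    target_class: object | None = None
    ig_steps: int = 50
    lime_samples: int = 5000
    lime_mask_rate: float = 0.3
    lime_kernel_width_frac: float = 0.25
    shuffle_reps: int = 10
    rollout_residual: float = 0.5
    attn_readout: str = "column_mean"
    seed: int = 0

    def __post_init__(self):
        if self.ig_steps < 1:
            raise ValueError("ig_steps must be >= 1")
        if self.lime_samples < 10:
            raise ValueError("lime_samples must be >= 10")
        if not 0.0 < self.lime_mask_rate < 1.0:
            raise ValueError("lime_mask_rate must be in (0, 1)")
        if self.shuffle_reps < 1:
            raise ValueError("shuffle_reps must be >= 1")
        if self.target_rule not in ("predicted", "given"):
            raise ValueError("target_rule must be 'predicted' or 'given'")
        if self.target_rule == "given" and self.target_class is None:
            raise ValueError("target_rule 'given' requires target_class")


def _as_tokens(model, seq) -> TokenizedSequence:
    if isinstance(seq, TokenizedSequence):
        return seq
    config = getattr(model, "config_", None)
    return tokenize(seq, config)


def _target_index(model, logits: np.ndarray, cfg: SaliencyConfig) -> int:
    if cfg.target_rule == "predicted":
        return int(np.argmax(logits))
    classes = getattr(model, "classes_", None)
    if classes is not None:
        hits = np.flatnonzero(np.asarray(classes, dtype=object) == cfg.target_class)
        if hits.size:
            return int(hits[0])
    return int(cfg.target_class)


def _strip(values: np.ndarray, tokens: TokenizedSequence, method: str,
           seq_id: str | None = None) -> ImportanceVector:
    kept = np.flatnonzero(~tokens.special_mask)
    positions = np.array([tokens.residue_map[int(i)] for i in kept])
    order = np.argsort(positions)
    return ImportanceVector(seq_id=seq_id, scores=np.asarray(values)[kept][order], method=method)


# ------------------------------------------------------------ gradient family

def grad_saliency(model, seq, cfg: SaliencyConfig = SaliencyConfig(),
                  seq_id: str | None = None) -> ImportanceVector:
    """Euclidean norm of d(target logit)/d(input embedding) per residue."""
    tokens = _as_tokens(model, seq)
    x0 = model.embeddings(tokens)
    logits, dx0 = model.input_gradient(x0, _target_index(model, model.logits_from_embeddings(x0), cfg))
    if not np.all(np.isfinite(dx0)):
        raise FloatingPointError("non-finite gradients in saliency computation")
    return _strip(np.linalg.norm(dx0, axis=1), tokens, "Grad", seq_id)


def grad_x_input(model, seq, cfg: SaliencyConfig = SaliencyConfig(),
                 seq_id: str | None = None) -> ImportanceVector:
    """Norm of the elementwise product gradient * input embedding."""
    tokens = _as_tokens(model, seq)
    x0 = model.embeddings(tokens)
    logits, dx0 = model.input_gradient(x0, _target_index(model, model.logits_from_embeddings(x0), cfg))
    if not np.all(np.isfinite(dx0)):
        raise FloatingPointError("non-finite gradients in saliency computation")
    return _strip(np.linalg.norm(dx0 * x0, axis=1), tokens, "Grad X input", seq_id)


def integrated_gradients(model, seq, cfg: SaliencyConfig = SaliencyConfig(),
                         seq_id: str | None = None, return_raw: bool = False):
    """Path integral of gradients from a zero-information baseline.

    The baseline zeroes the token embeddings but keeps any fixed positional
    encoding (models expose it via ``embedding_baseline``; absent that, an
    all-zero baseline is used). Keeping the positional part matters for
    layer-normalised encoders: they are nearly scale-invariant, so a fully
    zero baseline concentrates the whole path integral in a vanishing
    neighbourhood of the origin and the completeness axiom becomes
    numerically unattainable. Uses the midpoint Riemann rule with
    ``cfg.ig_steps`` steps (a single step is one midpoint gradient); the
    signed per-position attribution sums converge to
    ``logit(input) - logit(baseline)``.
    """
    tokens = _as_tokens(model, seq)
    x0 = model.embeddings(tokens)
    base_fn = getattr(model, "embedding_baseline", None)
    base = base_fn(tokens) if base_fn is not None else np.zeros_like(x0)
    delta = x0 - base
    logits0 = model.logits_from_embeddings(x0)
    target = _target_index(model, logits0, cfg)
    m = cfg.ig_steps
    total = np.zeros_like(x0)
    for k in range(m):
        alpha = (k + 0.5) / m
        _, g = model.input_gradient(base + alpha * delta, target)
        total += g
    attributions = delta * total / m
    if not np.all(np.isfinite(attributions)):
        raise FloatingPointError("non-finite attributions in integrated gradients")
    iv = _strip(np.linalg.norm(attributions, axis=1), tokens, "Integrated grad", seq_id)
    if return_raw:
        return iv, attributions
    return iv


# ----------------------------------------------------------- attention family

def attention_last_layer(capture: AttentionCapture, cfg: SaliencyConfig = SaliencyConfig(),
                         seq_id: str | None = None) -> ImportanceVector:
    """Head-averaged final-layer attention map, read out per residue.

    The default readout is the column mean — the mean attention a token
    receives — which makes the single-layer single-head case coincide with
    AttnAgg1A1A. A ``cls_row`` readout (attention paid by the CLS token) is
    available via the config.
    """
    last = capture.layer_head_maps()[-1].mean(axis=0)  # (T, T)
    if cfg.attn_readout == "column_mean":
        values = last.mean(axis=0)
    elif cfg.attn_readout == "cls_row":
        cls_idx = int(np.flatnonzero(capture.special_mask)[0])
        values = last[cls_idx]
    else:
        raise ValueError(f"unknown attn_readout {cfg.attn_readout!r}")
    from .aggregation import strip_special_tokens

    iv = strip_special_tokens(values, capture, method="Attn last layer")
    iv.seq_id = seq_id if seq_id is not None else capture.seq_id
    return iv


def attention_rollout(capture: AttentionCapture, cfg: SaliencyConfig = SaliencyConfig(),
                      seq_id: str | None = None) -> ImportanceVector:
    """Attention flow approximated by multiplying residual-mixed maps.

    Per layer the head-averaged map A is replaced by the row-normalised
    mixture ``(1-r) * A + r * I`` (r = ``rollout_residual``), the mixtures
    are multiplied from the first to the last layer, and the CLS row of the
    product gives the attention each token ultimately receives from the
    classification readout.
    """
    if not capture.special_mask.any():
        raise ValueError("attention rollout needs a CLS token as readout row; "
                         "this capture has no special tokens")
    maps = capture.layer_head_maps().mean(axis=1)  # (L, T, T)
    r = cfg.rollout_residual
    eye = np.eye(maps.shape[-1])
    rollout = None
    for a in maps:
        mixed = (1.0 - r) * a + r * eye
        row_sums = mixed.sum(axis=1, keepdims=True)
        if np.any(row_sums <= 0):
            raise ValueError("cannot row-normalise a map with a zero row")
        mixed = mixed / row_sums
        rollout = mixed if rollout is None else mixed @ rollout
    cls_idx = int(np.flatnonzero(capture.special_mask)[0])
    values = rollout[cls_idx]
    from .aggregation import strip_special_tokens

    iv = strip_special_tokens(values, capture, method="Rollout")
    iv.seq_id = seq_id if seq_id is not None else capture.seq_id
    return iv


# ------------------------------------------------------------------ LIME-style

def _prob_fn(model, target_idx: int):
    if callable(model) and not hasattr(model, "classify"):
        return lambda s: float(np.asarray(model(s)).ravel()[target_idx])
    return lambda s: float(model.classify(s).probabilities[target_idx])


def lime_saliency(model, seq: str, cfg: SaliencyConfig = SaliencyConfig(),
                  seq_id: str | None = None) -> ImportanceVector:
    """Local linear surrogate fitted to wildcard-masked perturbations.

    Each perturbation keeps every residue independently with probability
    ``1 - lime_mask_rate`` (masked residues become the wildcard symbol); a
    weighted least-squares fit of the target-class probability on the
    binary presence matrix, with weights ``exp(-hamming / width)`` and
    width ``lime_kernel_width_frac * len(seq)``, gives one signed
    coefficient per residue.
    """
    if not isinstance(seq, str):
        raise TypeError("lime_saliency perturbs raw residue strings")
    n = len(seq)
    rng = np.random.default_rng(cfg.seed)
    probs_now = (
        model(seq) if callable(model) and not hasattr(model, "classify")
        else model.classify(seq).probabilities
    )
    target = _target_index(model, np.asarray(probs_now, dtype=float), cfg)
    predict = _prob_fn(model, target)

    keep = rng.random((cfg.lime_samples, n)) >= cfg.lime_mask_rate
    keep[0] = True  # anchor the fit at the unperturbed sequence
    y = np.empty(cfg.lime_samples)
    chars = np.array(list(seq))
    for i, row in enumerate(keep):
        perturbed = chars.copy()
        perturbed[~row] = WILDCARD
        y[i] = predict("".join(perturbed))
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite model probabilities during LIME sampling")

    hamming = n - keep.sum(axis=1)
    width = max(cfg.lime_kernel_width_frac * n, 1e-12)
    w = np.exp(-hamming / width)

    z = keep.astype(float)
    variable = z.std(axis=0) > 0
    if not variable.all():
        warnings.warn(
            f"{int((~variable).sum())} residue column(s) constant across LIME "
            "perturbations; their coefficients are set to 0",
            UserWarning,
        )
    design = np.column_stack([np.ones(cfg.lime_samples), z[:, variable]])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    coefs = np.zeros(n)
    coefs[variable] = beta[1:]
    return ImportanceVector(seq_id=seq_id, scores=coefs, method="LIME")


# ------------------------------------------------------------------- baseline

def shuffled_baseline(
    importances: list[ImportanceVector], cfg: SaliencyConfig = SaliencyConfig()
) -> list[list[ImportanceVector]]:
    """Null method: permute each sequence's scores uniformly at random.

    Returns one list of shuffled importance vectors per repetition;
    downstream metrics over the repetitions are reported as mean +/- sd.
    """
    rng = np.random.default_rng(cfg.seed)
    reps = []
    for _ in range(cfg.shuffle_reps):
        shuffled = [
            ImportanceVector(
                seq_id=iv.seq_id,
                scores=rng.permutation(iv.scores),
                method=f"Random ({iv.method})",
            )
            for iv in importances
        ]
        reps.append(shuffled)
    return reps
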