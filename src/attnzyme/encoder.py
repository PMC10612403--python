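"""Minimal self-attention (transformer) encoder with a CLS classification head.

The encoder is written directly in numpy with manual backpropagation so that
(i) every attention map can be captured as a row-stochastic tensor for the
interpretability modules and (ii) gradients with respect to the input
embeddings are available for the saliency baselines.

Architecture: token embedding + fixed sinusoidal positional encoding, then
``n_layers`` post-norm transformer blocks (multi-head self-attention and a
GELU feed-forward, each with a residual connection followed by layer
normalisation), a layer-norm on the final CLS embedding, dropout on that CLS
embedding only during training, and a linear projection to class logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
from scipy.special import ndtr

__all__ = [
    "AMINO_ACIDS",
    "WILDCARD",
    "CLS_TOKEN",
    "PAD_TOKEN",
    "DEFAULT_VOCAB",
    "EncoderConfig",
    "TokenizedSequence",
    "AttentionCapture",
    "tokenize",
    "sinusoidal_encoding",
    "init_params",
    "forward_from_embeddings",
    "forward_tokens",
    "backward",
    "cross_entropy",
    "softmax",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD = "X"
CLS_TOKEN = "<cls>"
PAD_TOKEN = "<pad>"
#: padding + CLS + the 20 standard amino acids + wildcard for ambiguous residues
DEFAULT_VOCAB: tuple[str, ...] = (PAD_TOKEN, CLS_TOKEN) + tuple(AMINO_ACIDS) + (WILDCARD,)

_LN_EPS = 1e-5
_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class EncoderConfig:
    """Hyper-parameters of the encoder (L layers, H heads per layer)."""

    n_layers: int = 2
    n_heads: int = 4
    embed_dim: int = 64
    ff_dim: int = 128
    max_len: int = 1024
    vocab: tuple[str, ...] = DEFAULT_VOCAB

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.n_heads < 1 or self.embed_dim < 1 or self.ff_dim < 1:
            raise ValueError("n_layers, n_heads, embed_dim and ff_dim must be positive")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim ({self.embed_dim}) must be divisible by n_heads ({self.n_heads})"
            )
        if self.max_len < 2:
            raise ValueError("max_len must be at least 2")
        if len(set(self.vocab)) != len(self.vocab):
            raise ValueError("vocab contains duplicate symbols")
        for special in (CLS_TOKEN, WILDCARD):
            if special not in self.vocab:
                raise ValueError(f"vocab must contain the {special!r} token")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads

    def token_index(self) -> dict[str, int]:
        return {tok: i for i, tok in enumerate(self.vocab)}


@dataclass
class TokenizedSequence:
    """A residue string turned into encoder tokens, with one CLS token added
    at the front (so its positional encoding is the same for every sequence).

    ``residue_map`` maps the 0-based token index of each residue token to its
    1-based position in the original sequence; special tokens are absent from
    the map and flagged in ``special_mask``.
    """

    tokens: list[str]
    token_ids: np.ndarray
    residue_map: dict[int, int]
    special_mask: np.ndarray

    @property
    def length(self) -> int:
        return len(self.tokens)

    @property
    def n_residues(self) -> int:
        return len(self.residue_map)


@dataclass
class AttentionCapture:
    """All attention maps of one forward pass, shape ``(L*H, T, T)``.

    Axis 0 enumerates layer-major head slots (layer 0 heads first). Axis 1
    indexes the attending (query) token, axis 2 the attended (key) token;
    each row over the last axis is softmax-normalised, so the attention
    *received* by token j is column j.
    """

    tensor: np.ndarray
    special_mask: np.ndarray
    n_layers: int
    n_heads: int
    residue_map: dict[int, int] = field(default_factory=dict)
    seq_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, dtype=float)
        if t.ndim != 3 or t.shape[1] != t.shape[2]:
            raise ValueError(f"attention tensor must have shape (L*H, T, T), got {t.shape}")
        if t.shape[0] != self.n_layers * self.n_heads:
            raise ValueError("first axis must equal n_layers * n_heads")
        if np.any(t < -1e-12):
            raise ValueError("attention weights must be non-negative")
        rows = t.sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=1e-5):
            raise ValueError("every attention row must sum to 1 (within 1e-5)")
        self.tensor = t
        self.special_mask = np.asarray(self.special_mask, dtype=bool)
        if self.special_mask.shape != (t.shape[1],):
            raise ValueError("special_mask length must equal the token count")

    @property
    def n_tokens(self) -> int:
        return self.tensor.shape[1]

    def layer_head_maps(self) -> np.ndarray:
        """View of the tensor reshaped to ``(L, H, T, T)``."""
        lh, t, _ = self.tensor.shape
        return self.tensor.reshape(self.n_layers, self.n_heads, t, t)


def tokenize(sequence: str, config: EncoderConfig | None = None) -> TokenizedSequence:
    """Tokenize a residue string and add the CLS token at the front.

    Ambiguous residue letters outside the 20 standard amino acids (B, J, O,
    U, Z, ...) map to the wildcard symbol ``X``; non-letter characters are
    rejected.
    """
    config = config or EncoderConfig()
    if not sequence:
        raise ValueError("cannot tokenize an empty sequence")
    limit = config.max_len - 1
    if len(sequence) > limit:
        raise ValueError(
            f"sequence of length {len(sequence)} exceeds the maximum of {limit} residues "
            f"(max_len={config.max_len} minus one CLS token)"
        )
    index = config.token_index()
    tokens: list[str] = [CLS_TOKEN]
    residue_map: dict[int, int] = {}
    for pos, ch in enumerate(sequence.upper(), start=1):
        if not ch.isalpha():
            raise ValueError(f"invalid residue symbol {ch!r} at position {pos}")
        tok = ch if ch in index else WILDCARD
        residue_map[len(tokens)] = pos
        tokens.append(tok)
    token_ids = np.array([index[t] for t in tokens], dtype=np.int64)
    special_mask = np.zeros(len(tokens), dtype=bool)
    special_mask[0] = True
    return TokenizedSequence(tokens, token_ids, residue_map, special_mask)


def sinusoidal_encoding(length: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding, shape ``(length, dim)``."""
    pos = np.arange(length, dtype=float)[:, None]
    i = np.arange(dim // 2, dtype=float)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / dim)
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    return enc


def init_params(
    config: EncoderConfig, n_classes: int, rng: np.random.Generator, init_scale: float = 0.02
) -> dict[str, np.ndarray]:
    """Gaussian(0, ``init_scale``) weight init; layer-norm gains 1, biases 0."""
    d, f = config.embed_dim, config.ff_dim

    def w(*shape: int) -> np.ndarray:
        return rng.normal(0.0, init_scale, size=shape)

    params: dict[str, np.ndarray] = {"embed": w(len(config.vocab), d)}
    for l in range(config.n_layers):
        p = f"l{l}."
        for name in ("wq", "wk", "wv", "wo"):
            params[p + name] = w(d, d)
        for name in ("bq", "bk", "bv", "bo"):
            params[p + name] = np.zeros(d)
        params[p + "ln1_g"] = np.ones(d)
        params[p + "ln1_b"] = np.zeros(d)
        params[p + "w1"] = w(d, f)
        params[p + "b1"] = np.zeros(f)
        params[p + "w2"] = w(f, d)
        params[p + "b2"] = np.zeros(d)
        params[p + "ln2_g"] = np.ones(d)
        params[p + "ln2_b"] = np.zeros(d)
    params["lnf_g"] = np.ones(d)
    params["lnf_b"] = np.zeros(d)
    params["wc"] = w(d, n_classes)
    params["bc"] = np.zeros(n_classes)
    return params


def _layernorm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)

def _layernorm_bwd(dy: np.ndarray, g: np.ndarray, cache):
    xhat, inv = cache
    dg = (dy * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
    db = dy.reshape(-1, xhat.shape[-1]).sum(axis=0)
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _gelu(x: np.ndarray) -> np.ndarray:
    return x * ndtr(x)

def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return ndtr(x) + x * np.exp(-0.5 * x * x) / _SQRT_2PI


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def embed_tokens(params: dict, config: EncoderConfig, token_ids: np.ndarray) -> np.ndarray:
    """Token embedding (scaled by sqrt(d)) plus sinusoidal positional encoding.

    The sqrt(d) factor is the usual convention that keeps the token signal
    comparable in magnitude to the O(1) positional encoding.
    """
    t = len(token_ids)
    scale = np.sqrt(config.embed_dim)
    return params["embed"][token_ids] * scale + sinusoidal_encoding(t, config.embed_dim)


def forward_from_embeddings(
    params: dict,
    config: EncoderConfig,
    x0: np.ndarray,
    *,
    cls_index: int | None = None,
    dropout_mask: np.ndarray | None = None,
    want_cache: bool = False,
    want_attention: bool = False,
):
    """Run the encoder on input embeddings ``x0`` of shape (T, d).

    Returns ``(logits, attention, cache)`` where ``attention`` is an array of
    shape (L, H, T, T) if requested and ``cache`` holds every intermediate
    needed by :func:`backward`.
    """
    T, d = x0.shape
    if d != config.embed_dim:
        raise ValueError(f"embedding dim {d} does not match config embed_dim {config.embed_dim}")
    H, dh = config.n_heads, config.head_dim
    cls = T - 1 if cls_index is None else cls_index
    scale = 1.0 / np.sqrt(dh)

    x = x0
    layers = []
    attn_maps = [] if want_attention else None
    for l in range(config.n_layers):
        p = f"l{l}."
        q = (x @ params[p + "wq"] + params[p + "bq"]).reshape(T, H, dh).transpose(1, 0, 2)
        k = (x @ params[p + "wk"] + params[p + "bk"]).reshape(T, H, dh).transpose(1, 0, 2)
        v = (x @ params[p + "wv"] + params[p + "bv"]).reshape(T, H, dh).transpose(1, 0, 2)
        scores = (q @ k.transpose(0, 2, 1)) * scale
        a = softmax(scores, axis=-1)  # (H, T, T), rows over keys
        if want_attention:
            attn_maps.append(a)
        ctx = (a @ v).transpose(1, 0, 2).reshape(T, d)
        attn_out = ctx @ params[p + "wo"] + params[p + "bo"]
        r1 = x + attn_out
        h1, ln1c = _layernorm(r1, params[p + "ln1_g"], params[p + "ln1_b"])
        u = h1 @ params[p + "w1"] + params[p + "b1"]
        gact = _gelu(u)
        r2 = h1 + gact @ params[p + "w2"] + params[p + "b2"]
        h2, ln2c = _layernorm(r2, params[p + "ln2_g"], params[p + "ln2_b"])
        if want_cache:
            layers.append(
                dict(x_in=x, q=q, k=k, v=v, a=a, ctx=ctx, ln1c=ln1c, h1=h1, u=u,
                     gact=gact, ln2c=ln2c)
            )
        x = h2

    c0 = x[cls]
    cn, lnfc = _layernorm(c0, params["lnf_g"], params["lnf_b"])
    cd = cn if dropout_mask is None else cn * dropout_mask
    logits = cd @ params["wc"] + params["bc"]

    cache = None
    if want_cache:
        cache = dict(layers=layers, x_final=x, cls=cls, c0=c0, cn=cn, cd=cd,
                     lnfc=lnfc, dropout_mask=dropout_mask, T=T)
    attention = np.stack(attn_maps) if want_attention else None
    return logits, attention, cache


def forward_tokens(
    params: dict,
    config: EncoderConfig,
    tokens: TokenizedSequence,
    *,
    dropout_mask: np.ndarray | None = None,
    want_cache: bool = False,
    want_attention: bool = False,
):
    if tokens.token_ids.max() >= params["embed"].shape[0]:
        raise ValueError("token ids exceed the model's vocabulary size")
    x0 = embed_tokens(params, config, tokens.token_ids)
    cls = int(np.flatnonzero(tokens.special_mask)[-1])
    return forward_from_embeddings(
        params, config, x0, cls_index=cls, dropout_mask=dropout_mask,
        want_cache=want_cache, want_attention=want_attention,
    )


def backward(
    params: dict, config: EncoderConfig, cache: dict, dlogits: np.ndarray
):
    """Backpropagate ``dlogits`` through a cached forward pass.

    Returns ``(grads, dx0)``: gradients for every parameter and for the input
    embeddings (shape (T, d)).
    """
    H, dh, d = config.n_heads, config.head_dim, config.embed_dim
    T = cache["T"]
    scale = 1.0 / np.sqrt(dh)
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    grads["wc"] += np.outer(cache["cd"], dlogits)
    grads["bc"] += dlogits
    dcd = params["wc"] @ dlogits
    if cache["dropout_mask"] is not None:
        dcd = dcd * cache["dropout_mask"]
    dc0, dgf, dbf = _layernorm_bwd(dcd, params["lnf_g"], cache["lnfc"])
    grads["lnf_g"] += dgf
    grads["lnf_b"] += dbf

    dx = np.zeros((T, d))
    dx[cache["cls"]] = dc0

    for l in reversed(range(config.n_layers)):
        p = f"l{l}."
        c = cache["layers"][l]
        dr2, dg2, db2 = _layernorm_bwd(dx, params[p + "ln2_g"], c["ln2c"])
        grads[p + "ln2_g"] += dg2
        grads[p + "ln2_b"] += db2
        dh1 = dr2.copy()
        dgact = dr2 @ params[p + "w2"].T
        grads[p + "w2"] += c["gact"].T @ dr2
        grads[p + "b2"] += dr2.sum(axis=0)
        du = dgact * _gelu_grad(c["u"])
        grads[p + "w1"] += c["h1"].T @ du
        grads[p + "b1"] += du.sum(axis=0)
        dh1 += du @ params[p + "w1"].T
        dr1, dg1, db1 = _layernorm_bwd(dh1, params[p + "ln1_g"], c["ln1c"])
        grads[p + "ln1_g"] += dg1
        grads[p + "ln1_b"] += db1
        dx_in = dr1.copy()
        dattn_out = dr1
        grads[p + "wo"] += c["ctx"].T @ dattn_out
        grads[p + "bo"] += dattn_out.sum(axis=0)
        dctx = (dattn_out @ params[p + "wo"].T).reshape(T, H, dh).transpose(1, 0, 2)
        da = dctx @ c["v"].transpose(0, 2, 1)  # (H, T, T)
        dv = c["a"].transpose(0, 2, 1) @ dctx
        # softmax backward, row-wise over keys
        ds = c["a"] * (da - (da * c["a"]).sum(axis=-1, keepdims=True))
        dq = (ds @ c["k"]) * scale
        dk = (ds.transpose(0, 2, 1) @ c["q"]) * scale
        for name, dmat in (("wq", dq), ("wk", dk), ("wv", dv)):
            flat = dmat.transpose(1, 0, 2).reshape(T, d)
            grads[p + name] += c["x_in"].T @ flat
            grads[p + "b" + name[1]] += flat.sum(axis=0)
            dx_in += flat @ params[p + name].T
        dx = dx_in
    return grads, dx


def accumulate_embedding_grad(
    grads: dict, config: EncoderConfig, token_ids: np.ndarray, dx0: np.ndarray
) -> None:
    """Scatter the input-embedding gradient back into the embedding table.

    Includes the sqrt(d) factor applied by :func:`embed_tokens`.
    """
    np.add.at(grads["embed"], token_ids, dx0 * np.sqrt(config.embed_dim))


def cross_entropy(logits: np.ndarray, target: int):
    """Stable cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max()
    logp = z - np.log(np.exp(z).sum())
    probs = np.exp(logp)
    dlogits = probs.copy()
    dlogits[target] -= 1.0
    return -logp[target], dlogits
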