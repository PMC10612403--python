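"""Two-stage pooling of the attention tensor into per-residue importance.

The full attention stack of an encoder forward pass is a tensor of shape
``(L*H, T, T)``: axis 1 is the head slot (all heads of all layers), axis 2
the attending (query) token and axis 3 the attended (key) token, with each
row over the key axis softmax-normalised. An *aggregation variant* collapses
first one tensor axis (the head axis or the query axis) and then one axis of
the remaining matrix, using the arithmetic mean or the elementwise maximum
at each stage, yielding one score per surviving index.

``AttnAgg1A1A`` — average over heads, then average over queries — scores
each token by the mean attention it *receives* and is the variant that
tracks catalytic residues best. Enumerating both stage axes and both pooling
functions gives 16 nominal variants which collapse to 13 functionally
distinct ones: averaging commutes across stages (``1A1A`` == ``2A1A``, and
likewise for the double maximum), and the variants that average over the key
axis of row-stochastic maps produce a constant (uninformative) score.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np

from .encoder import AttentionCapture
from .importance import ImportanceVector

__all__ = [
    "AggSpec",
    "ALL_SPECS",
    "AggregationResult",
    "aggregate",
    "strip_special_tokens",
    "attn_agg",
    "enumerate_variants",
    "VariantClass",
]

_FUNC = {"A": np.mean, "M": np.max}
_FUNC_NAME = {"A": "average", "M": "maximum"}
_NAME_RE = re.compile(r"^AttnAgg([12])([AM])([12])([AM])$")

#: semantics of the stage-1 axis code on the (head, query, key) tensor
_STAGE1_AXIS = {1: 0, 2: 1}

# after collapsing a tensor axis the remaining matrix keeps the other two
# axes in order; stage-2 axis 1/2 is the first/second axis of that matrix
_SURVIVOR = {
    # (stage1_axis, stage2_axis) -> surviving tensor axis name
    (1, 1): "key",    # matrix (query, key), collapse query  -> received attention
    (1, 2): "query",  # matrix (query, key), collapse key    -> given attention
    (2, 1): "key",    # matrix (head, key), collapse head    -> received attention
    (2, 2): "head",   # matrix (head, key), collapse key     -> head profile
}


@dataclass(frozen=True)
class AggSpec:
    """One member of the two-stage pooling family.

    ``stage1_axis``: 1 collapses the head axis of the tensor, 2 the first
    token (query) axis. ``stage2_axis``: 1 or 2, the axis of the remaining
    matrix. Functions are ``"A"`` (average) or ``"M"`` (maximum).
    """

    stage1_axis: int
    stage1_func: str
    stage2_axis: int
    stage2_func: str

    def __post_init__(self):
        if self.stage1_axis not in (1, 2) or self.stage2_axis not in (1, 2):
            raise ValueError("axes must be 1 or 2")
        if self.stage1_func not in _FUNC or self.stage2_func not in _FUNC:
            raise ValueError("pooling functions must be 'A' (average) or 'M' (maximum)")

    @property
    def name(self) -> str:
        return (
            f"AttnAgg{self.stage1_axis}{self.stage1_func}"
            f"{self.stage2_axis}{self.stage2_func}"
        )

    @classmethod
    def from_name(cls, name: str) -> "AggSpec":
        m = _NAME_RE.match(name)
        if not m:
            raise ValueError(f"not a valid aggregation variant name: {name!r}")
        return cls(int(m.group(1)), m.group(2), int(m.group(3)), m.group(4))

    @property
    def surviving_axis(self) -> str:
        """Which tensor axis the output vector is indexed by."""
        return _SURVIVOR[(self.stage1_axis, self.stage2_axis)]

    @property
    def degenerate(self) -> bool:
        """True when the output is a per-head profile rather than per-token."""
        return self.surviving_axis == "head"


#: the 16 nominal variants, in lexicographic name order
ALL_SPECS: tuple[AggSpec, ...] = tuple(
    AggSpec(a1, f1, a2, f2)
    for a1, f1, a2, f2 in itertools.product((1, 2), "AM", (1, 2), "AM")
)


@dataclass
class AggregationResult:
    """Raw (token-indexed) aggregation output plus provenance metadata."""

    values: np.ndarray
    spec: AggSpec
    surviving_axis: str
    degenerate: bool


def aggregate(capture: AttentionCapture | np.ndarray, spec: AggSpec) -> AggregationResult:
    """Apply a two-stage pooling variant to an attention tensor.

    Accepts either an :class:`AttentionCapture` or a bare ``(L*H, T, T)``
    array. The output stays token-indexed (CLS included); use
    :func:`strip_special_tokens` afterwards, matching the order of
    operations used for the variant family.
    """
    tensor = capture.tensor if isinstance(capture, AttentionCapture) else np.asarray(capture)
    if tensor.ndim != 3:
        raise ValueError(f"attention tensor must be 3-dimensional, got shape {tensor.shape}")
    f1 = _FUNC[spec.stage1_func]
    f2 = _FUNC[spec.stage2_func]
    matrix = f1(tensor, axis=_STAGE1_AXIS[spec.stage1_axis])
    vector = f2(matrix, axis=spec.stage2_axis - 1)
    return AggregationResult(
        values=np.asarray(vector, dtype=float),
        spec=spec,
        surviving_axis=spec.surviving_axis,
        degenerate=spec.degenerate,
    )


def strip_special_tokens(
    raw: np.ndarray | AggregationResult,
    capture: AttentionCapture,
    method: str | None = None,
) -> ImportanceVector:
    """Drop special-token scores and re-index to 1-based residue positions."""
    if isinstance(raw, AggregationResult):
        method = method or raw.spec.name
        raw = raw.values
    raw = np.asarray(raw, dtype=float)
    mask = capture.special_mask
    if raw.shape != mask.shape:
        raise ValueError(
            f"score vector of length {raw.size} does not match token count {mask.size}"
        )
    if mask.all():
        raise ValueError("capture has no residue tokens to keep")
    kept_idx = np.flatnonzero(~mask)
    if capture.residue_map:
        positions = np.array([capture.residue_map[int(i)] for i in kept_idx])
        order = np.argsort(positions)
        scores = raw[kept_idx][order]
    else:
        scores = raw[kept_idx]
    return ImportanceVector(
        seq_id=capture.seq_id, scores=scores, method=method or "aggregated"
    )


def attn_agg(
    capture: AttentionCapture, spec: AggSpec | str = "AttnAgg1A1A"
) -> ImportanceVector:
    """Aggregate and strip in one call (the usual entry point)."""
    if isinstance(spec, str):
        spec = AggSpec.from_name(spec)
    return strip_special_tokens(aggregate(capture, spec), capture)


@dataclass
class VariantClass:
    """An equivalence class of aggregation variants."""

    representative: AggSpec
    members: tuple[AggSpec, ...]
    constant: bool


def _probe_shapes(n_probe: int) -> list[tuple[int, int]]:
    # distinct head-count and token-count so axis mix-ups cannot alias
    shapes = [(6, 5), (8, 7), (4, 9)]
    return [shapes[i % len(shapes)] for i in range(n_probe)]


def enumerate_variants(n_probe: int = 100, seed: int = 0) -> list[VariantClass]:
    """Partition the 16 nominal variants into functional equivalence classes.

    Each variant is evaluated on ``n_probe`` random row-stochastic tensors
    (rows drawn from a flat Dirichlet). Two variants merge when their outputs
    agree within 1e-9 on every probe; variants whose output has zero variance
    on every probe are uninformative as rankings and merge into a single
    degenerate class. Under this convention the family has 13 classes.
    """
    if n_probe < 1:
        raise ValueError("n_probe must be >= 1")
    rng = np.random.default_rng(seed)
    probes = []
    for lh, t in _probe_shapes(n_probe):
        probes.append(rng.dirichlet(np.ones(t), size=(lh, t)))

    outputs: dict[AggSpec, list[np.ndarray]] = {
        spec: [aggregate(p, spec).values for p in probes] for spec in ALL_SPECS
    }
    constant = {
        spec: all(np.ptp(v) < 1e-9 for v in outs) for spec, outs in outputs.items()
    }

    def same(a: AggSpec, b: AggSpec) -> bool:
        return all(
            va.shape == vb.shape and np.max(np.abs(va - vb)) < 1e-9
            for va, vb in zip(outputs[a], outputs[b])
        )

    classes: list[list[AggSpec]] = []
    const_class: list[AggSpec] = []
    for spec in ALL_SPECS:
        if constant[spec]:
            const_class.append(spec)
            continue
        for cls in classes:
            if same(spec, cls[0]):
                cls.append(spec)
                break
        else:
            classes.append([spec])
    result = [
        VariantClass(representative=min(c, key=lambda s: s.name), members=tuple(c), constant=False)
        for c in classes
    ]
    if const_class:
        result.append(
            VariantClass(
                representative=min(const_class, key=lambda s: s.name),
                members=tuple(const_class),
                constant=True,
            )
        )
    result.sort(key=lambda vc: vc.representative.name)
    return result
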