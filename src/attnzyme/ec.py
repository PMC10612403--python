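"""EC-number data model and hierarchical evaluation.

EC numbers are four-level codes ``class.subclass.sub-subclass.serial`` with
the top-level class in 1..7 (7 = translocases, introduced in 2018). "Level
0" is the coarser enzyme vs non-enzyme discrimination. Predictions made at
level 4 are evaluated at every level by truncation; metrics are macro
(unweighted per-class averages over the classes present in the truth) so
that rare classes weigh as much as common ones.

Two evaluation protocols are supported: ``enzymes_only`` scores level 0 on
all sequences but levels 1-4 on true enzymes only, while ``all_sequences``
keeps the non-enzyme label as its own class at every level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

__all__ = [
    "ECLabel",
    "NON_ENZYME",
    "ENZYME",
    "LevelMetrics",
    "parse_ec",
    "truncate_level",
    "macro_metrics_at_level",
    "multi_level_report",
]

NON_ENZYME_TOKEN = "non-enzyme"
_MAX_CLASS = 7


@dataclass(frozen=True)
class ECLabel:
    """An EC code truncated to some depth, or the non-enzyme label.

    ``components`` holds the concrete numeric fields (unknown deeper levels,
    written as dashes, are simply absent); ``depth`` is their count. The
    distinguished non-enzyme label has ``enzyme=False`` and no components;
    a depth-0 *enzyme* label (the level-0 "is an enzyme" truncation) has
    ``enzyme=True`` and no components.
    """

    components: tuple = ()
    enzyme: bool = True

    def __post_init__(self):
        comps = tuple(int(c) for c in self.components)
        object.__setattr__(self, "components", comps)
        if not self.enzyme and comps:
            raise ValueError("the non-enzyme label carries no EC components")
        if len(comps) > 4:
            raise ValueError("EC numbers have at most four levels")
        if comps:
            if not 1 <= comps[0] <= _MAX_CLASS:
                raise ValueError(
                    f"EC class must be between 1 and {_MAX_CLASS}, got {comps[0]}"
                )
            if any(c < 1 for c in comps[1:]):
                raise ValueError("EC components must be positive integers")

    @property
    def depth(self) -> int:
        return len(self.components)

    @property
    def ec_class(self) -> int | None:
        return self.components[0] if self.components else None

    def __str__(self) -> str:
        if not self.enzyme:
            return NON_ENZYME_TOKEN
        if not self.components:
            return "enzyme"
        return ".".join(str(c) for c in self.components)


NON_ENZYME = ECLabel(components=(), enzyme=False)
ENZYME = ECLabel(components=(), enzyme=True)


def parse_ec(text: str) -> ECLabel:
    """Parse a dotted EC string (dashes for unknown deeper levels) or the
    non-enzyme token."""
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty EC label")
    t = text.strip()
    if t.lower() in (NON_ENZYME_TOKEN, "nonenzyme", "non_enzyme"):
        return NON_ENZYME
    if t.lower() == "enzyme":
        return ENZYME
    fields = t.split(".")
    if len(fields) > 4:
        raise ValueError(f"malformed EC number {text!r}: more than four fields")
    comps: list[int] = []
    seen_dash = False
    for f in fields:
        f = f.strip()
        if f == "-":
            seen_dash = True
            continue
        if seen_dash:
            raise ValueError(f"malformed EC number {text!r}: concrete field after a dash")
        if not f.isdigit():
            raise ValueError(f"malformed EC number {text!r}: field {f!r} is not numeric")
        comps.append(int(f))
    if not comps:
        raise ValueError(f"malformed EC number {text!r}: no concrete component")
    return ECLabel(components=tuple(comps), enzyme=True)


def truncate_level(label: ECLabel, level: int) -> ECLabel:
    """Truncate to a level in 0..4; non-enzyme is absorbing at every level."""
    if not 0 <= level <= 4:
        raise ValueError("level must be between 0 and 4")
    if not label.enzyme:
        return NON_ENZYME
    if level == 0:
        return ENZYME
    return ECLabel(components=label.components[:level], enzyme=True)


@dataclass(frozen=True)
class LevelMetrics:
    level: int
    macro_f1: float
    macro_precision: float
    macro_recall: float
    accuracy: float
    n_classes: int


def _as_label(x) -> ECLabel:
    return x if isinstance(x, ECLabel) else parse_ec(str(x))


def macro_metrics_at_level(
    truth, pred, level: int, include_nonenzyme: bool = True
) -> LevelMetrics:
    """Macro precision/recall/F1 and accuracy at one truncation level.

    The macro averages run over the classes present in the *truth* at that
    level (classes without truth support are excluded); per-class F1 with
    zero precision and recall counts as 0. With ``include_nonenzyme=False``
    pairs whose truth is non-enzyme are dropped first (the protocol that
    scores levels 1-4 on true enzymes only).
    """
    truth = [_as_label(t) for t in truth]
    pred = [_as_label(p) for p in pred]
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lists must be aligned")
    pairs = [
        (str(truncate_level(t, level)), str(truncate_level(p, level)))
        for t, p in zip(truth, pred)
        if include_nonenzyme or t.enzyme
    ]
    if not pairs:
        raise ValueError("no evaluation pairs left after filtering")
    y_true = np.array([a for a, _ in pairs], dtype=object)
    y_pred = np.array([b for _, b in pairs], dtype=object)
    classes = sorted(set(y_true))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="macro", zero_division=0
    )
    return LevelMetrics(
        level=level,
        macro_f1=float(f1),
        macro_precision=float(prec),
        macro_recall=float(rec),
        accuracy=float(np.mean(y_true == y_pred)),
        n_classes=len(classes),
    )


def multi_level_report(truth, pred_level4, protocol: str = "enzymes_only") -> dict:
    """LevelMetrics for levels 0-4, all derived from one level-4 prediction.

    ``enzymes_only``: level 0 on all sequences, levels 1-4 restricted to
    sequences whose truth is an enzyme. ``all_sequences``: every sequence at
    every level, the non-enzyme label acting as its own class.
    """
    if protocol not in ("enzymes_only", "all_sequences"):
        raise ValueError("protocol must be 'enzymes_only' or 'all_sequences'")
    report = {}
    for level in range(5):
        include = protocol == "all_sequences" or level == 0
        report[level] = macro_metrics_at_level(
            truth, pred_level4, level, include_nonenzyme=include
        )
    return report
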