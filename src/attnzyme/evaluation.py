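"""Evaluation of importance scores against catalytic-residue gold labels.

Catalytic residues are rare (about 1% of all residues), so ordinary
accuracy-style summaries are uninformative. This module provides the
metrics suited to that regime:

* top-k F1 curves (per-sequence F1 of the k most important residues,
  averaged over sequences, for k = 1..k_max),
* pooled precision-recall curves and their precision-recall-*gain*
  transform, where gain(x) = (x - pi) / ((1 - pi) * x) at prevalence pi,
  so that 0 marks the always-positive classifier and 1 perfection,
* the maximum F-Gain score over a global score threshold sweep, with a
  per-sequence rescaling step (min-max, z-score, L1, L2 or none),
* a one-sided exact binomial enrichment test for top-n hit counts,
* a comparison harness producing one report row per method plus the
  shuffled-score null baseline as mean +/- sd over repetitions.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.metrics import precision_recall_curve

from .importance import ImportanceVector

__all__ = [
    "GoldAnnotation",
    "PRGCurve",
    "EnrichmentResult",
    "InterpReport",
    "RESCALE_MODES",
    "rescale_scores",
    "topk_f1_curve",
    "pooled_pr_and_prg",
    "max_fgain",
    "enrichment_test",
    "compare_methods",
]


@dataclass(frozen=True)
class GoldAnnotation:
    """Catalytic-residue positions (1-based) of one protein."""

    seq_id: str
    catalytic_positions: frozenset
    protein_length: int

    def __post_init__(self):
        object.__setattr__(self, "catalytic_positions", frozenset(self.catalytic_positions))
        if self.protein_length < 1:
            raise ValueError("protein_length must be positive")
        for p in self.catalytic_positions:
            if not 1 <= p <= self.protein_length:
                raise ValueError(
                    f"catalytic position {p} outside [1, {self.protein_length}] for {self.seq_id}"
                )

    def label_vector(self) -> np.ndarray:
        y = np.zeros(self.protein_length, dtype=int)
        for p in self.catalytic_positions:
            y[p - 1] = 1
        return y


@dataclass
class PRGCurve:
    """Precision-gain vs recall-gain curve with its trapezoidal AUC."""

    points: np.ndarray  # (n, 2) columns: recall_gain, precision_gain
    prevalence: float
    auc: float


@dataclass(frozen=True)
class EnrichmentResult:
    p_value: float        # rounded to 5 decimals, as conventionally reported
    p_value_full: float


@dataclass
class InterpReport:
    """Table-shaped comparison of interpretability methods."""

    rows: dict = field(default_factory=dict)       # method -> dict of metrics
    baseline: dict | None = None                   # mean/std over shuffles
    rescale_mode: str = "none"

    def as_text(self) -> str:
        lines = [f"{'Method':<22}{'PRG-AUC (x100)':>16}{'Max F-Gain (%)':>16}{'Time (s)':>10}"]
        if self.baseline is not None:
            b = self.baseline
            lines.append(
                f"{'Random':<22}"
                f"{b['prg_auc_mean']:>10.2f}±{b['prg_auc_std']:<5.2f}"
                f"{b['max_fgain_mean']:>9.2f}±{b['max_fgain_std']:<5.2f}"
            )
        for name, row in self.rows.items():
            lines.append(
                f"{name:<22}{row['prg_auc']:>16.2f}{row['max_fgain']:>16.2f}"
                f"{row['runtime_s']:>10.2f}"
            )
        return "\n".join(lines)


RESCALE_MODES = ("none", "minmax", "zscore", "l1", "l2")


def rescale_scores(scores: np.ndarray, mode: str = "none") -> np.ndarray:
    """Per-sequence rescaling applied before pooling scores across proteins.

    Degenerate inputs (constant scores, zero norms) map to all-zero vectors.
    """
    x = np.asarray(scores, dtype=float)
    if mode == "none":
        return x
    if mode == "minmax":
        span = x.max() - x.min()
        return (x - x.min()) / span if span > 0 else np.zeros_like(x)
    if mode == "zscore":
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    if mode == "l1":
        norm = np.abs(x).sum()
        return x / norm if norm > 0 else np.zeros_like(x)
    if mode == "l2":
        norm = np.sqrt((x * x).sum())
        return x / norm if norm > 0 else np.zeros_like(x)
    raise ValueError(f"unknown rescale mode {mode!r}; choose from {RESCALE_MODES}")


def _match_gold(importances, gold: dict, *, error_on_missing_method: bool = False):
    """Pair importance vectors with gold annotations by sequence id."""
    matched = []
    covered = set()
    for iv in importances:
        g = gold.get(iv.seq_id)
        if g is None:
            warnings.warn(
                f"sequence {iv.seq_id!r} has no gold annotation and is excluded",
                UserWarning,
            )
            continue
        if len(iv) != g.protein_length:
            raise ValueError(
                f"importance vector for {iv.seq_id!r} has {len(iv)} residues, "
                f"gold says {g.protein_length}"
            )
        matched.append((iv, g))
        covered.add(iv.seq_id)
    if error_on_missing_method:
        missing = sorted(set(gold) - covered)
        if missing:
            raise ValueError(f"method output missing sequence(s) present in gold: {missing}")
    if not matched:
        raise ValueError("no importance vector could be matched to a gold annotation")
    return matched


# ------------------------------------------------------------------ top-k F1

def topk_f1_curve(importances, gold: dict, k_max: int = 50) -> np.ndarray:
    """Mean per-sequence F1 of the top-k residues, for k = 1..k_max.

    F1 at k is 2*TP / (k + n_gold); ties in the score ranking are broken by
    ascending position.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    matched = _match_gold(importances, gold)
    curve = np.zeros(k_max)
    for k in range(1, k_max + 1):
        f1s = []
        for iv, g in matched:
            top = set(iv.top_k(k).tolist())
            tp = len(top & g.catalytic_positions)
            denom = k + len(g.catalytic_positions)
            f1s.append(2.0 * tp / denom if denom else 0.0)
        curve[k - 1] = np.mean(f1s)
    return curve


# --------------------------------------------------------------- PRG curves

def _pool(matched, rescale_mode: str):
    scores = np.concatenate([rescale_scores(iv.scores, rescale_mode) for iv, _ in matched])
    labels = np.concatenate([g.label_vector() for _, g in matched])
    return scores, labels


def _gain(x: np.ndarray, pi: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return (x - pi) / ((1.0 - pi) * x)


def _prg_from_scores(scores: np.ndarray, labels: np.ndarray) -> PRGCurve:
    pi = labels.mean()
    if pi <= 0.0 or pi >= 1.0:
        raise ValueError(f"prevalence must lie strictly between 0 and 1, got {pi}")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # drop the (precision=1, recall=0) sentinel and order by increasing recall
    precision, recall = precision[:-1][::-1], recall[:-1][::-1]
    keep = recall > 0
    precision, recall = precision[keep], recall[keep]
    rg = _gain(recall, pi)
    pg = np.clip(_gain(precision, pi), 0.0, 1.0)

    pts_x: list[float] = []
    pts_y: list[float] = []
    for i in range(len(rg)):
        if rg[i] < 0:
            continue
        if not pts_x and i > 0 and rg[i - 1] < 0:
            # linear interpolation of the segment crossing recall_gain = 0
            t = (0.0 - rg[i - 1]) / (rg[i] - rg[i - 1])
            pts_x.append(0.0)
            pts_y.append(pg[i - 1] + t * (pg[i] - pg[i - 1]))
        pts_x.append(float(rg[i]))
        pts_y.append(float(pg[i]))
    if not pts_x:
        return PRGCurve(points=np.empty((0, 2)), prevalence=float(pi), auc=0.0)
    if pts_x[0] > 0.0:
        # no observed point below the always-positive recall: extend flat
        pts_x.insert(0, 0.0)
        pts_y.insert(0, pts_y[0])
    x = np.asarray(pts_x)
    y = np.asarray(pts_y)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    auc = float(np.trapezoid(y, x))
    return PRGCurve(points=np.column_stack([x, y]), prevalence=float(pi), auc=auc)


def pooled_pr_and_prg(
    importances, gold: dict, rescale_mode: str = "none", per_protein: bool = False
):
    """Precision-recall-gain curve of the pooled (corpus-level) ranking.

    Scores are rescaled per sequence, then pooled across all residues of all
    sequences; prevalence is computed from the pooled gold labels. With
    ``per_protein`` a dict of per-sequence curves is returned alongside.
    """
    matched = _match_gold(importances, gold)
    scores, labels = _pool(matched, rescale_mode)
    pooled = _prg_from_scores(scores, labels)
    if not per_protein:
        return pooled
    per = {}
    for iv, g in matched:
        try:
            per[iv.seq_id] = _prg_from_scores(
                rescale_scores(iv.scores, rescale_mode), g.label_vector()
            )
        except ValueError:
            continue  # sequences with no (or all) gold labels have no curve
    return pooled, per


# -------------------------------------------------------------- max F-Gain

def _f1(tp: int, n_pos: int, n_gold: int) -> float:
    denom = n_pos + n_gold
    return 2.0 * tp / denom if denom else 0.0


def max_fgain(importances, gold: dict, rescale_mode: str = "none"):
    """Maximum gain-transformed F1 over a global threshold sweep.

    Residues with a (rescaled, pooled) score strictly above the threshold
    count as predicted-catalytic; thresholds run over every unique score and
    +inf. The best F1 is mapped to gain space via (F1 - pi)/((1 - pi)*F1),
    clipped below at 0 (no better than the always-positive reference), and
    reported as a percentage together with the achieving threshold.
    """
    matched = _match_gold(importances, gold)
    scores, labels = _pool(matched, rescale_mode)
    pi = labels.mean()
    if pi <= 0.0:
        raise ValueError("gold labels are empty across the whole set")
    if pi >= 1.0:
        raise ValueError("every residue is gold-labelled; gains are undefined")
    n_gold = int(labels.sum())

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tp_cum = np.cumsum(labels[order])
    best_gain, best_thr = 0.0, np.inf
    # last index of each distinct-score group, descending order; the final
    # group is unreachable ("score > threshold" with thresholds at unique
    # scores never selects everything), so the sweep stops before it
    uniq_last = np.flatnonzero(np.diff(sorted_scores, append=-np.inf))
    for idx in uniq_last[:-1]:
        f1 = _f1(int(tp_cum[idx]), idx + 1, n_gold)
        if f1 > 0:
            gain = (f1 - pi) / ((1.0 - pi) * f1)
            if gain > best_gain:
                best_gain = gain
                best_thr = sorted_scores[idx + 1]  # next distinct score down
    return 100.0 * best_gain, best_thr


# --------------------------------------------------------- enrichment test

def enrichment_test(hits: int, top_n: int, annotated: int, length: int) -> EnrichmentResult:
    """One-sided exact binomial tail for annotation enrichment in a top list.

    With ``annotated`` of ``length`` residues carrying an annotation, the
    probability of observing at least ``hits`` annotated residues among the
    ``top_n`` most important ones under the null (uniform pick, rate
    annotated/length) is P(X >= hits), X ~ Binomial(top_n, annotated/length).
    """
    if not 0 <= hits <= top_n <= length:
        raise ValueError("need 0 <= hits <= top_n <= length")
    if not 0 < annotated < length:
        raise ValueError("need 0 < annotated < length")
    p = annotated / length
    full = float(binom.sf(hits - 1, top_n, p))
    return EnrichmentResult(p_value=round(full, 5), p_value_full=full)


# --------------------------------------------------------- method comparison

def compare_methods(
    method_outputs: dict,
    gold: dict,
    rescale_mode: str = "none",
    shuffle_reps: int = 10,
    seed: int = 0,
) -> InterpReport:
    """One report row (PRG-AUC x100, max F-Gain %, runtime) per method.

    The shuffled-score null baseline is derived from the first method's
    importance vectors and reported as mean +/- sd over ``shuffle_reps``
    repetitions. Every method must cover every gold-annotated sequence.
    """
    if not method_outputs:
        raise ValueError("compare_methods requires at least one method")
    from .saliency import SaliencyConfig, shuffled_baseline

    report = InterpReport(rescale_mode=rescale_mode)
    for name, importances in method_outputs.items():
        _match_gold(importances, gold, error_on_missing_method=True)
        t0 = time.perf_counter()
        prg = pooled_pr_and_prg(importances, gold, rescale_mode)
        fgain, _ = max_fgain(importances, gold, rescale_mode)
        elapsed = time.perf_counter() - t0
        report.rows[name] = {
            "prg_auc": 100.0 * prg.auc,
            "max_fgain": fgain,
            "runtime_s": elapsed / max(len(importances), 1),
        }

    first = next(iter(method_outputs.values()))
    cfg = SaliencyConfig(shuffle_reps=shuffle_reps, seed=seed)
    aucs, gains = [], []
    for rep in shuffled_baseline(first, cfg):
        aucs.append(100.0 * pooled_pr_and_prg(rep, gold, rescale_mode).auc)
        gains.append(max_fgain(rep, gold, rescale_mode)[0])
    report.baseline = {
        "prg_auc_mean": float(np.mean(aucs)),
        "prg_auc_std": float(np.std(aucs)),
        "max_fgain_mean": float(np.mean(gains)),
        "max_fgain_std": float(np.std(gains)),
        "n_reps": shuffle_reps,
    }
    return report
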