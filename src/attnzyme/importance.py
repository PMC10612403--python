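"""Per-residue importance scores, the common currency of all interpretability
methods in this package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImportanceVector"]


@dataclass
class ImportanceVector:
    """Scores aligned to the residues of one sequence (special tokens removed).

    ``scores[i]`` is the importance of residue position ``i + 1`` (1-based).
    """

    seq_id: str | None
    scores: np.ndarray
    method: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if self.scores.size == 0:
            raise ValueError("importance vector must cover at least one residue")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("importance scores must be finite")

    def __len__(self) -> int:
        return self.scores.size

    def top_k(self, k: int) -> np.ndarray:
        """1-based positions of the k highest scores, ties broken by
        ascending position (stable)."""
        order = np.argsort(-self.scores, kind="stable")
        return order[:k] + 1
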