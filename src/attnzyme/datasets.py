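"""Time-based, identity-filtered benchmark construction.

The evaluation protocol tests on sequences annotated *after* a training
release, with an extra leakage guard: training and candidate test sequences
are clustered at a 40% identity threshold, every cluster touching the
training release is discarded, and one representative of each surviving
cluster enters the test set. Clustering is pluggable — the canonical path
consumes an externally produced two-column cluster table (as emitted by
large-scale clustering tools), while a built-in greedy aligner-based
clusterer covers desk-scale use without external binaries.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .ec import parse_ec

__all__ = [
    "SequenceRecord",
    "AnnotationRecord",
    "ClusterTable",
    "SplitConfig",
    "DatasetSplit",
    "assign_level0_labels",
    "pairwise_identity",
    "greedy_identity_cluster",
    "build_time_split",
    "apply_filters",
    "census",
]

_CLASS_NAMES = {
    1: "Oxidoreductases",
    2: "Transferases",
    3: "Hydrolases",
    4: "Lyases",
    5: "Isomerases",
    6: "Ligases",
    7: "Translocase",
}


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    release: str = "old"  # "old" = training release, "new" = later additions

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.release not in ("old", "new"):
            raise ValueError("release must be 'old' or 'new'")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRecord:
    id: str
    ec_labels: tuple = ()
    catalytic_go: bool = False

    def __post_init__(self):
        object.__setattr__(self, "ec_labels", tuple(self.ec_labels))


def assign_level0_labels(annotations) -> dict:
    """Enzyme / non-enzyme / excluded status per record id.

    Non-enzyme means *neither* an EC number *nor* a catalytic-activity GO
    flag. Records with the GO flag but no EC number are excluded: they are
    not non-enzymes, but carry no class label to train on either.
    """
    out = {}
    for ann in annotations:
        if ann.ec_labels:
            out[ann.id] = "enzyme"
        elif ann.catalytic_go:
            out[ann.id] = "excluded"
        else:
            out[ann.id] = "non-enzyme"
    return out


@dataclass
class ClusterTable:
    """Mapping of member id -> cluster representative id."""

    representative_of: dict

    def __post_init__(self):
        for member, rep in self.representative_of.items():
            if rep not in self.representative_of:
                raise ValueError(f"representative {rep!r} is not itself in the table")
            if self.representative_of[rep] != rep:
                raise ValueError(f"representative {rep!r} does not map to itself")

    def __getitem__(self, member: str) -> str:
        return self.representative_of[member]

    def __contains__(self, member: str) -> bool:
        return member in self.representative_of

    def clusters(self) -> dict:
        by_rep = defaultdict(list)
        for member, rep in self.representative_of.items():
            by_rep[rep].append(member)
        return {rep: sorted(members) for rep, members in by_rep.items()}


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    return a


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Identity = identical positions / alignment length under a global
    alignment with match 1, mismatch 0 and gap -1 scoring."""
    aln = _aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total if total else 0.0


def greedy_identity_cluster(records, threshold: float = 0.40) -> ClusterTable:
    """Length-sorted greedy clustering against cluster representatives.

    Records are visited by decreasing length (ties by id); each joins the
    first cluster whose representative shares at least ``threshold``
    identity, otherwise it founds a new cluster.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot cluster an empty record set")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[SequenceRecord] = []
    table: dict[str, str] = {}
    for rec in ordered:
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence) >= threshold:
                table[rec.id] = rep.id
                break
        else:
            reps.append(rec)
            table[rec.id] = rec.id
    return ClusterTable(table)


@dataclass(frozen=True)
class SplitConfig:
    """Filtering and splitting parameters.

    Length presets: the stricter protocol keeps 41..1024 residues ("more
    than 40 AA, up to 1024"), the alternative 40..1000 inclusive.
    """

    identity_threshold: float = 0.40
    min_len: int = 41
    max_len: int = 1024
    allowed_classes: tuple | None = None
    keep_all_training_members: bool = True
    validation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.identity_threshold < 1.0:
            raise ValueError("identity_threshold must be in (0, 1)")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.allowed_classes is not None:
            object.__setattr__(self, "allowed_classes", tuple(self.allowed_classes))

    @classmethod
    def ecpred_style(cls, **kw) -> "SplitConfig":
        return cls(min_len=41, max_len=1024, **kw)

    @classmethod
    def deepec_style(cls, **kw) -> "SplitConfig":
        return cls(min_len=40, max_len=1000, **kw)


@dataclass
class DatasetSplit:
    train_ids: list
    valid_ids: list
    test_ids: list
    discarded_clusters: list
    provenance: dict = field(default_factory=dict)


def build_time_split(
    train_records, new_records, clusters: ClusterTable, cfg: SplitConfig = SplitConfig()
) -> DatasetSplit:
    """Cluster-exclusion split: testing only on clusters untouched by the
    training release.

    Every cluster containing at least one training-release record is
    discarded from test candidacy; the longest sequence (ties by id) of each
    surviving cluster becomes a test record. All training-release records
    stay in training by default ("keep all"), otherwise one representative
    per training cluster. An optional validation fraction is drawn from the
    training records (training clusters only, so the test guarantee is
    unaffected).
    """
    train_records = list(train_records)
    new_records = list(new_records)
    by_id = {r.id: r for r in train_records + new_records}
    for rid in by_id:
        if rid not in clusters:
            raise ValueError(f"cluster table does not cover record {rid!r}")

    train_reps = {clusters[r.id] for r in train_records}
    surviving = defaultdict(list)
    for r in new_records:
        rep = clusters[r.id]
        if rep not in train_reps:
            surviving[rep].append(r)

    test_ids = [
        min(members, key=lambda r: (-len(r.sequence), r.id)).id
        for members in surviving.values()
    ]
    test_ids.sort()
    if not test_ids:
        warnings.warn("time-based split produced an empty test set", UserWarning)

    if cfg.keep_all_training_members:
        train_ids = sorted(r.id for r in train_records)
    else:
        per_cluster = defaultdict(list)
        for r in train_records:
            per_cluster[clusters[r.id]].append(r)
        train_ids = sorted(
            min(members, key=lambda r: (-len(r.sequence), r.id)).id
            for members in per_cluster.values()
        )

    valid_ids: list = []
    if cfg.validation_fraction > 0 and train_ids:
        rng = np.random.default_rng(cfg.seed)
        n_valid = int(round(cfg.validation_fraction * len(train_ids)))
        picked = rng.choice(len(train_ids), size=n_valid, replace=False)
        valid_set = {train_ids[i] for i in picked}
        valid_ids = sorted(valid_set)
        train_ids = [t for t in train_ids if t not in valid_set]

    discarded = sorted(
        {clusters[r.id] for r in new_records} & train_reps
    )
    return DatasetSplit(
        train_ids=train_ids,
        valid_ids=valid_ids,
        test_ids=test_ids,
        discarded_clusters=discarded,
        provenance={
            "identity_threshold": cfg.identity_threshold,
            "n_train_release": len(train_records),
            "n_new_release": len(new_records),
            "n_surviving_clusters": len(surviving),
            "n_discarded_clusters": len(discarded),
        },
    )


def apply_filters(records, cfg: SplitConfig, labels: dict | None = None):
    """Length and class filters; returns (kept records, removal counts).

    ``labels`` maps record id to an EC string (or the non-enzyme token).
    When ``cfg.allowed_classes`` is given, records carrying an EC label not
    in the list are removed (an explicitly empty list therefore removes
    every enzyme); non-enzyme records pass the class filter.
    """
    kept = []
    removed = {"length": 0, "class": 0}
    allowed = None
    if cfg.allowed_classes is not None:
        allowed = {str(parse_ec(c)) for c in cfg.allowed_classes}
    for rec in records:
        if not cfg.min_len <= len(rec.sequence) <= cfg.max_len:
            removed["length"] += 1
            continue
        if allowed is not None and labels is not None:
            lab = labels.get(rec.id)
            if lab is not None:
                parsed = parse_ec(str(lab))
                if parsed.enzyme and str(parsed) not in allowed:
                    removed["class"] += 1
                    continue
        kept.append(rec)
    return kept, removed


def census(split: DatasetSplit, labels: dict) -> pd.DataFrame:
    """Per-partition counts by EC first-level class, non-enzymes and total."""
    columns = ["Not an enzyme"] + [_CLASS_NAMES[c] for c in range(1, 8)] + ["Total"]
    rows = {}
    for part, ids in (
        ("training", split.train_ids),
        ("validation", split.valid_ids),
        ("testing", split.test_ids),
    ):
        counts = dict.fromkeys(columns, 0)
        for rid in ids:
            lab = parse_ec(str(labels[rid]))
            key = "Not an enzyme" if not lab.enzyme else _CLASS_NAMES[lab.ec_class]
            counts[key] += 1
            counts["Total"] += 1
        rows[part] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
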