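"""File formats: FASTA sequences, TSV tables, HDF5 model state, JSONL logs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import ClusterTable, DatasetSplit, SequenceRecord, AnnotationRecord
from .evaluation import GoldAnnotation
from .importance import ImportanceVector

__all__ = [
    "read_fasta", "write_fasta",
    "read_labels_tsv", "write_labels_tsv",
    "read_annotations_tsv", "write_annotations_tsv",
    "read_gold_tsv", "write_gold_tsv",
    "read_importance_tsv", "write_importance_tsv",
    "read_cluster_tsv", "write_cluster_tsv",
    "write_split_tsv", "read_split_tsv",
    "save_model", "load_model",
    "append_jsonl",
]


def read_fasta(path, release: str = "old") -> list[SequenceRecord]:
    return [
        SequenceRecord(id=rec.id, sequence=str(rec.seq), release=release)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description=r.release) for r in records),
        str(path),
        "fasta",
    )


def read_labels_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["id"], df["class"]))


def write_labels_tsv(labels: dict, path) -> None:
    pd.DataFrame(sorted(labels.items()), columns=["id", "class"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations_tsv(path) -> list[AnnotationRecord]:
    """Columns: id, ec (semicolon-joined, empty for none), catalytic_go (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        ecs = tuple(e for e in str(row["ec"]).split(";") if e)
        out.append(
            AnnotationRecord(
                id=row["id"], ec_labels=ecs, catalytic_go=str(row["catalytic_go"]) == "1"
            )
        )
    return out


def write_annotations_tsv(annotations, path) -> None:
    rows = [
        {"id": a.id, "ec": ";".join(a.ec_labels), "catalytic_go": int(a.catalytic_go)}
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gold_tsv(path, lengths: dict) -> dict:
    """Columns: id, position (1-based), residue. ``lengths`` supplies each
    protein's residue count."""
    df = pd.read_csv(path, sep="\t")
    gold = {}
    for rid, grp in df.groupby("id"):
        gold[str(rid)] = GoldAnnotation(
            seq_id=str(rid),
            catalytic_positions=frozenset(int(p) for p in grp["position"]),
            protein_length=int(lengths[str(rid)]),
        )
    return gold


def write_gold_tsv(gold: dict, sequences: dict, path) -> None:
    rows = []
    for rid in sorted(gold):
        seq = sequences.get(rid, "")
        for pos in sorted(gold[rid].catalytic_positions):
            residue = seq[pos - 1] if pos <= len(seq) else "?"
            rows.append({"id": rid, "position": pos, "residue": residue})
    pd.DataFrame(rows, columns=["id", "position", "residue"]).to_csv(
        path, sep="\t", index=False
    )


def write_importance_tsv(importances, sequences: dict, path) -> None:
    rows = []
    for iv in importances:
        seq = sequences.get(iv.seq_id, "")
        for i, score in enumerate(iv.scores, start=1):
            rows.append(
                {
                    "id": iv.seq_id,
                    "position": i,
                    "residue": seq[i - 1] if i <= len(seq) else "?",
                    "score": score,
                    "method": iv.method,
                }
            )
    pd.DataFrame(rows, columns=["id", "position", "residue", "score", "method"]).to_csv(
        path, sep="\t", index=False
    )


def read_importance_tsv(path) -> list[ImportanceVector]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (rid, method), grp in df.groupby(["id", "method"], sort=True):
        grp = grp.sort_values("position")
        out.append(
            ImportanceVector(seq_id=str(rid), scores=grp["score"].to_numpy(), method=str(method))
        )
    return out


def read_cluster_tsv(path) -> ClusterTable:
    """Two columns: representative, member (the external clustering format)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["representative", "member"], dtype=str)
    return ClusterTable(dict(zip(df["member"], df["representative"])))


def write_cluster_tsv(table: ClusterTable, path) -> None:
    rows = sorted((rep, member) for member, rep in table.representative_of.items())
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_split_tsv(split: DatasetSplit, path) -> None:
    rows = (
        [{"id": i, "partition": "train"} for i in split.train_ids]
        + [{"id": i, "partition": "valid"} for i in split.valid_ids]
        + [{"id": i, "partition": "test"} for i in split.test_ids]
    )
    pd.DataFrame(rows, columns=["id", "partition"]).to_csv(path, sep="\t", index=False)


def read_split_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["id"], df["partition"]))


def save_model(model, path) -> None:
    """Serialise a fitted classifier to an HDF5 container."""
    from .model import TransformerECClassifier  # noqa: F401  (documented type)

    with h5py.File(str(path), "w") as f:
        for k, v in model.params_.items():
            f.create_dataset(f"params/{k}", data=v)
        f.attrs["classes"] = json.dumps([str(c) for c in model.classes_])
        f.attrs["estimator_params"] = json.dumps(model.get_params())
        f.attrs["history"] = json.dumps(getattr(model, "history_", []))


def load_model(path):
    from .model import TransformerECClassifier

    with h5py.File(str(path), "r") as f:
        est = TransformerECClassifier(**json.loads(f.attrs["estimator_params"]))
        est.classes_ = np.array(json.loads(f.attrs["classes"]), dtype=object)
        est.params_ = {k: np.array(v) for k, v in f["params"].items()}
        est.history_ = json.loads(f.attrs["history"])
    from .encoder import EncoderConfig

    est.config_ = EncoderConfig(
        n_layers=est.n_layers, n_heads=est.n_heads, embed_dim=est.embed_dim,
        ff_dim=est.ff_dim, max_len=est.max_len,
    )
    return est


def append_jsonl(entry: dict, path) -> None:
    with open(path, "a") as f:
        f.write(json.dumps(entry) + "\n")
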