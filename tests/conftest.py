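"""Shared fixtures: a micro encoder for gradient checks and the full
seeded study run (motif-classed corpus -> training -> attention
interpretability) reused by the end-to-end tests."""

import numpy as np
import pytest

from attnzyme.aggregation import attn_agg
from attnzyme.encoder import EncoderConfig
from attnzyme.evaluation import compare_methods
from attnzyme.model import TransformerECClassifier
from attnzyme.synthetic import SyntheticSpec, gen_classified_sequences


@pytest.fixture(scope="session")
def micro_model():
    """A tiny initialised (untrained) classifier for gradient-based checks."""
    est = TransformerECClassifier(
        n_layers=1, n_heads=2, embed_dim=8, ff_dim=12, max_len=64,
        n_epochs=0, random_state=7,
    )
    rng = np.random.default_rng(3)
    X = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 12)) for _ in range(6)]
    y = ["1", "2", "3"] * 2
    est.fit(X, y)
    return est


@pytest.fixture(scope="session")
def study_corpus():
    """The default synthetic study corpus: 300 motif-classed sequences of
    380-460 residues (gold prevalence ~1.2%), 80/20 train/validation."""
    spec = SyntheticSpec(seed=0)
    records, labels, gold, motifs = gen_classified_sequences(spec)
    n = len(records)
    split = int(0.8 * n)
    return {
        "spec": spec,
        "records": records,
        "labels": labels,
        "gold": gold,
        "motifs": motifs,
        "train_idx": list(range(split)),
        "valid_idx": list(range(split, n)),
    }


@pytest.fixture(scope="session")
def study_model(study_corpus):
    """The seeded end-to-end training run on the study corpus.

    Training configuration: the reference recipe except a from-scratch
    learning rate (1e-3) and no gradient accumulation (300 examples give
    too few optimizer steps at effective batch 32).
    """
    c = study_corpus
    X = [r.sequence for r in c["records"]]
    y = np.array([c["labels"][r.id] for r in c["records"]], dtype=object)
    est = TransformerECClassifier(
        learning_rate=1e-3, accumulation_steps=1, n_epochs=10,
        balance_sampling=True, random_state=0,
    )
    est.fit(
        [X[i] for i in c["train_idx"]], y[c["train_idx"]],
        validation_data=([X[i] for i in c["valid_idx"]], y[c["valid_idx"]]),
    )
    return est


@pytest.fixture(scope="session")
def study_interp(study_model, study_corpus):
    """AttnAgg1A1A importances on the validation set plus the comparison
    report against the shuffled-score baseline."""
    c = study_corpus
    importances, gold = [], {}
    for i in c["valid_idx"]:
        rec = c["records"][i]
        _, capture = study_model.forward_with_attention(rec.sequence)
        capture.seq_id = rec.id
        iv = attn_agg(capture, "AttnAgg1A1A")
        iv.seq_id = rec.id
        importances.append(iv)
        gold[rec.id] = c["gold"][rec.id]
    report = compare_methods(
        {"Attn agg": importances}, gold, rescale_mode="minmax",
        shuffle_reps=10, seed=1,
    )
    return {"importances": importances, "gold": gold, "report": report}
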