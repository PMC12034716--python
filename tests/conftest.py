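"""Shared fixtures: stub backbones and a session-scoped pretrained study.

The stub backbones satisfy the backbone contract but emit prescribed
mask-fill distributions, so verbalizer and classifier behavior can be
checked against hand-computed values without any training.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pytest

from softverb import fixtures
from softverb.autodiff import Tensor
from softverb.backbone import TrainConfig, Vocabulary, tokenize, train_tiny_mlm


class StubModel:
    """Backbone stub with a fixed embedding table and a constant mask-fill
    distribution (uniform unless ``probs`` is given)."""

    def __init__(
        self,
        vocab: Vocabulary,
        dim: int = 8,
        probs: np.ndarray | None = None,
        table: np.ndarray | None = None,
        seed: int = 0,
    ):
        self.vocab = vocab
        self.dim = dim
        self.frozen = True
        rng = np.random.default_rng(seed)
        self.table = (
            np.asarray(table, dtype=np.float64)
            if table is not None
            else rng.normal(size=(len(vocab), dim))
        )
        if probs is None:
            probs = np.full(len(vocab), 1.0 / len(vocab))
        self.probs = np.asarray(probs, dtype=np.float64)
        assert abs(self.probs.sum() - 1.0) < 1e-9

    def embed_ids(self, ids):
        return self.table[np.asarray(ids, dtype=np.intp)].copy()

    def forward_embeddings(self, emb: Tensor, real: np.ndarray) -> Tensor:
        B, L = emb.shape[0], emb.shape[1]
        logits = np.broadcast_to(np.log(self.probs), (B, L, len(self.vocab))).copy()
        return Tensor(logits)

    def mask_fill_batch(self, ids, positions, real=None):
        return np.tile(self.probs, (len(np.atleast_2d(ids)), 1))

    def param_digest(self) -> str:
        h = hashlib.sha256(self.table.tobytes())
        h.update(self.probs.tobytes())
        return h.hexdigest()


def make_vocab(words: list[str]) -> Vocabulary:
    return Vocabulary.from_words(words)


@pytest.fixture(scope="session")
def small_vocab() -> Vocabulary:
    return make_vocab(["fever", "cough", "rash", "ache", "nausea"])


@pytest.fixture
def uniform_stub(small_vocab) -> StubModel:
    return StubModel(small_vocab)


# ---------------------------------------------------------------------------
# The shipped benchmark study: 4 classes, mixing 0.9, tiny MLM, fixed seeds.
# Pretrained once per session; several test modules and the acceptance
# checks share it.
# ---------------------------------------------------------------------------

STUDY_SEEDS = {"pool": 5, "kb": 6, "corpus": 11, "mlm": 3}


@pytest.fixture(scope="session")
def study_specs():
    return fixtures.default_specs(n_classes=4)


@pytest.fixture(scope="session")
def study_vocab(study_specs):
    return fixtures.build_vocabulary(study_specs)


@pytest.fixture(scope="session")
def study_pool(study_specs):
    return fixtures.gen_dataset(study_specs, 120, seed=STUDY_SEEDS["pool"], mixing=0.9)


@pytest.fixture(scope="session")
def study_kb(study_specs):
    return fixtures.gen_toy_kb(study_specs, seed=STUDY_SEEDS["kb"])


@pytest.fixture(scope="session")
def study_model(study_specs, study_vocab):
    corpus = [
        tokenize(t, study_vocab)
        for t in fixtures.pretrain_corpus(study_specs, 400, seed=STUDY_SEEDS["corpus"], mixing=0.9)
    ]
    model, curve = train_tiny_mlm(
        corpus,
        study_vocab,
        TrainConfig(learning_rate=2e-3, weight_decay=0.0, epochs=8, seed=STUDY_SEEDS["mlm"]),
        seed=STUDY_SEEDS["mlm"],
    )
    model.mlm_curve = curve
    return model
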