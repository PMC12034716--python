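"""Cloze classification: mean label-word probability per class.

A text is wrapped in the soft template, the backbone fills the mask with a
vocabulary distribution, and each class y scores the unweighted mean of the
probabilities of its label words V_y — every word in the verbalizer
contributes equally.  The prediction is the argmax class, ties broken by
the lowest index in the verbalizer's class order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .backbone import (
    MASK_ID,
    BackboneModel,
    TokenSequence,
    mask_fill_distribution,
    tokenize,
)
from .soft_template import SoftPromptConfig, SoftPromptState, assemble_prompt, encode_soft_tokens
from .verbalizer import Verbalizer

logger = logging.getLogger(__name__)


@dataclass
class ClassScores:
    """Per-class mean label-word probabilities and the resulting prediction."""

    classes: tuple[str, ...]
    scores: np.ndarray  # same order as classes, each in [0, 1]
    predicted: str
    tie: bool

    def score(self, y: str) -> float:
        return float(self.scores[self.classes.index(y)])


def _resolve_word_ids(verbalizer: Verbalizer, model: BackboneModel) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for y in verbalizer.classes:
        ids = []
        for w in verbalizer.label_words(y):
            if w in model.vocab:
                ids.append(model.vocab.index(w))
            else:
                logger.warning("label word %r of class %r not in vocabulary; skipped", w, y)
        if not ids:
            raise ValueError(f"every label word of class {y!r} is out of vocabulary")
        out[y] = np.array(sorted(set(ids)), dtype=np.intp)
    return out


def class_scores(
    text: str | TokenSequence,
    soft_state: SoftPromptState,
    verbalizer: Verbalizer,
    model: BackboneModel,
    sp_config: SoftPromptConfig | None = None,
) -> ClassScores:
    """Score all classes for one text via the mean label-word probability.

    Out-of-vocabulary label words are skipped with the class mean taken
    over the remaining words; a class with no in-vocabulary words is an
    error.
    """
    sp_config = sp_config or soft_state.config
    x = text if isinstance(text, TokenSequence) else tokenize(text, model.vocab)
    word_ids = _resolve_word_ids(verbalizer, model)
    h = encode_soft_tokens(soft_state, training=False)
    from .backbone import embed_sequence

    assembly = assemble_prompt(
        h, embed_sequence(x, model), model.embed_ids([MASK_ID])[0], sp_config
    )
    dist = mask_fill_distribution(assembly.sequence, assembly.mask_pos, model)
    scores = np.array([dist.probabilities[word_ids[y]].mean() for y in verbalizer.classes])
    best = int(np.argmax(scores))  # lowest index wins ties
    tie = bool(np.sum(scores == scores[best]) > 1)
    return ClassScores(
        classes=tuple(verbalizer.classes),
        scores=scores,
        predicted=verbalizer.classes[best],
        tie=tie,
    )


def classify_batch(
    texts: list[str | TokenSequence],
    soft_state: SoftPromptState,
    verbalizer: Verbalizer,
    model: BackboneModel,
    sp_config: SoftPromptConfig | None = None,
) -> list[str]:
    """Elementwise, order-preserving classification of a batch of texts."""
    labels = []
    for i, text in enumerate(texts):
        try:
            labels.append(class_scores(text, soft_state, verbalizer, model, sp_config).predicted)
        except Exception as exc:
            raise type(exc)(f"while classifying input {i}: {exc}") from exc
    return labels


@dataclass
class EvalReport:
    """Accuracy, per-class precision/recall, and confusion counts."""

    classes: tuple[str, ...]
    confusion: np.ndarray  # confusion[i, j] = count(gold=i, pred=j)
    episode: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion)) / self.total

    def precision(self, y: str) -> float:
        j = self.classes.index(y)
        col = self.confusion[:, j].sum()
        return float(self.confusion[j, j] / col) if col else 0.0

    def recall(self, y: str) -> float:
        i = self.classes.index(y)
        row = self.confusion[i, :].sum()
        return float(self.confusion[i, i] / row) if row else 0.0

    def summary(self) -> str:
        lines = [f"accuracy: {100.0 * self.accuracy:.2f}% ({self.total} examples)"]
        for y in self.classes:
            lines.append(
                f"  {y}: precision {100.0 * self.precision(y):.2f}%"
                f"  recall {100.0 * self.recall(y):.2f}%"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "episode": self.episode,
        }


def evaluate(predictions: list[str], gold: list[str], episode: dict | None = None) -> EvalReport:
    """Exact confusion counts and accuracy for aligned prediction/gold lists."""
    if len(predictions) != len(gold):
        raise ValueError(f"{len(predictions)} predictions vs {len(gold)} gold labels")
    classes = tuple(sorted(set(gold) | set(predictions)))
    index = {y: i for i, y in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for g, p in zip(gold, predictions):
        confusion[index[g], index[p]] += 1
    return EvalReport(classes=classes, confusion=confusion, episode=episode or {})
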