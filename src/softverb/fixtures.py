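"""Synthetic study material: topical short texts, a toy knowledge base,
and the K-shot episode sampler.

The generator emulates the statistical structure the method assumes in
real department-triage inquiries: each class (a hospital department) has a
private topical vocabulary of entity words (symptom-like surface forms that
the knowledge base knows about) and concept words (department-related terms
the knowledge base maps those entities to), mixed with a shared background
vocabulary.  Texts are short — 5 to 20 tokens — and drawn from the class's
unigram mixture; a single ``mixing`` parameter controls how much of each
text is topical versus background, i.e. class separability.

Episodes follow the K-shot protocol: K training and K test texts per class
(test size overridable), resampled independently three times, with the
reported metric the mean ± standard deviation across resamples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbone import TokenSequence, Vocabulary, tokenize
from .verbalizer import KnowledgeBase

DEFAULT_CLASS_NAMES = (
    "cardiology",
    "dermatology",
    "neurology",
    "oncology",
    "pediatrics",
    "psychiatry",
    "urology",
    "radiology",
)

DEFAULT_LENGTH_RANGE = (5, 20)  # the short-text regime
DEFAULT_MIXING = 0.9
DEFAULT_VOCAB_SIZE = 500


@dataclass
class TopicSpec:
    """Class-conditional vocabulary and unigram weights for one class."""

    name: str
    entity_words: list[str]
    concept_words: list[str]
    weights: np.ndarray  # over entity_words + concept_words + [name]
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != len(self.topic_words):
            raise ValueError("one weight per topic word required")
        if (self.weights <= 0).any():
            raise ValueError("topic weights must be positive")
        lo, hi = self.length_range
        if not (1 <= lo <= hi <= 20):
            raise ValueError("length range must stay within the short-text regime (<= 20)")

    @property
    def topic_words(self) -> list[str]:
        return self.entity_words + self.concept_words + [self.name]

    def probabilities(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def default_specs(
    n_classes: int = 4,
    n_entities: int = 12,
    n_concepts: int = 20,
) -> list[TopicSpec]:
    """Topic specs for the shipped benchmark fixture.

    Entity words carry most of the probability mass (they are the text's
    surface), concept words and the class name appear with lower but
    non-negligible frequency so the backbone can learn their co-occurrence.
    """
    if not 2 <= n_classes <= len(DEFAULT_CLASS_NAMES):
        raise ValueError(f"n_classes must be in [2, {len(DEFAULT_CLASS_NAMES)}]")
    specs = []
    for c in range(n_classes):
        name = DEFAULT_CLASS_NAMES[c]
        entities = [f"ent{c}x{i:02d}" for i in range(n_entities)]
        concepts = [f"con{c}x{j:02d}" for j in range(n_concepts)]
        w_ent = 3.0 / (1.0 + 0.15 * np.arange(n_entities))
        w_con = 1.2 / (1.0 + 0.10 * np.arange(n_concepts))
        w_name = np.array([1.5])
        specs.append(
            TopicSpec(
                name=name,
                entity_words=entities,
                concept_words=concepts,
                weights=np.concatenate([w_ent, w_con, w_name]),
            )
        )
    return specs


def background_words(specs: list[TopicSpec], vocab_size: int = DEFAULT_VOCAB_SIZE) -> list[str]:
    n_topic = sum(len(s.topic_words) for s in specs)
    n_background = vocab_size - n_topic - 3  # specials
    if n_background < 10:
        raise ValueError(
            f"vocabulary of {vocab_size} too small for {n_topic} topic words"
        )
    return [f"w{i:03d}" for i in range(n_background)]


def build_vocabulary(specs: list[TopicSpec], vocab_size: int = DEFAULT_VOCAB_SIZE) -> Vocabulary:
    words: list[str] = []
    for s in specs:
        words.extend(s.topic_words)
    words.extend(background_words(specs, vocab_size))
    return Vocabulary.from_words(words)


def gen_dataset(
    specs: list[TopicSpec],
    n_per_class: int,
    seed: int,
    mixing: float = DEFAULT_MIXING,
    vocab_size: int = DEFAULT_VOCAB_SIZE,
) -> list[tuple[str, str]]:
    """Sample a labeled dataset of class-conditional short texts.

    Each token is topical (drawn from the class unigram) with probability
    ``mixing`` and background otherwise; texts are 5-20 tokens.
    Deterministic given the seed.
    """
    if len(specs) < 2:
        raise ValueError("need at least two classes")
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must be in [0, 1]")
    bg = background_words(specs, vocab_size)
    rng = np.random.default_rng(seed)
    data: list[tuple[str, str]] = []
    for spec in specs:
        words = spec.topic_words
        probs = spec.probabilities()
        lo, hi = spec.length_range
        for _ in range(n_per_class):
            length = int(rng.integers(lo, hi + 1))
            toks = []
            for _t in range(length):
                if rng.random() < mixing:
                    toks.append(words[int(rng.choice(len(words), p=probs))])
                else:
                    toks.append(bg[int(rng.integers(len(bg)))])
            data.append((" ".join(toks), spec.name))
    return data


def pretrain_corpus(
    specs: list[TopicSpec],
    n_per_class: int,
    seed: int,
    mixing: float = DEFAULT_MIXING,
    vocab_size: int = DEFAULT_VOCAB_SIZE,
) -> list[str]:
    """Unlabeled text pool for backbone pretraining (same generator)."""
    return [t for t, _ in gen_dataset(specs, n_per_class, seed, mixing, vocab_size)]


def gen_toy_kb(
    specs: list[TopicSpec],
    seed: int,
    concepts_per_entity: int = 15,
    n_distractors: int = 2,
) -> KnowledgeBase:
    """A Probase-style toy knowledge base over the fixture vocabulary.

    Every entity word maps to its class's concept words with membership
    probabilities decreasing in rank (small per-entity jitter keeps the
    ranking nontrivial), plus a few low-probability distractor edges into
    other classes' concepts.
    """
    if not specs:
        raise ValueError("no topic specs given")
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, str, float]] = []
    all_concepts = [(i, c) for i, s in enumerate(specs) for c in s.concept_words]
    for ci, spec in enumerate(specs):
        k = min(concepts_per_entity, len(spec.concept_words))
        for entity in spec.entity_words:
            order = rng.permutation(len(spec.concept_words))[:k]
            for rank, j in enumerate(order):
                prob = float(np.clip(0.95 * 0.88 ** rank + rng.uniform(-0.01, 0.01), 0.01, 1.0))
                entries.append((entity, spec.concept_words[int(j)], prob))
            others = [c for (oc, c) in all_concepts if oc != ci]
            picks = rng.choice(len(others), size=min(n_distractors, len(others)), replace=False)
            for p in picks:
                entries.append((entity, others[int(p)], float(rng.uniform(0.02, 0.10))))
    return KnowledgeBase(entries)


@dataclass
class Episode:
    """One K-shot train/test split (the unit of the evaluation protocol)."""

    K: int
    train: list[tuple[str, str]]
    test: list[tuple[str, str]]
    seed: int
    repetition: int
    train_indices: list[int] = field(default_factory=list)
    test_indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.train_indices) & set(self.test_indices)
        if overlap:
            raise ValueError(f"train/test overlap at indices {sorted(overlap)}")

    def tokenized_train(self, vocab: Vocabulary) -> list[tuple[TokenSequence, str]]:
        return [(tokenize(t, vocab), y) for t, y in self.train]

    def manifest(self) -> dict:
        return {
            "K": self.K,
            "seed": self.seed,
            "repetition": self.repetition,
            "train_indices": list(self.train_indices),
            "test_indices": list(self.test_indices),
        }


def kshot_episodes(
    dataset: list[tuple[str, str]],
    K: int,
    repetitions: int = 3,
    seed: int = 0,
    test_size: int | None = None,
) -> list[Episode]:
    """Sample ``repetitions`` independent K-shot episodes.

    Each episode draws K training texts per class and, disjointly, K test
    texts per class (``test_size`` overrides the test count).
    """
    test_size = K if test_size is None else test_size
    by_class: dict[str, list[int]] = {}
    for i, (_t, y) in enumerate(dataset):
        by_class.setdefault(y, []).append(i)
    for y, idx in by_class.items():
        if len(idx) < K + test_size:
            raise ValueError(
                f"class {y!r} has {len(idx)} texts; K={K} plus test {test_size} needed"
            )
    episodes = []
    for r in range(repetitions):
        ep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(ep_seed)
        train_idx: list[int] = []
        test_idx: list[int] = []
        for y in sorted(by_class):
            pool = np.array(by_class[y])
            picked = rng.choice(len(pool), size=K + test_size, replace=False)
            train_idx.extend(int(i) for i in pool[picked[:K]])
            test_idx.extend(int(i) for i in pool[picked[K:]])
        episodes.append(
            Episode(
                K=K,
                train=[dataset[i] for i in train_idx],
                test=[dataset[i] for i in test_idx],
                seed=ep_seed,
                repetition=r + 1,
                train_indices=train_idx,
                test_indices=test_idx,
            )
        )
    return episodes


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def save_dataset(path, data: list[tuple[str, str]]) -> None:
    pd.DataFrame(data, columns=["text", "label"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def load_dataset(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["text", "label"], dtype=str)
    return list(df.itertuples(index=False, name=None))


def save_episodes(path, episodes: list[Episode]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([e.manifest() for e in episodes], fh, indent=2, sort_keys=True)
        fh.write("\n")
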