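"""Automatic verbalizer construction.

Two complementary strategies expand each class name into a set of label
words whose mask-fill probability will count as evidence for the class:

* **Concepts Retrieval (CR)** — entities mentioned in the class's training
  texts are looked up in a Probase-style knowledge base (entity, concept,
  membership probability); retrieved concepts are ranked by probability and
  then the N_a closest to the class-name anchor in the backbone's embedding
  space are kept, excluding morphological derivations of the class name.

* **Context Information (CI)** — candidate words the backbone itself
  predicts at the mask of the wrapped training texts are re-scored by a
  windowed pseudo-log-likelihood: with the candidate placed at the center
  of a symmetric window of half-size c, each position is masked in turn and
  the mean masked-token cross-entropy is the candidate's loss.  The N_a
  lowest-loss candidates are kept.

The union of both selections, with cross-class duplicates removed, is the
final verbalizer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone import (
    MASK_ID,
    PAD_ID,
    UNK_ID,
    BackboneModel,
    ContextWindow,
    EmbeddingSequence,
    TokenSequence,
    TAG_INPUT,
    TAG_MASK,
    masked_token_loss,
    normalize,
    tokenize,
)
from .soft_template import PromptAssembly

logger = logging.getLogger(__name__)

SOURCE_CR = "concepts_retrieval"
SOURCE_CI = "context_information"
SOURCE_BOTH = "both"
SOURCE_SINGLETON = "singleton"

DEFAULT_N_A = 15  # label words kept per strategy per class
DEFAULT_N_V = 50  # concepts retrieved per entity
DEFAULT_K_CAND = 50  # mask-fill candidates pooled per training text
DEFAULT_WINDOW = 5  # context half-size c


# ---------------------------------------------------------------------------
# Knowledge base
# ---------------------------------------------------------------------------


class KnowledgeBase:
    """Entity→concept edges with membership probabilities (Probase-style)."""

    def __init__(self, entries: list[tuple[str, str, float]]):
        seen: set[tuple[str, str]] = set()
        self._by_entity: dict[str, list[tuple[str, float]]] = {}
        for entity, concept, prob in entries:
            entity, concept = normalize(entity), normalize(concept)
            if not 0 < prob <= 1:
                raise ValueError(f"probability {prob} for ({entity}, {concept}) not in (0, 1]")
            if (entity, concept) in seen:
                raise ValueError(f"duplicate edge ({entity}, {concept})")
            seen.add((entity, concept))
            self._by_entity.setdefault(entity, []).append((concept, float(prob)))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_entity.values())

    @property
    def entities(self) -> list[str]:
        return list(self._by_entity)

    def __contains__(self, entity: str) -> bool:
        return normalize(entity) in self._by_entity

    def concepts(self, entity: str) -> list[tuple[str, float]]:
        return list(self._by_entity.get(normalize(entity), []))

    def entries(self) -> list[tuple[str, str, float]]:
        return [
            (e, c, p) for e, cps in sorted(self._by_entity.items()) for c, p in sorted(cps)
        ]

    @classmethod
    def from_tsv(cls, path) -> "KnowledgeBase":
        df = pd.read_csv(path, sep="\t", header=None, names=["entity", "concept", "probability"])
        if isinstance(df.iloc[0]["probability"], str):  # optional header row
            df = df.iloc[1:]
        df["probability"] = df["probability"].astype(float)
        return cls(list(df.itertuples(index=False, name=None)))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.entries(), columns=["entity", "concept", "probability"]).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass(frozen=True)
class CandidateWord:
    """A proposed label word with its score and provenance."""

    word: str
    score: float
    source: str
    class_name: str

    def __post_init__(self):
        if not np.isfinite(self.score) and self.score != np.inf:
            raise ValueError("candidate score must be finite or the +inf sentinel")


class Verbalizer:
    """Per-class label-word sets V_y with provenance."""

    def __init__(self, classes: list[str], words: dict[str, list[CandidateWord]], n_a: int = DEFAULT_N_A):
        self.classes = list(classes)
        self.words = {y: list(words[y]) for y in self.classes}
        self.n_a = n_a
        self._validate()

    def _validate(self) -> None:
        claimed: dict[str, str] = {}
        for y in self.classes:
            ws = [cw.word for cw in self.words[y]]
            if not ws:
                raise ValueError(f"class {y!r} has an empty label-word set")
            if len(set(ws)) != len(ws):
                raise ValueError(f"duplicate label words within class {y!r}")
            for w in ws:
                if w in claimed:
                    raise ValueError(f"label word {w!r} claimed by both {claimed[w]!r} and {y!r}")
                claimed[w] = y

    def label_words(self, y: str) -> list[str]:
        return [cw.word for cw in self.words[y]]

    @classmethod
    def singleton(cls, classes: list[str]) -> "Verbalizer":
        """Baseline verbalizer: each class name is its sole label word."""
        return cls(
            list(classes),
            {y: [CandidateWord(normalize(y), 0.0, SOURCE_SINGLETON, y)] for y in classes},
            n_a=1,
        )

    def to_json(self, path=None) -> str:
        payload = {
            "n_a": self.n_a,
            "classes": {
                y: [
                    {"word": cw.word, "source": cw.source, "score": cw.score}
                    for cw in self.words[y]
                ]
                for y in self.classes
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "Verbalizer":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        classes = sorted(payload["classes"])
        words = {
            y: [CandidateWord(d["word"], d["score"], d["source"], y) for d in payload["classes"][y]]
            for y in classes
        }
        return cls(classes, words, n_a=payload.get("n_a", DEFAULT_N_A))


# ---------------------------------------------------------------------------
# Concepts Retrieval
# ---------------------------------------------------------------------------


def match_entities(text: str, kb: KnowledgeBase) -> list[str]:
    """Greedy longest-match scan of the text's token n-grams against KB
    entity surface forms; matches never overlap."""
    tokens = normalize(text).split()
    if not tokens:
        return []
    entity_grams = {tuple(e.split()): e for e in kb.entities}
    max_len = max((len(g) for g in entity_grams), default=0)
    out: list[str] = []
    i = 0
    while i < len(tokens):
        hit = None
        for n in range(min(max_len, len(tokens) - i), 0, -1):
            gram = tuple(tokens[i : i + n])
            if gram in entity_grams:
                hit = entity_grams[gram]
                break
        if hit is not None:
            out.append(hit)
            i += len(hit.split())
        else:
            i += 1
    return out


def retrieve_concepts(
    entities: list[str], kb: KnowledgeBase, n_v: int = DEFAULT_N_V, class_name: str = ""
) -> list[CandidateWord]:
    """Per entity, the top n_v concepts by KB membership probability;
    merged across entities keeping each concept's maximum probability.
    Ties break lexicographically."""
    best: dict[str, float] = {}
    for entity in entities:
        concepts = kb.concepts(entity)
        if not concepts:
            logger.warning("entity %r not in knowledge base; skipped", entity)
            continue
        ranked = sorted(concepts, key=lambda cp: (-cp[1], cp[0]))[:n_v]
        for concept, prob in ranked:
            if prob > best.get(concept, -1.0):
                best[concept] = prob
    merged = sorted(best.items(), key=lambda cp: (-cp[1], cp[0]))
    return [CandidateWord(c, p, SOURCE_CR, class_name) for c, p in merged]


def anchor_distance(word: str, anchor: str, model: BackboneModel) -> float:
    """Cosine distance between a word and the class-name anchor in the
    backbone embedding space; multi-token strings use mean pooling;
    entirely-unknown words get the +inf sentinel (ranked last)."""

    def vector(s: str) -> np.ndarray | None:
        ids = [model.vocab.index(t) for t in normalize(s).split()]
        ids = [i for i in ids if i != UNK_ID]
        if not ids:
            return None
        return model.embed_ids(ids).mean(axis=0)

    va, vb = vector(word), vector(anchor)
    if va is None or vb is None:
        return float("inf")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return float("inf")
    cos = float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))
    return 1.0 - cos


def _char_bigrams(s: str) -> set[str]:
    s = s.replace(" ", "")
    return {s[i : i + 2] for i in range(len(s) - 1)} or {s}


def is_morphological_derivation(word: str, y: str) -> bool:
    """Heuristic exclusion of derivations of the class name: equality,
    substring containment either way, or character-bigram Jaccard >= 0.5."""
    w, a = normalize(word), normalize(y)
    if w == a or w in a or a in w:
        return True
    bw, ba = _char_bigrams(w), _char_bigrams(a)
    return len(bw & ba) / len(bw | ba) >= 0.5


def select_by_anchor(
    candidates: list[CandidateWord], y: str, n_a: int, model: BackboneModel
) -> list[CandidateWord]:
    """Keep the n_a candidates closest to the class-name anchor,
    excluding morphological derivations of y.  Ties break by distance,
    then lexicographically."""
    if not candidates:
        raise ValueError(f"no candidates to select for class {y!r}")
    scored = [
        CandidateWord(cw.word, anchor_distance(cw.word, y, model), SOURCE_CR, y)
        for cw in candidates
        if not is_morphological_derivation(cw.word, y)
    ]
    if not scored:
        raise ValueError(f"all candidates for class {y!r} excluded as derivations of the name")
    scored.sort(key=lambda cw: (cw.score, cw.word))
    return scored[: n_a]


# ---------------------------------------------------------------------------
# Context Information
# ---------------------------------------------------------------------------


def predict_mask_candidates(
    wrapped_inputs: list[PromptAssembly], model: BackboneModel, k_cand: int = DEFAULT_K_CAND
) -> list[str]:
    """Union over wrapped inputs of the top-k_cand vocabulary words by
    mask-fill probability; PAD/UNK/MASK excluded; within equal
    probabilities the lexicographically smaller word ranks first."""
    from .backbone import mask_fill_distribution

    words: set[str] = set()
    specials = {PAD_ID, UNK_ID, MASK_ID}
    for assembly in wrapped_inputs:
        dist = mask_fill_distribution(assembly.sequence, assembly.mask_pos, model)
        order = sorted(
            (i for i in range(len(dist.probabilities)) if i not in specials),
            key=lambda i: (-dist.probabilities[i], model.vocab.token(i)),
        )
        words.update(model.vocab.token(i) for i in order[:k_cand])
    return sorted(words)


def sequence_loss(window: ContextWindow, model: BackboneModel, loss_fn=None) -> float:
    """Windowed pseudo-log-likelihood: each non-padding position of the
    window is masked in turn and the masked-token losses are averaged.
    Padding positions are excluded from both the sum and the count."""
    positions = [i for i in range(len(window.tokens)) if not window.padding[i]]
    if not positions:
        raise ValueError("window contains only padding")
    if loss_fn is None:
        pos = np.array(positions)
        ids = np.tile(window.tokens, (len(pos), 1))
        real = np.tile(~window.padding, (len(pos), 1))
        probs = model.mask_fill_batch(ids, pos, real=real)
        true = window.tokens[pos]
        losses = -np.log(np.maximum(probs[np.arange(len(pos)), true], 1e-300))
        return float(losses.mean())
    return float(np.mean([loss_fn(window, i, model) for i in positions]))


def rank_by_context(
    candidates: list[str],
    windows: list[ContextWindow],
    model: BackboneModel,
    n_a: int = DEFAULT_N_A,
    class_name: str = "",
    loss_fn=None,
) -> list[CandidateWord]:
    """Score each candidate by its mean windowed pseudo-log-likelihood over
    the class's context windows (candidate substituted at the center);
    keep the n_a lowest-loss candidates.  Ties break by score, then
    lexicographically."""
    if not windows:
        raise ValueError(f"no context windows for class {class_name!r}")
    if not candidates:
        raise ValueError(f"no candidates for class {class_name!r}")
    scored = []
    for word in candidates:
        wid = model.vocab.index(word)
        losses = [
            sequence_loss(w.with_center(wid), model, loss_fn=loss_fn) for w in windows
        ]
        scored.append(CandidateWord(word, float(np.mean(losses)), SOURCE_CI, class_name))
    scored.sort(key=lambda cw: (cw.score, cw.word))
    return scored[: n_a]


# ---------------------------------------------------------------------------
# Merge and pipeline
# ---------------------------------------------------------------------------


def merge_strategies(
    cr: dict[str, list[CandidateWord]],
    ci: dict[str, list[CandidateWord]],
    n_a: int = DEFAULT_N_A,
) -> Verbalizer:
    """Set-union of the two strategies' per-class selections.

    Words selected by both strategies keep provenance "both" (with the CR
    score).  A word claimed by more than one class is dropped from all of
    them: under the equal-weight class score a shared word carries no
    discriminative signal.  Passing an empty mapping for one strategy
    yields the single-strategy ablation verbalizer.
    """
    classes = sorted(set(cr) | set(ci))
    if not classes:
        raise ValueError("no classes to merge")
    merged: dict[str, dict[str, CandidateWord]] = {}
    for y in classes:
        per: dict[str, CandidateWord] = {}
        for cw in cr.get(y, []):
            per[cw.word] = cw
        for cw in ci.get(y, []):
            if cw.word in per:
                prev = per[cw.word]
                per[cw.word] = CandidateWord(cw.word, prev.score, SOURCE_BOTH, y)
            else:
                per[cw.word] = cw
        merged[y] = per
    counts: dict[str, int] = {}
    for y in classes:
        for w in merged[y]:
            counts[w] = counts.get(w, 0) + 1
    words: dict[str, list[CandidateWord]] = {}
    for y in classes:
        kept = [cw for w, cw in sorted(merged[y].items()) if counts[w] == 1]
        if not kept:
            raise ValueError(
                f"class {y!r} lost all label words to cross-class deduplication"
            )
        words[y] = kept
    return Verbalizer(classes, words, n_a=n_a)


def _wrap_plain(x: TokenSequence, model: BackboneModel) -> PromptAssembly:
    """Wrap a text as e(x) + e([MASK]) with no soft tokens (used before any
    soft prompt exists, e.g. during verbalizer construction)."""
    vectors = np.concatenate([model.embed_ids(x.ids), model.embed_ids([MASK_ID])], axis=0)
    tags = (TAG_INPUT,) * len(x.ids) + (TAG_MASK,)
    return PromptAssembly(EmbeddingSequence(vectors=vectors, tags=tags), len(x.ids))


def build_verbalizer(
    train: list[tuple[TokenSequence, str]],
    model: BackboneModel,
    kb: KnowledgeBase | None = None,
    strategy: str = "both",
    n_a: int = DEFAULT_N_A,
    n_v: int = DEFAULT_N_V,
    k_cand: int = DEFAULT_K_CAND,
    window_half_size: int = DEFAULT_WINDOW,
) -> Verbalizer:
    """Construct the verbalizer from K-shot training data.

    strategy: "cr" (Concepts Retrieval only), "ci" (Context Information
    only), or "both" (union).  Candidates are pooled per class across the
    class's training texts.
    """
    if strategy not in {"cr", "ci", "both"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy in {"cr", "both"} and kb is None:
        raise ValueError("Concepts Retrieval requires a knowledge base")
    by_class: dict[str, list[TokenSequence]] = {}
    for x, y in train:
        by_class.setdefault(y, []).append(x)
    classes = sorted(by_class)
    cr_sel: dict[str, list[CandidateWord]] = {}
    ci_sel: dict[str, list[CandidateWord]] = {}
    if strategy in {"cr", "both"}:
        for y in classes:
            entities: list[str] = []
            for x in by_class[y]:
                entities.extend(match_entities(x.source, kb))
            pooled = retrieve_concepts(sorted(set(entities)), kb, n_v=n_v, class_name=y)
            cr_sel[y] = select_by_anchor(pooled, y, n_a, model)
    if strategy in {"ci", "both"}:
        for y in classes:
            assemblies = [_wrap_plain(x, model) for x in by_class[y]]
            candidates = predict_mask_candidates(assemblies, model, k_cand=k_cand)
            candidates = [c for c in candidates if not is_morphological_derivation(c, y)] or candidates
            windows = [
                ContextWindow.around(list(x.ids) + [MASK_ID], len(x.ids), window_half_size)
                for x in by_class[y]
            ]
            ci_sel[y] = rank_by_context(candidates, windows, model, n_a=n_a, class_name=y)
    if strategy == "cr":
        return merge_strategies(cr_sel, {y: [] for y in classes}, n_a=n_a)
    if strategy == "ci":
        return merge_strategies({y: [] for y in classes}, ci_sel, n_a=n_a)
    return merge_strategies(cr_sel, ci_sel, n_a=n_a)
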