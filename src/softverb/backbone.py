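"""Frozen masked-language-model backbone: contract and tiny reference model.

Every other stage of the pipeline (soft prompt training, verbalizer
construction, cloze classification) talks to the backbone through a small
contract: a vocabulary, an embedding table, a forward pass from embeddings
to per-position vocabulary logits, and a parameter digest used to verify
that the backbone stays frozen while soft prompts train.

The reference backbone (:class:`TinyMLM`) is a one-block pre-LayerNorm
self-attention encoder with a tanh feed-forward and a tied-embedding output
head, small enough (embedding dim ~48, vocabulary of a few hundred types)
to pretrain from scratch on a synthetic corpus in seconds on one CPU.  It
uses no positional encodings: the synthetic short texts it is meant for are
topical bags of words, and a positionless encoder transfers unchanged to
the longer prompt-assembled sequences seen at classification time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .autodiff import AdamW, Tensor, constant, layer_norm, parameter

PAD = "[PAD]"
UNK = "[UNK]"
MASK = "[MASK]"
PAD_ID, UNK_ID, MASK_ID = 0, 1, 2
_SPECIALS = (PAD, UNK, MASK)

# tags used in EmbeddingSequence
TAG_SOFT = "soft"
TAG_INPUT = "input"
TAG_MASK = "mask"


class Vocabulary:
    """Ordered token inventory with reserved PAD/UNK/MASK slots.

    Index 0/1/2 are always PAD/UNK/MASK; regular tokens follow.
    """

    def __init__(self, tokens: Sequence[str]):
        tokens = list(tokens)
        if tokens[:3] != list(_SPECIALS):
            raise ValueError(f"vocabulary must start with {_SPECIALS}")
        if len(set(tokens)) != len(tokens):
            raise ValueError("vocabulary tokens must be unique")
        self._tokens = tokens
        self._index = {t: i for i, t in enumerate(tokens)}

    @classmethod
    def from_words(cls, words: Sequence[str]) -> "Vocabulary":
        """Build a vocabulary from regular words, prepending the specials."""
        seen: dict[str, None] = {}
        for w in words:
            if w not in _SPECIALS:
                seen.setdefault(w, None)
        return cls(list(_SPECIALS) + list(seen))

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def tokens(self) -> list[str]:
        return list(self._tokens)

    def index(self, token: str) -> int:
        """Index of ``token``, falling back to UNK."""
        return self._index.get(token, UNK_ID)

    def token(self, idx: int) -> str:
        return self._tokens[idx]

    def content_hash(self) -> str:
        h = hashlib.sha256("\n".join(self._tokens).encode("utf-8"))
        return h.hexdigest()

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self._tokens) + "\n")

    @classmethod
    def from_file(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            tokens = [line.rstrip("\n") for line in fh if line.strip()]
        return cls(tokens)


@dataclass(frozen=True)
class TokenSequence:
    """A tokenized text: vocabulary ids plus the source string."""

    ids: tuple[int, ...]
    source: str

    def __post_init__(self):
        if len(self.ids) < 1:
            raise ValueError("token sequence must contain at least one token")

    def tokens(self, vocab: Vocabulary) -> list[str]:
        return [vocab.token(i) for i in self.ids]


def normalize(text: str) -> str:
    return " ".join(text.lower().split())


def tokenize(text: str, vocab: Vocabulary) -> TokenSequence:
    """Whitespace tokenization with lowercase normalization and UNK fallback."""
    norm = normalize(text)
    if not norm:
        raise ValueError("cannot tokenize empty or whitespace-only text")
    ids = tuple(vocab.index(tok) for tok in norm.split(" "))
    return TokenSequence(ids=ids, source=text)


@dataclass
class EmbeddingSequence:
    """A sequence of embedding vectors with per-position role tags."""

    vectors: np.ndarray  # (L, d)
    tags: tuple[str, ...]  # each in {soft, input, mask}

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a (length, dim) array")
        if len(self.tags) != self.vectors.shape[0]:
            raise ValueError("one tag per vector required")
        bad = set(self.tags) - {TAG_SOFT, TAG_INPUT, TAG_MASK}
        if bad:
            raise ValueError(f"unknown tags: {bad}")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class MaskDistribution:
    """A probability distribution over the vocabulary at a mask position."""

    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 1:
            raise ValueError("probabilities must be a vector")
        if (p < 0).any():
            raise ValueError("negative probability")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1 within 1e-6")
        self.probabilities = p

    def prob(self, token_id: int) -> float:
        return float(self.probabilities[token_id])

    def top_k(self, k: int, exclude: Sequence[int] = ()) -> list[int]:
        """Top-k token ids by probability; ties broken by id (lexicographic
        order is applied by callers that care about surface forms)."""
        mask = np.ones_like(self.probabilities, dtype=bool)
        mask[list(exclude)] = False
        order = np.lexsort((np.arange(len(self.probabilities)), -self.probabilities))
        return [int(i) for i in order if mask[i]][:k]


@dataclass
class ContextWindow:
    """A symmetric window of half-size c around a center word.

    ``tokens`` has length 2c+1; ``padding`` flags positions that fall
    outside the source text and are excluded from loss averages.
    """

    tokens: np.ndarray  # (2c+1,) int ids
    padding: np.ndarray  # (2c+1,) bool, True = synthetic boundary padding
    half_size: int

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.intp)
        self.padding = np.asarray(self.padding, dtype=bool)
        if len(self.tokens) != 2 * self.half_size + 1:
            raise ValueError("window length must be 2c+1")
        if len(self.padding) != len(self.tokens):
            raise ValueError("padding flags must align with tokens")
        if self.padding[self.center]:
            raise ValueError("center of a context window cannot be padding")

    @property
    def center(self) -> int:
        return self.half_size

    @classmethod
    def around(cls, ids: Sequence[int], center: int, half_size: int) -> "ContextWindow":
        """Extract the window around position ``center`` of ``ids``,
        padding with PAD at text boundaries."""
        ids = list(ids)
        if not 0 <= center < len(ids):
            raise IndexError("center outside sequence")
        toks, pad = [], []
        for off in range(-half_size, half_size + 1):
            j = center + off
            if 0 <= j < len(ids):
                toks.append(ids[j])
                pad.append(False)
            else:
                toks.append(PAD_ID)
                pad.append(True)
        return cls(np.array(toks), np.array(pad), half_size)

    def with_center(self, token_id: int) -> "ContextWindow":
        toks = self.tokens.copy()
        toks[self.center] = token_id
        return ContextWindow(toks, self.padding.copy(), self.half_size)


@runtime_checkable
class BackboneModel(Protocol):
    """Contract every backbone (reference or external adapter) satisfies."""

    vocab: Vocabulary
    dim: int
    frozen: bool

    def embed_ids(self, ids: Sequence[int]) -> np.ndarray: ...

    def forward_embeddings(self, emb: Tensor, real: np.ndarray) -> Tensor: ...

    def mask_fill_batch(
        self, ids: np.ndarray, positions: np.ndarray, real: np.ndarray | None = None
    ) -> np.ndarray: ...

    def param_digest(self) -> str: ...


@dataclass
class TrainConfig:
    """Optimization settings shared by MLM pretraining and prompt tuning."""

    optimizer: str = "adamw"
    learning_rate: float = 3e-4
    weight_decay: float = 0.01
    batch_size: int = 64
    epochs: int = 10
    seed: int = 0

    # learning rate at which the sensitivity sweep peaks; exposed as a named
    # preset rather than the default
    LR_SENSITIVITY_OPTIMUM = 3e-5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class TinyMLMConfig:
    """Architecture of the tiny reference MLM."""

    dim: int = 48
    ff_dim: int = 96
    mask_rate: float = 0.15
    init_scale: float = 0.1


class TinyMLM:
    """One-block self-attention masked language model (reference backbone)."""

    def __init__(self, vocab: Vocabulary, config: TinyMLMConfig, seed: int):
        self.vocab = vocab
        self.config = config
        self.dim = config.dim
        self.frozen = False
        rng = np.random.default_rng(seed)
        d, f, V = config.dim, config.ff_dim, len(vocab)
        s = config.init_scale

        def p(*shape, scale=s):
            return parameter(shape, rng=rng, scale=scale)

        self.params: dict[str, Tensor] = {
            "tok_emb": p(V, d),
            "wq": p(d, d), "bq": parameter(np.zeros(d)),
            "wk": p(d, d), "bk": parameter(np.zeros(d)),
            "wv": p(d, d), "bv": parameter(np.zeros(d)),
            "wo": p(d, d), "bo": parameter(np.zeros(d)),
            "ln1_g": parameter(np.ones(d)), "ln1_b": parameter(np.zeros(d)),
            "ln2_g": parameter(np.ones(d)), "ln2_b": parameter(np.zeros(d)),
            "ln3_g": parameter(np.ones(d)), "ln3_b": parameter(np.zeros(d)),
            "w1": p(d, f), "b1": parameter(np.zeros(f)),
            "w2": p(f, d), "b2": parameter(np.zeros(d)),
            "out_b": parameter(np.zeros(V)),
        }

    # -- contract -------------------------------------------------------
    def embed_ids(self, ids: Sequence[int]) -> np.ndarray:
        ids = np.asarray(ids, dtype=np.intp)
        if ids.size and (ids.min() < 0 or ids.max() >= len(self.vocab)):
            raise IndexError("token id out of vocabulary range")
        return self.params["tok_emb"].data[ids].copy()

    def forward_embeddings(self, emb: Tensor, real: np.ndarray) -> Tensor:
        """Map embeddings (B, L, d) to vocabulary logits (B, L, |V|).

        ``real`` is a boolean (B, L) array; False marks padding positions,
        which are excluded from attention as keys.
        """
        P = self.params
        d = self.dim
        neg = np.where(real, 0.0, -1e9)[:, None, :]  # (B, 1, L) key mask
        a = layer_norm(emb, P["ln1_g"], P["ln1_b"])
        q = a @ P["wq"] + P["bq"]
        k = a @ P["wk"] + P["bk"]
        v = a @ P["wv"] + P["bv"]
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d)) + constant(neg)
        attn = scores.softmax(axis=-1)
        h = emb + (attn @ v) @ P["wo"] + P["bo"]
        f = layer_norm(h, P["ln2_g"], P["ln2_b"])
        h = h + (f @ P["w1"] + P["b1"]).tanh() @ P["w2"] + P["b2"]
        out = layer_norm(h, P["ln3_g"], P["ln3_b"])
        return out @ P["tok_emb"].swapaxes(0, 1) + P["out_b"]

    def param_digest(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()

    def trainable_params(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    # -- batched inference helper ---------------------------------------
    def mask_fill_batch(
        self, ids: np.ndarray, positions: np.ndarray, real: np.ndarray | None = None
    ) -> np.ndarray:
        """Probabilities (B, |V|) of the vocabulary at ``positions``,
        after replacing those positions with [MASK]."""
        ids = np.asarray(ids, dtype=np.intp)
        positions = np.asarray(positions, dtype=np.intp)
        if real is None:
            real = ids != PAD_ID
        masked = ids.copy()
        rows = np.arange(len(ids))
        masked[rows, positions] = MASK_ID
        emb = constant(self.params["tok_emb"].data[masked])
        logits = self.forward_embeddings(emb, real).data[rows, positions]
        m = logits.max(axis=-1, keepdims=True)
        e = np.exp(logits - m)
        return e / e.sum(axis=-1, keepdims=True)

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        meta = {
            "config": dataclasses.asdict(self.config),
            "frozen": self.frozen,
            "vocab_tokens": self.vocab.tokens,
            "vocab_hash": self.vocab.content_hash(),
        }
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "TinyMLM":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(Vocabulary(meta["vocab_tokens"]), TinyMLMConfig(**meta["config"]), seed=0)
            for k in model.params:
                model.params[k].data = np.array(data[k], dtype=np.float64)
        model.frozen = meta["frozen"]
        if model.vocab.content_hash() != meta["vocab_hash"]:
            raise ValueError("vocabulary hash mismatch in checkpoint")
        return model


# ---------------------------------------------------------------------------
# Contract operations
# ---------------------------------------------------------------------------


def embed_sequence(tokens: TokenSequence, model: BackboneModel) -> EmbeddingSequence:
    """Look up input embeddings e(x) for a token sequence.

    The i-th vector is exactly the embedding-table row of the i-th id;
    [MASK] positions are tagged as mask, all others as input.
    """
    vectors = model.embed_ids(tokens.ids)
    tags = tuple(TAG_MASK if i == MASK_ID else TAG_INPUT for i in tokens.ids)
    return EmbeddingSequence(vectors=vectors, tags=tags)


def mask_fill_distribution(
    seq: EmbeddingSequence, mask_pos: int, model: BackboneModel
) -> MaskDistribution:
    """Vocabulary distribution p([MASK] = v | sequence) at ``mask_pos``."""
    if not 0 <= mask_pos < len(seq):
        raise IndexError("mask position outside sequence")
    if seq.tags[mask_pos] != TAG_MASK:
        raise ValueError(f"no mask tag at position {mask_pos}")
    emb = constant(seq.vectors[None, :, :])
    real = np.ones((1, len(seq)), dtype=bool)
    logits = model.forward_embeddings(emb, real).data[0, mask_pos]
    m = logits.max()
    e = np.exp(logits - m)
    return MaskDistribution(probabilities=e / e.sum())


def masked_token_loss(window: ContextWindow, position: int, model: BackboneModel) -> float:
    """Cross-entropy −log p(v = w_position | window with position masked).

    The true token at ``position`` is replaced by [MASK]; the loss is the
    negative log-probability the backbone assigns back to it.
    """
    if not 0 <= position < len(window.tokens):
        raise IndexError("position outside window")
    if window.padding[position]:
        raise ValueError("cannot score a padding position")
    true_id = int(window.tokens[position])
    probs = model.mask_fill_batch(
        window.tokens[None, :], np.array([position]), real=~window.padding[None, :]
    )[0]
    return float(-np.log(max(probs[true_id], 1e-300)))


def train_tiny_mlm(
    corpus: Sequence[TokenSequence],
    vocab: Vocabulary,
    config: TrainConfig | None = None,
    seed: int = 0,
    arch: TinyMLMConfig | None = None,
) -> tuple[TinyMLM, list[float]]:
    """Pretrain the tiny reference MLM by random-masking cross-entropy.

    15% of positions per sequence (at least one) are replaced with [MASK]
    and the model is trained to recover them.  Returns the frozen model and
    the per-epoch mean loss curve.  Deterministic given ``seed``.
    """
    if not corpus:
        raise ValueError("cannot train on an empty corpus")
    config = config or TrainConfig(learning_rate=2e-3, weight_decay=0.0, epochs=8, seed=seed)
    arch = arch or TinyMLMConfig()
    rng = np.random.default_rng(seed)
    model = TinyMLM(vocab, arch, seed=seed)
    opt = AdamW(
        model.trainable_params(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    curve: list[float] = []
    n = len(corpus)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses: list[float] = []
        for start in range(0, n, config.batch_size):
            batch = [corpus[i] for i in order[start : start + config.batch_size]]
            L = max(len(s.ids) for s in batch)
            ids = np.full((len(batch), L), PAD_ID, dtype=np.intp)
            for r, s in enumerate(batch):
                ids[r, : len(s.ids)] = s.ids
            real = ids != PAD_ID
            rows, cols, targets = [], [], []
            masked = ids.copy()
            for r, s in enumerate(batch):
                ln = len(s.ids)
                k = max(1, int(round(arch.mask_rate * ln)))
                pos = rng.choice(ln, size=k, replace=False)
                for pidx in pos:
                    rows.append(r)
                    cols.append(int(pidx))
                    targets.append(ids[r, pidx])
                    masked[r, pidx] = MASK_ID
            from .autodiff import embedding

            emb = embedding(model.params["tok_emb"], masked)
            logits = model.forward_embeddings(emb, real)
            logp = logits.log_softmax(axis=-1)
            picked = logp[np.array(rows), np.array(cols), np.array(targets)]
            loss = -picked.mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        curve.append(float(np.mean(losses)))
    model.frozen = True
    return model, curve
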