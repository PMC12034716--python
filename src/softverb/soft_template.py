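"""Soft template: trainable soft tokens re-encoded by a BiLSTM.

The template wraps an input text x into

    {h_0, ..., h_i, e(x), h_{i+1}, ..., h_n, e([MASK])}

where the h vectors are BiLSTM re-encodings of n raw trainable soft-token
embeddings (projected to the backbone embedding dimension) and i counts how
many of them precede the text.  Training optimizes only the soft-prompt
parameters — raw embeddings, BiLSTM, projection — with cross-entropy over
classes whose logits are the log mean label-word probabilities of the
verbalizer; the backbone stays frozen throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .autodiff import AdamW, Tensor, concat, constant, parameter, stack
from .backbone import (
    MASK_ID,
    TAG_INPUT,
    TAG_MASK,
    TAG_SOFT,
    BackboneModel,
    EmbeddingSequence,
    TokenSequence,
    TrainConfig,
)

__all__ = [
    "SoftPromptConfig",
    "SoftPromptState",
    "PromptAssembly",
    "TrainConfig",
    "encode_soft_tokens",
    "assemble_prompt",
    "layout_tags",
    "train_soft_prompt",
]


@dataclass
class SoftPromptConfig:
    """Shape of the soft template.

    n_soft soft tokens, the first ``insert_index`` of which precede the
    input text; BiLSTM hidden width 200 per direction and dropout 0.5 on
    its outputs (training only).
    """

    n_soft: int = 4
    insert_index: int = 2
    hidden_size: int = 200
    dropout: float = 0.5

    def __post_init__(self):
        if self.n_soft < 1:
            raise ValueError("need at least one soft token")
        if not 0 <= self.insert_index <= self.n_soft:
            raise ValueError("insert_index must be in [0, n_soft]")
        if self.hidden_size <= 0:
            raise ValueError("hidden_size must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


class SoftPromptState:
    """Trainable soft-prompt parameters: raw embeddings, BiLSTM, projection."""

    def __init__(
        self,
        config: SoftPromptConfig,
        dim: int,
        seed: int = 0,
        init_from: np.ndarray | None = None,
        init_scale: float = 0.02,
    ):
        self.config = config
        self.dim = dim
        rng = np.random.default_rng(seed)
        n, d, H = config.n_soft, dim, config.hidden_size
        if init_from is not None:
            if init_from.shape != (n, d):
                raise ValueError("init_from must have shape (n_soft, dim)")
            self.raw = Tensor(np.array(init_from, dtype=np.float64), requires_grad=True)
        else:
            self.raw = parameter((n, d), rng=rng, scale=init_scale)
        lstm_scale = 1.0 / np.sqrt(H)
        self.params: dict[str, Tensor] = {"raw": self.raw}
        for direction in ("f", "b"):
            self.params[f"wx_{direction}"] = parameter((d, 4 * H), rng=rng, scale=lstm_scale)
            self.params[f"wh_{direction}"] = parameter((H, 4 * H), rng=rng, scale=lstm_scale)
            self.params[f"bias_{direction}"] = parameter(np.zeros(4 * H))
        self.params["proj_w"] = parameter((2 * H, d), rng=rng, scale=1.0 / np.sqrt(2 * H))
        self.params["proj_b"] = parameter(np.zeros(d))

    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def param_digest(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()

    def clone(self) -> "SoftPromptState":
        other = SoftPromptState(self.config, self.dim, seed=0)
        for k in self.params:
            other.params[k].data = self.params[k].data.copy()
        other.raw = other.params["raw"]
        return other

    def save(self, path, vocab_hash: str) -> None:
        """Checkpoint the state together with its config and the hash of the
        backbone vocabulary it was trained against."""
        import dataclasses as _dc
        import json as _json

        meta = {
            "config": _dc.asdict(self.config),
            "dim": self.dim,
            "vocab_hash": vocab_hash,
        }
        arrays = {k: v.data for k, v in self.params.items()}
        with open(path, "wb") as fh:
            np.savez(
                fh,
                __meta__=np.frombuffer(_json.dumps(meta).encode(), dtype=np.uint8),
                **arrays,
            )

    @classmethod
    def load(cls, path, vocab_hash: str) -> "SoftPromptState":
        """Load a checkpoint; refuses to load against a different vocabulary."""
        import json as _json

        with np.load(path) as data:
            meta = _json.loads(bytes(data["__meta__"]).decode())
            if meta["vocab_hash"] != vocab_hash:
                raise ValueError(
                    "soft-prompt checkpoint was trained against a different vocabulary"
                )
            state = cls(SoftPromptConfig(**meta["config"]), meta["dim"], seed=0)
            for k in state.params:
                state.params[k].data = np.array(data[k], dtype=np.float64)
        state.raw = state.params["raw"]
        return state


def _lstm_direction(state: SoftPromptState, xs: list[Tensor], direction: str) -> list[Tensor]:
    H = state.config.hidden_size
    wx = state.params[f"wx_{direction}"]
    wh = state.params[f"wh_{direction}"]
    bias = state.params[f"bias_{direction}"]
    h = constant(np.zeros((1, H)))
    c = constant(np.zeros((1, H)))
    outs: list[Tensor] = []
    for x in xs:
        gates = x @ wx + h @ wh + bias
        i = gates[:, 0 * H : 1 * H].sigmoid()
        f = gates[:, 1 * H : 2 * H].sigmoid()
        g = gates[:, 2 * H : 3 * H].tanh()
        o = gates[:, 3 * H : 4 * H].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        outs.append(h)
    return outs


def encode_soft_tokens(
    state: SoftPromptState,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """BiLSTM re-encoding of the raw soft tokens.

    Returns an (n_soft, dim) tensor whose i-th row is the concatenation of
    the forward and backward LSTM states at step i, projected to the
    backbone embedding dimension.  Dropout is applied to the outputs only
    when ``training`` is set (requires ``rng``).
    """
    n = state.config.n_soft
    xs = [state.raw[t : t + 1, :] for t in range(n)]
    fwd = _lstm_direction(state, xs, "f")
    bwd = list(reversed(_lstm_direction(state, list(reversed(xs)), "b")))
    rows = []
    for f, b in zip(fwd, bwd):
        hcat = concat([f, b], axis=1)
        rows.append(hcat @ state.params["proj_w"] + state.params["proj_b"])
    out = concat(rows, axis=0)
    if training and state.config.dropout > 0:
        if rng is None:
            raise ValueError("training-mode encoding needs an rng for dropout")
        keep = (rng.random(out.shape) >= state.config.dropout).astype(np.float64)
        out = out * constant(keep / (1.0 - state.config.dropout))
    return out


def layout_tags(n_soft: int, insert_index: int, x_len: int) -> tuple[tuple[str, ...], int]:
    """Role tags of the assembled prompt and the mask position.

    Layout: insert_index soft vectors, the x embeddings, the remaining
    soft vectors, then the single mask slot at the end.
    """
    tags = (
        (TAG_SOFT,) * insert_index
        + (TAG_INPUT,) * x_len
        + (TAG_SOFT,) * (n_soft - insert_index)
        + (TAG_MASK,)
    )
    return tags, len(tags) - 1


@dataclass
class PromptAssembly:
    """An input wrapped in the soft template, ready for mask filling."""

    sequence: EmbeddingSequence
    mask_pos: int

    def __post_init__(self):
        if self.sequence.tags.count(TAG_MASK) != 1:
            raise ValueError("assembled prompt must contain exactly one mask")
        if self.sequence.tags[self.mask_pos] != TAG_MASK:
            raise ValueError("mask_pos does not point at the mask slot")


def _assemble_tensor(
    h: Tensor, x_emb: np.ndarray, mask_emb: np.ndarray, config: SoftPromptConfig
) -> tuple[Tensor, int]:
    """Tensor-level assembly used inside the training graph."""
    i = config.insert_index
    parts = []
    if i > 0:
        parts.append(h[:i, :])
    parts.append(constant(x_emb))
    if i < config.n_soft:
        parts.append(h[i:, :])
    parts.append(constant(mask_emb[None, :]))
    seq = concat(parts, axis=0)
    return seq, seq.shape[0] - 1


def assemble_prompt(
    h: Tensor | np.ndarray,
    x_emb: EmbeddingSequence,
    mask_emb: np.ndarray,
    config: SoftPromptConfig,
) -> PromptAssembly:
    """Lay out {h_0..h_i, e(x), h_{i+1}..h_n, e([MASK])}."""
    h_data = h.data if isinstance(h, Tensor) else np.asarray(h, dtype=np.float64)
    if h_data.shape[0] != config.n_soft:
        raise ValueError("got %d soft vectors for n_soft=%d" % (h_data.shape[0], config.n_soft))
    dims = {h_data.shape[1], x_emb.dim, len(mask_emb)}
    if len(dims) != 1:
        raise ValueError(f"incompatible embedding dimensions: {sorted(dims)}")
    i = config.insert_index
    vectors = np.concatenate(
        [h_data[:i], x_emb.vectors, h_data[i:], np.asarray(mask_emb)[None, :]], axis=0
    )
    tags, mask_pos = layout_tags(config.n_soft, i, len(x_emb))
    return PromptAssembly(EmbeddingSequence(vectors=vectors, tags=tags), mask_pos)


def _class_word_ids(verbalizer, model: BackboneModel) -> tuple[list[str], list[np.ndarray]]:
    """Resolve verbalizer words to vocabulary ids, skipping OOV words."""
    classes = list(verbalizer.classes)
    ids_per_class = []
    for y in classes:
        ids = [model.vocab.index(w) for w in verbalizer.label_words(y) if w in model.vocab]
        if not ids:
            raise ValueError(f"no label word of class {y!r} is in the backbone vocabulary")
        ids_per_class.append(np.array(sorted(set(ids)), dtype=np.intp))
    return classes, ids_per_class


def _example_class_logits(
    x: TokenSequence,
    h: Tensor,
    model: BackboneModel,
    config: SoftPromptConfig,
    ids_per_class: list[np.ndarray],
) -> Tensor:
    x_emb = model.embed_ids(x.ids)
    mask_emb = model.embed_ids([MASK_ID])[0]
    seq, mask_pos = _assemble_tensor(h, x_emb, mask_emb, config)
    logits = model.forward_embeddings(seq.reshape(1, *seq.shape), np.ones((1, seq.shape[0]), bool))
    probs = logits.softmax(axis=-1)[0, mask_pos, :]
    return stack([probs[ids].mean().log() for ids in ids_per_class])


def train_soft_prompt(
    train: list[tuple[TokenSequence, str]],
    verbalizer,
    model: BackboneModel,
    sp_config: SoftPromptConfig | None = None,
    t_config: TrainConfig | None = None,
    state: SoftPromptState | None = None,
) -> tuple[SoftPromptState, dict]:
    """Optimize the soft prompt on K-shot data with the backbone frozen.

    Per-example loss is the cross-entropy of the gold class under
    softmax-normalized class logits, each logit the log of the mean
    label-word mask-fill probability of that class.  Only soft-prompt
    parameters receive updates; the training log records the per-epoch mean
    loss.  Deterministic given the config seed.
    """
    sp_config = sp_config or SoftPromptConfig()
    t_config = t_config or TrainConfig()
    if not getattr(model, "frozen", False):
        raise ValueError("backbone must be frozen before soft-prompt training")
    classes, ids_per_class = _class_word_ids(verbalizer, model)
    class_index = {y: j for j, y in enumerate(classes)}
    for _, label in train:
        if label not in class_index:
            raise ValueError(f"label {label!r} missing from verbalizer")
    rng = np.random.default_rng(t_config.seed)
    if state is None:
        state = SoftPromptState(sp_config, model.dim, seed=t_config.seed)
    opt = AdamW(
        state.parameters(),
        lr=t_config.learning_rate,
        weight_decay=t_config.weight_decay,
    )
    log: dict = {"epoch_loss": [], "config": {"n_soft": sp_config.n_soft}}
    n = len(train)
    for epoch in range(t_config.epochs):
        order = rng.permutation(n)
        epoch_losses: list[float] = []
        for start in range(0, n, t_config.batch_size):
            batch = [train[i] for i in order[start : start + t_config.batch_size]]
            h = encode_soft_tokens(state, training=True, rng=rng)
            example_losses = []
            for x, label in batch:
                class_logits = _example_class_logits(x, h, model, sp_config, ids_per_class)
                nll = -class_logits.log_softmax()[class_index[label]]
                example_losses.append(nll)
            loss = stack(example_losses).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss in epoch {epoch}, batch starting at {start}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        log["epoch_loss"].append(float(np.mean(epoch_losses)))
    return state, log
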