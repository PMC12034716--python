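# Methods

This note records the model as implemented, the defaults and why they are
set where they are, what the synthetic benchmark does and does not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer from the code.

## Model and procedure

**Soft template.** An input `x = {x_0 … x_h}` is embedded by the frozen
backbone as `e(x)` and wrapped as
`T = {h_0 … h_i, e(x), h_{i+1} … h_n, e([MASK])}` — `insert_index = i`
soft vectors before the text, the rest after, the mask always last. The
`h_j` come from `n_soft` raw trainable embeddings passed through a
bidirectional LSTM; `h_j` is the concatenation of the forward and backward
hidden states at step *j*, linearly projected to the backbone embedding
width. The bidirectional re-encoding couples the soft tokens so they
train as a sequence; the published formulation of this recurrence is
loosely indexed, and the standard BiLSTM concatenation is the
interpretation implemented here.

**Classification.** The backbone's distribution at the mask is averaged
over each class's label words: `g(y) = mean_{v∈V_y} p([MASK]=v | x_p)`,
prediction `argmax_y g(y)`. Probabilities are taken over the full
vocabulary (not renormalized over the union of label words); the decision
rule is invariant to that choice only when all `|V_y|` are equal, and the
full-vocabulary form is the one the score definition states.
Ties at the argmax break to the lowest class index in the verbalizer's
class order. Label words missing from the backbone vocabulary are skipped
with the denominator adjusted, keeping `g(y)` an average over realizable
words; a class whose words are all missing is an error, not a silent
zero.

**Training.** Per-example loss is cross-entropy over classes with logits
`log g(y)` — the differentiable counterpart of the decision rule. Only
the soft-prompt parameters receive updates; the backbone's parameter
digest is checked bit-identical before and after training in the test
suite. Dropout (0.5) applies to the BiLSTM outputs, during training only,
redrawn once per batch so every example in a batch sees the same prompt.

**Verbalizer construction.**

* *Concepts Retrieval.* Entities are found in the training texts by a
  greedy longest-match scan of token n-grams against the knowledge base's
  entity surface forms (no overlaps; deterministic). Per entity the top
  `N_v = 50` concepts by membership probability are retrieved; the
  retrieval breadth is not prescribed anywhere, and 50 is wide enough that
  the anchor-distance stage, not the retrieval cut, is what selects.
  Entity candidate pools are merged per class (maximum probability per
  concept) across all of the class's training texts. Selection is by
  cosine distance to the class-name anchor on backbone input embeddings
  (multi-token strings mean-pooled; entirely-unknown words ranked last by
  a +inf sentinel). "Morphological derivations" of the class name are
  excluded by a surface heuristic: equality, substring containment either
  way, or character-bigram Jaccard ≥ 0.5.
* *Context Information.* Candidates are the union of the top
  `K_cand = 50` mask-fill predictions over the class's wrapped training
  texts (specials excluded, ties broken lexicographically). Each
  candidate is scored by the windowed pseudo-log-likelihood: the window is
  the `c = 5` tokens either side of the mask slot, the candidate sits at
  the center, every non-padding position is masked in turn, and the
  per-position cross-entropies are averaged. At text boundaries the
  window is padded and padding positions are excluded from both the sum
  and the count — a deliberate deviation from the literal `1/(2c+1)`
  denominator, which would otherwise reward short texts with free zeros.
  "Discarding words with higher loss" is realized as truncation to the
  `N_a` lowest-loss candidates.
* *Merge.* Unweighted set-union per class, provenance retained (a word
  chosen by both strategies is tagged `both`). A word claimed by two
  classes is removed from all of them: under the equal-weight average a
  shared word adds identical evidence to every claimant and is pure
  noise. A class emptied by this deduplication is an error naming the
  class.

Both ranking stages (anchor distance, context loss) are verified against
exhaustive brute-force sorts in the test suite, and the class score
against a brute-force mean.

## Parameters

| parameter | default | notes |
|---|---|---|
| `n_soft` | 4 | soft tokens; template places them both sides of the text, so `insert_index = 2` |
| `hidden_size` | 200 | BiLSTM width per direction |
| `dropout` | 0.5 | BiLSTM outputs, training only |
| learning rate | 3e-4 | AdamW; a sensitivity-sweep optimum of 3e-5 is exposed as `TrainConfig.LR_SENSITIVITY_OPTIMUM`, not the default (the two published settings disagree; the configuration section's value wins) |
| weight decay | 0.01 | AdamW, decoupled |
| batch size | 64 | the configured setting; the same source's prose elsewhere argues for 16 — 64 is kept |
| epochs | 10 | per-dataset knob |
| `N_a` | 15 | label words kept per strategy per class |
| `N_v` | 50 | concepts retrieved per entity (unprescribed; see above) |
| `K_cand` | 50 | mask-fill candidates per training text (reading of "all the predicted words") |
| `c` | 5 | context-window half-size |
| K grid | {10, 15, 20} | with 3 episode resamples, metric mean ± std |

Soft tokens initialize from N(0, 0.02²), seed-controlled; initialization
from sampled vocabulary embeddings is available via `init_from`.

## Reference backbone

The tiny MLM is a one-block pre-LayerNorm single-head self-attention
encoder with a tanh feed-forward and tied input/output embeddings
(dim 48, feed-forward 96, vocabulary ≈ 500). Two deliberate departures
from convention:

* **No positional encodings.** The synthetic texts are exchangeable bags
  of topic words, so position carries no signal, and a positionless
  encoder transfers unchanged to the longer prompt-assembled sequences
  seen at classification time (soft tokens + text + mask exceeds any
  pretraining length).
* **Masking always substitutes `[MASK]`** (no 80/10/10 keep/random
  split), at a 15% rate with at least one position per sequence.
  Inference only ever queries a literal mask, so the mismatch the
  80/10/10 scheme mitigates does not arise here.

Pretraining: random-masking cross-entropy, AdamW without weight decay,
learning rate 2e-3, 8 epochs over 1600 synthetic texts (~7 s on one CPU;
loss 5.59 → 3.95 against a uniform baseline of ln 500 ≈ 6.21).

Everything trains on an in-package reverse-mode autodiff core (float64,
dense). Its primitives are finite-difference-checked in the test suite.
The backbone contract (`embed_ids`, `forward_embeddings`,
`mask_fill_batch`, `param_digest`, `frozen`) is deliberately small so a
full-size pretrained model can be adapted behind it.

## Synthetic benchmark: what it does and does not show

The generator emulates the statistics the method relies on: short texts
(5–20 tokens), class-private topical vocabulary split into entity words
(what the knowledge base indexes) and concept words (what it maps to,
including the class name), a shared background vocabulary, and a `mixing`
parameter setting the topical fraction per token (default 0.9). The toy
knowledge base gives every entity its class's concepts with probabilities
decaying in rank (per-entity jitter keeps rankings nontrivial) plus
low-probability distractor edges into other classes.

It does **not** emulate: real orthography or subword structure (tokens
are whitespace-split synthetic strings), Chinese text, polysemy, noisy or
contradictory knowledge-base edges, class imbalance, or label noise.
Passing the end-to-end tests therefore shows the pipeline is correct and
that the method recovers class structure when its assumptions hold — not
that it attains any particular accuracy on clinical data. At the default
mixing of 0.9 the benchmark is strongly separable and all strategy
variants saturate near 100%; the margin of the expanded verbalizer over
the bare class name becomes visible in harder regimes (about five points
at mixing 0.25, see `examples/03_kshot_benchmark.py`).

## Numerical choices and degenerate inputs

* Float64 throughout; mask distributions are validated to sum to 1 within
  1e-6; probabilities are floored at 1e-300 before logs.
* Deterministic tie-breaks everywhere a sort appears: candidate rankings
  by (score, word), mask-fill top-k by (−p, word), argmax by lowest class
  index. Rerunning any stage with the same seed reproduces results
  byte-for-byte; the harness derives all stage seeds from one master seed
  via `numpy.random.SeedSequence`.
* Empty/whitespace text, out-of-range token ids, windows whose center is
  padding, a missing mask tag, K larger than the per-class pool, an
  unfrozen backbone at prompt-training time, and a label absent from the
  verbalizer all raise immediately with the offending item named.
* Harness problem sizes (pool of 120 texts per class, 1600-text
  pretraining corpus, 3 episode resamples) are chosen so a full run
  completes in about a minute on one CPU; they are configuration, not
  protocol — the episode sampler and the K-per-class test extraction
  implement the protocol, and a `test_size` override allows larger fixed
  test sets.

## Known limitations

* The reference backbone is far below the capacity regime of a real
  pretrained model; conclusions about absolute accuracy do not transfer.
* Entity linking is exact surface matching; no normalization beyond
  lowercasing, no fuzzy or cross-lingual matching.
* The morphological-derivation filter is a surface heuristic tuned to
  space-separated scripts.
* Single-label classification only; no calibration or abstention.
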