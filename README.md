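# softverb

Soft prompt-tuning with automatically constructed verbalizers for few-shot
classification of short texts — the regime of online medical inquiries and
department-triage questions, where texts run under 20 tokens, vocabulary is
specialized, and labeled data is scarce (10–20 examples per class).

The package is aimed at practitioners who want to study or apply
cloze-style prompt classification without fine-tuning a language model:
the backbone stays frozen; only a handful of continuous prompt vectors
train.

## Method

Classification is reframed as filling a `[MASK]` slot. An input sentence
*x* is wrapped in a **soft template**

```
T = {h_0, …, h_i, e(x), h_{i+1}, …, h_n, e([MASK])}
```

where `e(·)` are the backbone's input embeddings and the `h_j` are *n*
trainable soft tokens, re-encoded by a BiLSTM
(`h_j = [LSTM→_j ; LSTM←_j]`, projected to the embedding width) so that the
soft tokens form a coherent sequence rather than independent vectors. The
frozen masked language model M then yields `p([MASK] = v | x_p)` over its
vocabulary, and each class *y* scores the unweighted mean over its label
words `V_y`:

```
g(y) = (1/|V_y|) · Σ_{v ∈ V_y} p([MASK] = v | x_p),    ŷ = argmax_y g(y)
```

The label-word sets `V_y` are built automatically from the K-shot training
texts by two strategies:

* **Concepts Retrieval (CR)** — entities mentioned in the class's texts
  are looked up in a Probase-style knowledge base of
  (entity, concept, membership probability) triples; retrieved concepts are
  ranked by probability, then the `N_a = 15` closest to the class-name
  anchor in embedding space are kept (cosine distance, morphological
  derivations of the class name excluded).
* **Context Information (CI)** — candidate words the backbone itself
  predicts at the mask are re-scored by a windowed pseudo-log-likelihood:
  with the candidate at the center of a symmetric window of half-size
  `c = 5`, each position *i* is masked in turn,
  `L(w_i) = −log p(v_i = w_i | W \ w_i)`, and `L(W)` is the average over
  the window; the `N_a` lowest-loss candidates are kept.

The final verbalizer is the union of both selections with cross-class
duplicates removed. Only the soft-prompt parameters (soft embeddings,
BiLSTM, projection) are optimized — AdamW, learning rate 3e-4, weight
decay 0.01, batch size 64, dropout 0.5 on the BiLSTM outputs — with
cross-entropy over classes whose logits are `log g(y)`.

Because real clinical inquiry datasets of this kind are not publicly
deposited, the package ships a first-class synthetic fixture family: a
generator of class-conditional topical short texts with a controllable
topical/background `mixing` parameter, a toy knowledge base over the same
vocabulary, and a tiny from-scratch-pretrained reference MLM (one
self-attention block, 48-dim embeddings, ~500-type vocabulary) so the
whole pipeline runs and is testable on one CPU in seconds. Any external
backbone can be plugged in by satisfying the small `BackboneModel`
contract in `softverb.backbone`.

## Worked example

`examples/03_kshot_benchmark.py` runs the full harness — fixture
generation, backbone pretraining, verbalizer construction, soft-prompt
training, K-shot evaluation — for the combined verbalizer, each single
strategy, and a class-name-only singleton baseline:

```
   K    strategy    accuracy (%)
  10          cr     100.00±0.00
  20          cr     100.00±0.00
  10          ci     100.00±0.00
  20          ci     100.00±0.00
  10        both     100.00±0.00
  20        both     100.00±0.00
  10   singleton     100.00±0.00
  20   singleton     100.00±0.00

hard regime (mixing=0.25, K=20):
        both      74.58±2.12
   singleton      69.58±3.12
```

Each cell is mean ± standard deviation of accuracy over 3 independently
resampled K-shot episodes (K training and K test texts per class). At the
default mixing of 0.9 the benchmark is strongly separable and every
variant saturates; at mixing 0.25 — three background tokens for every
topical one — the expanded verbalizer's pooled evidence is worth about
five accuracy points over the bare class name.

The other examples show the stages in isolation:
`examples/01_pretrain_backbone.py` pretrains the tiny MLM and prints its
mask-fill predictions after topical words (epoch losses fall from 5.59 to
3.95 against a uniform baseline of ln 500 ≈ 6.21, and the top predictions
after six cardiology entity words are all cardiology vocabulary);
`examples/02_build_verbalizer.py` prints the label words each strategy
contributes per class (26–28 words per class at `N_a = 15` per strategy,
with 2–4 selected by both strategies at once).

A thin CLI mirrors the library (`softverb gen-fixtures | pretrain-mlm |
build-verbalizer | train | predict | eval | run-kshot | report`); run any
verb with `--help`.

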