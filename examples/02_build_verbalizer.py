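"""Construct the verbalizer automatically from 10-shot data, by both
strategies, and inspect what each contributes.

Concepts Retrieval (CR) looks up in-text entities in a toy knowledge base
and keeps concepts close to the class-name anchor in embedding space.
Context Information (CI) asks the backbone itself for mask-fill candidates
and keeps the ones with the lowest windowed pseudo-log-likelihood.  The
final verbalizer is their union with cross-class duplicates removed.
"""

from softverb import fixtures
from softverb.backbone import TrainConfig, tokenize, train_tiny_mlm
from softverb.verbalizer import build_verbalizer

specs = fixtures.default_specs(n_classes=4)
vocab = fixtures.build_vocabulary(specs)
kb = fixtures.gen_toy_kb(specs, seed=6)
pool = fixtures.gen_dataset(specs, 120, seed=5)

corpus = [tokenize(t, vocab) for t in fixtures.pretrain_corpus(specs, 400, seed=11)]
model, _ = train_tiny_mlm(
    corpus, vocab, TrainConfig(learning_rate=2e-3, weight_decay=0.0, epochs=8, seed=3), seed=3
)

episode = fixtures.kshot_episodes(pool, K=10, repetitions=1, seed=42)[0]
train = episode.tokenized_train(vocab)
print(f"knowledge base: {len(kb)} entity->concept edges")

verb = build_verbalizer(train, model, kb=kb, strategy="both")
for y in verb.classes:
    by_source: dict[str, int] = {}
    for cw in verb.words[y]:
        by_source[cw.source] = by_source.get(cw.source, 0) + 1
    print(f"\n{y}: {len(verb.label_words(y))} label words {by_source}")
    print("  e.g.", ", ".join(verb.label_words(y)[:6]))
print(
    "\n(each class should collect up to 15 words per strategy; words picked by"
    "\n both strategies at once count once, with provenance 'both')"
)
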