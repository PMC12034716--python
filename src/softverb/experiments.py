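"""Reproducible K-shot experiment harness.

``run_kshot`` wires the full pipeline — fixture generation, tiny-MLM
pretraining, verbalizer construction (CR / CI / both / singleton
baseline), soft-prompt training, and K-shot evaluation — into one
deterministic run keyed by a single master seed.  Results carry full
provenance: the resolved configuration and content hashes of every input.
Accuracies are reported as mean ± standard deviation over the episode
resamples, formatted as percentages with two decimals ("86.93±0.63").
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import fixtures
from .backbone import TinyMLM, TinyMLMConfig, TrainConfig, tokenize, train_tiny_mlm
from .classifier import classify_batch, evaluate
from .soft_template import SoftPromptConfig, train_soft_prompt
from .verbalizer import Verbalizer, build_verbalizer

logger = logging.getLogger(__name__)

STRATEGIES = ("cr", "ci", "both", "singleton")


@dataclass
class RunConfig:
    """Everything one K-shot run depends on, serialized with its results."""

    # fixture conditions
    n_classes: int = 4
    vocab_size: int = fixtures.DEFAULT_VOCAB_SIZE
    mixing: float = fixtures.DEFAULT_MIXING
    pool_per_class: int = 120
    pretrain_per_class: int = 400

    # backbone pretraining
    mlm_dim: int = 48
    mlm_epochs: int = 8
    mlm_learning_rate: float = 2e-3

    # verbalizer
    strategy: str = "both"
    n_a: int = 15
    n_v: int = 50
    k_cand: int = 50
    window_half_size: int = 5

    # soft prompt + optimization
    n_soft: int = 4
    insert_index: int = 2
    hidden_size: int = 200
    dropout: float = 0.5
    learning_rate: float = 3e-4
    weight_decay: float = 0.01
    batch_size: int = 64
    epochs: int = 10

    # protocol
    k_grid: tuple[int, ...] = (10, 15, 20)
    repetitions: int = 3
    test_size: int | None = None
    master_seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_grid"] = list(self.k_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "k_grid" in d:
            d["k_grid"] = tuple(d["k_grid"])
        return cls(**d)


def _seeds(master_seed: int, n: int, label: str) -> list[int]:
    ss = np.random.SeedSequence([master_seed, int(hashlib.sha256(label.encode()).hexdigest(), 16) % (2**31)])
    return [int(s % (2**31)) for s in ss.generate_state(n)]


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


@dataclass
class PreparedStudy:
    """Shared material for a run: fixture data, KB, and pretrained backbone."""

    specs: list
    vocab: object
    pool: list[tuple[str, str]]
    kb: object
    model: TinyMLM
    mlm_curve: list[float]
    provenance: dict


def prepare_study(config: RunConfig) -> PreparedStudy:
    """Generate the study's fixture data and pretrain the frozen backbone."""
    seeds = _seeds(config.master_seed, 4, "prepare")
    specs = fixtures.default_specs(n_classes=config.n_classes)
    vocab = fixtures.build_vocabulary(specs, config.vocab_size)
    pool = fixtures.gen_dataset(
        specs, config.pool_per_class, seeds[0], config.mixing, config.vocab_size
    )
    kb = fixtures.gen_toy_kb(specs, seeds[1])
    corpus_texts = fixtures.pretrain_corpus(
        specs, config.pretrain_per_class, seeds[2], config.mixing, config.vocab_size
    )
    corpus = [tokenize(t, vocab) for t in corpus_texts]
    model, curve = train_tiny_mlm(
        corpus,
        vocab,
        TrainConfig(
            learning_rate=config.mlm_learning_rate,
            weight_decay=0.0,
            epochs=config.mlm_epochs,
            seed=seeds[3],
        ),
        seed=seeds[3],
        arch=TinyMLMConfig(dim=config.mlm_dim, ff_dim=2 * config.mlm_dim),
    )
    provenance = {
        "dataset_hash": _sha256_text("\n".join(f"{t}\t{y}" for t, y in pool)),
        "kb_hash": _sha256_text(
            "\n".join(f"{e}\t{c}\t{p:.6f}" for e, c, p in kb.entries())
        ),
        "vocab_hash": vocab.content_hash(),
        "model_digest": model.param_digest(),
    }
    return PreparedStudy(specs, vocab, pool, kb, model, curve, provenance)


def _episode_verbalizer(config: RunConfig, study: PreparedStudy, train_tok) -> Verbalizer:
    if config.strategy == "singleton":
        return Verbalizer.singleton(sorted({y for _x, y in train_tok}))
    return build_verbalizer(
        train_tok,
        study.model,
        kb=study.kb,
        strategy=config.strategy,
        n_a=config.n_a,
        n_v=config.n_v,
        k_cand=config.k_cand,
        window_half_size=config.window_half_size,
    )


def run_kshot(config: RunConfig, study: PreparedStudy | None = None) -> dict:
    """Run the full K-shot protocol and return a results dict.

    For each K in the grid: sample episodes, build the verbalizer from the
    episode's training texts, train the soft prompt with the backbone
    frozen, classify the test split, and aggregate accuracy as
    mean ± standard deviation across episodes.  Deterministic given the
    master seed.
    """
    study = study or prepare_study(config)
    sp_config = SoftPromptConfig(
        n_soft=config.n_soft,
        insert_index=config.insert_index,
        hidden_size=config.hidden_size,
        dropout=config.dropout,
    )
    results: dict = {
        "config": config.to_dict(),
        "provenance": dict(study.provenance),
        "mlm_loss_curve": [round(x, 6) for x in study.mlm_curve],
        "per_k": {},
    }
    for K in config.k_grid:
        ep_seed = _seeds(config.master_seed, 1, f"episodes-k{K}")[0]
        episodes = fixtures.kshot_episodes(
            study.pool, K, config.repetitions, ep_seed, test_size=config.test_size
        )
        accuracies: list[float] = []
        ep_records = []
        for ep in episodes:
            stage = "verbalizer"
            try:
                train_tok = ep.tokenized_train(study.vocab)
                verb = _episode_verbalizer(config, study, train_tok)
                stage = "soft-prompt-training"
                t_config = TrainConfig(
                    learning_rate=config.learning_rate,
                    weight_decay=config.weight_decay,
                    batch_size=config.batch_size,
                    epochs=config.epochs,
                    seed=ep.seed,
                )
                state, log = train_soft_prompt(
                    train_tok, verb, study.model, sp_config, t_config
                )
                stage = "evaluation"
                texts = [t for t, _y in ep.test]
                gold = [y for _t, y in ep.test]
                pred = classify_batch(texts, state, verb, study.model, sp_config)
                report = evaluate(pred, gold, episode=ep.manifest())
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage!r} failed on K={K} repetition {ep.repetition}: {exc}"
                ) from exc
            accuracies.append(report.accuracy)
            ep_records.append(
                {
                    "repetition": ep.repetition,
                    "seed": ep.seed,
                    "accuracy": round(report.accuracy, 6),
                    "final_train_loss": round(log["epoch_loss"][-1], 6),
                }
            )
            logger.info(
                "K=%d rep=%d strategy=%s accuracy=%.4f",
                K, ep.repetition, config.strategy, report.accuracy,
            )
        acc = np.array(accuracies)
        results["per_k"][str(K)] = {
            "episodes": ep_records,
            "mean_accuracy": round(float(acc.mean()), 6),
            "std_accuracy": round(float(acc.std(ddof=0)), 6),
        }
    return results


def format_mean_std(mean: float, std: float) -> str:
    """Render an accuracy fraction pair as e.g. 0.8693, 0.0063 -> "86.93±0.63"."""
    return f"{100.0 * mean:.2f}±{100.0 * std:.2f}"


def report(results: dict) -> str:
    """Human-readable table for a results dict (accuracy %, mean±std)."""
    lines = []
    strategy = results.get("config", {}).get("strategy", "?")
    header = f"{'K':>4}  {'strategy':>10}  {'accuracy (%)':>14}"
    lines.append(header)
    for k in sorted(results.get("per_k", {}), key=int):
        row = results["per_k"][k]
        lines.append(
            f"{k:>4}  {strategy:>10}  {format_mean_std(row['mean_accuracy'], row['std_accuracy']):>14}"
        )
    return "\n".join(lines)


def results_to_json(results: dict) -> str:
    return json.dumps(results, indent=2, sort_keys=True)


def compare_ablation(results_by_strategy: dict[str, dict], k: int) -> dict[str, float]:
    """Mean accuracies of several strategies at one K, with a warning when
    the combined verbalizer does not dominate the single strategies.

    On a given benchmark the combined (both) strategy is expected to do at
    least as well as CR or CI alone; this is a qualitative expectation, so
    a violation logs a warning rather than raising.
    """
    means = {
        s: res["per_k"][str(k)]["mean_accuracy"] for s, res in results_by_strategy.items()
    }
    if "both" in means:
        for s, m in means.items():
            if s != "both" and means["both"] < m:
                logger.warning(
                    "combined verbalizer (%.4f) below %s-only (%.4f) at K=%d",
                    means["both"], s, m, k,
                )
    return means
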