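"""Verbalizer construction: knowledge-base retrieval, anchor-distance
selection, windowed pseudo-log-likelihood ranking, and strategy merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from softverb.backbone import ContextWindow, MASK_ID, PAD_ID, UNK_ID, tokenize
from softverb.soft_template import PromptAssembly
from softverb.verbalizer import (
    CandidateWord,
    KnowledgeBase,
    Verbalizer,
    _wrap_plain,
    anchor_distance,
    build_verbalizer,
    is_morphological_derivation,
    match_entities,
    merge_strategies,
    predict_mask_candidates,
    rank_by_context,
    retrieve_concepts,
    select_by_anchor,
    sequence_loss,
)
from conftest import StubModel, make_vocab


class TestKnowledgeBase:
    def test_tsv_round_trip(self, tmp_path):
        kb = KnowledgeBase([("epilepsy", "neurology", 0.9), ("rash", "dermatology", 0.7)])
        path = tmp_path / "kb.tsv"
        kb.to_tsv(path)
        loaded = KnowledgeBase.from_tsv(path)
        assert loaded.entries() == kb.entries()

    @pytest.mark.parametrize("prob", [0.0, -0.2, 1.5])
    def test_probability_out_of_range_rejected(self, prob):
        with pytest.raises(ValueError):
            KnowledgeBase([("a", "b", prob)])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError):
            KnowledgeBase([("a", "b", 0.5), ("a", "b", 0.6)])


class TestMatchEntities:
    KB = KnowledgeBase(
        [
            ("epilepsy", "neurology", 0.9),
            ("cervical", "anatomy", 0.5),
            ("cervical diseases", "gynecology", 0.8),
        ]
    )

    def test_exact_containment(self):
        assert match_entities("i think i have epilepsy", self.KB) == ["epilepsy"]

    def test_no_match_gives_empty_list(self):
        assert match_entities("nothing relevant here", self.KB) == []

    def test_longest_match_wins_without_overlap(self):
        assert match_entities("severe cervical diseases today", self.KB) == [
            "cervical diseases"
        ]

    def test_single_token_fallback_when_longer_gram_absent(self):
        assert match_entities("cervical pain", self.KB) == ["cervical"]


class TestRetrieveConcepts:
    def test_sorted_by_probability(self):
        kb = KnowledgeBase([("e1", "ca", 0.9), ("e1", "cb", 0.4)])
        out = retrieve_concepts(["e1"], kb, n_v=10)
        assert [c.word for c in out] == ["ca", "cb"]
        assert [c.score for c in out] == [0.9, 0.4]

    def test_truncation_to_n_v(self):
        kb = KnowledgeBase([("e1", "ca", 0.9), ("e1", "cb", 0.4)])
        assert [c.word for c in retrieve_concepts(["e1"], kb, n_v=1)] == ["ca"]

    def test_merge_keeps_maximum_probability(self):
        kb = KnowledgeBase(
            [("e1", "ca", 0.3), ("e2", "ca", 0.8), ("e2", "cb", 0.5)]
        )
        out = retrieve_concepts(["e1", "e2"], kb, n_v=10)
        assert out[0].word == "ca" and out[0].score == pytest.approx(0.8)

    def test_unknown_entity_contributes_nothing(self):
        kb = KnowledgeBase([("e1", "ca", 0.9)])
        assert retrieve_concepts(["ghost"], kb, n_v=5) == []


class TestAnchorDistance:
    def test_identity_is_zero(self, uniform_stub):
        assert anchor_distance("fever", "fever", uniform_stub) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, uniform_stub):
        d1 = anchor_distance("fever", "cough", uniform_stub)
        d2 = anchor_distance("cough", "fever", uniform_stub)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_orthogonal_unit_vectors_distance_one(self):
        vocab = make_vocab(["north", "east"])
        table = np.zeros((len(vocab), 2))
        table[vocab.index("north")] = [1.0, 0.0]
        table[vocab.index("east")] = [0.0, 1.0]
        model = StubModel(vocab, dim=2, table=table)
        assert anchor_distance("north", "east", model) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_word_gets_infinite_sentinel(self, uniform_stub):
        assert anchor_distance("zzz qqq", "fever", uniform_stub) == float("inf")


class TestSelectByAnchor:
    def _candidates(self, words, y="anchor"):
        return [CandidateWord(w, 0.5, "concepts_retrieval", y) for w in words]

    def test_class_name_itself_excluded(self, uniform_stub):
        out = select_by_anchor(
            self._candidates(["fever", "cough"], y="fever"), "fever", 5, uniform_stub
        )
        assert [c.word for c in out] == ["cough"]

    def test_truncates_to_n_a(self):
        words = [f"word{i:02d}" for i in range(20)]
        vocab = make_vocab(words + ["anchorname"])
        model = StubModel(vocab, dim=6, seed=3)
        out = select_by_anchor(self._candidates(words), "anchorname", 15, model)
        assert len(out) == 15

    def test_all_candidates_excluded_raises(self, uniform_stub):
        with pytest.raises(ValueError, match="excluded"):
            select_by_anchor(self._candidates(["fever"], y="fever"), "fever", 5, uniform_stub)

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 10))
    def test_matches_brute_force_ranking(self, seed, n):
        words = [f"cand{i}" for i in range(n)]
        vocab = make_vocab(words + ["anchorx"])
        model = StubModel(vocab, dim=4, seed=seed)
        n_a = min(5, n)
        out = select_by_anchor(self._candidates(words), "anchorx", n_a, model)
        brute = sorted(
            words, key=lambda w: (anchor_distance(w, "anchorx", model), w)
        )[:n_a]
        assert [c.word for c in out] == brute


class TestMorphologicalDerivation:
    @pytest.mark.parametrize(
        "word,anchor,expected",
        [
            ("neurology", "neurology", True),
            ("neurolog", "neurology", True),  # substring
            ("neurologyx", "neurology", True),  # contains the anchor
            ("neurologist", "neurology", True),  # bigram overlap >= 0.5
            ("cardiology", "neurology", False),
            ("brain", "neurology", False),
        ],
    )
    def test_exclusion_rule(self, word, anchor, expected):
        assert is_morphological_derivation(word, anchor) is expected


class TestPredictMaskCandidates:
    def _assembly(self, model, text="fever cough"):
        return _wrap_plain(tokenize(text, model.vocab), model)

    def test_peaked_distribution_returns_its_peak(self, small_vocab):
        probs = np.full(len(small_vocab), 0.01)
        probs[small_vocab.index("rash")] = 1.0 - 0.01 * (len(small_vocab) - 1)
        model = StubModel(small_vocab, probs=probs)
        out = predict_mask_candidates([self._assembly(model)], model, k_cand=1)
        assert out == ["rash"]

    def test_specials_never_included(self, uniform_stub):
        out = predict_mask_candidates(
            [self._assembly(uniform_stub)], uniform_stub, k_cand=100
        )
        assert not {"[PAD]", "[UNK]", "[MASK]"} & set(out)
        assert len(out) == len(uniform_stub.vocab) - 3

    def test_uniform_tie_breaks_lexicographically(self, uniform_stub):
        out = predict_mask_candidates([self._assembly(uniform_stub)], uniform_stub, k_cand=2)
        regular = sorted(t for t in uniform_stub.vocab.tokens[3:])
        assert out == regular[:2]


class TestSequenceLoss:
    def test_hand_average_of_stub_losses(self, uniform_stub):
        window = ContextWindow.around([3, 4, 5], 1, 1)
        stub_losses = {0: 0.2, 1: 0.4, 2: 0.6}
        loss = sequence_loss(
            window, uniform_stub, loss_fn=lambda w, i, m: stub_losses[i]
        )
        assert loss == pytest.approx(0.4, abs=1e-12)

    def test_certain_model_gives_zero(self, small_vocab):
        # every position predicted with probability 1 is impossible for a
        # single stub distribution unless all tokens are identical
        true_id = small_vocab.index("rash")
        probs = np.zeros(len(small_vocab))
        probs[true_id] = 1.0
        model = StubModel(small_vocab, probs=probs)
        window = ContextWindow.around([true_id] * 3, 1, 1)
        assert sequence_loss(window, model) == pytest.approx(0.0, abs=1e-12)

    def test_constant_losses_average_to_constant(self, uniform_stub):
        window = ContextWindow.around([3, 4, 5, 3, 4], 2, 2)
        loss = sequence_loss(window, uniform_stub, loss_fn=lambda w, i, m: 1.7)
        assert loss == pytest.approx(1.7, abs=1e-12)

    def test_padding_positions_excluded_from_average(self, uniform_stub):
        # center at text edge: left neighbours are padding
        window = ContextWindow.around([3, 4], 0, 2)
        seen = []
        sequence_loss(window, uniform_stub, loss_fn=lambda w, i, m: seen.append(i) or 1.0)
        assert seen == [2, 3]  # only non-padding positions scored

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_average_bounded_by_min_and_max_position_loss(self, seed, small_vocab):
        rng = np.random.default_rng(seed)
        ids = list(rng.integers(3, len(small_vocab), size=5))
        window = ContextWindow.around(ids, 2, 2)
        losses = {i: float(rng.uniform(0, 5)) for i in range(5)}
        total = sequence_loss(window, None, loss_fn=lambda w, i, m: losses[i])
        assert min(losses.values()) - 1e-12 <= total <= max(losses.values()) + 1e-12

    def test_padding_center_rejected_at_construction(self):
        with pytest.raises(ValueError, match="center"):
            ContextWindow(
                tokens=np.array([PAD_ID, PAD_ID, PAD_ID]),
                padding=np.array([True, True, True]),
                half_size=1,
            )


def _pseudorandom_loss_fn(salt: int):
    def loss_fn(window, i, model):
        key = (salt, int(window.tokens[window.center]), i) + tuple(int(t) for t in window.tokens)
        return float(np.random.default_rng(abs(hash(key)) % 2**31).uniform(0, 3))

    return loss_fn


class TestRankByContext:
    def test_zero_loss_candidate_ranked_first(self, small_vocab):
        windows = [ContextWindow.around([3, 4, 5], 1, 1)]
        favored = small_vocab.index("rash")
        loss_fn = lambda w, i, m: 0.0 if w.tokens[w.center] == favored else 1.0
        out = rank_by_context(["fever", "rash"], windows, StubModel(small_vocab), 2, loss_fn=loss_fn)
        assert out[0].word == "rash"
        assert out[0].score == pytest.approx(0.0)

    def test_n_a_larger_than_candidate_count_returns_all_sorted(self, uniform_stub):
        windows = [ContextWindow.around([3, 4, 5], 1, 1)]
        out = rank_by_context(
            ["fever", "cough"], windows, uniform_stub, n_a=10,
            loss_fn=_pseudorandom_loss_fn(1),
        )
        assert len(out) == 2
        assert out[0].score <= out[1].score

    def test_no_windows_rejected(self, uniform_stub):
        with pytest.raises(ValueError, match="window"):
            rank_by_context(["fever"], [], uniform_stub, 5)

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 10))
    def test_matches_brute_force_ranking(self, seed, n, small_vocab):
        rng = np.random.default_rng(seed)
        candidates = [small_vocab.token(int(i)) for i in rng.choice(
            np.arange(3, len(small_vocab)), size=min(n, len(small_vocab) - 3), replace=False
        )]
        windows = [
            ContextWindow.around(list(rng.integers(3, len(small_vocab), size=5)), 2, 2)
            for _ in range(3)
        ]
        loss_fn = _pseudorandom_loss_fn(seed % 1000)
        model = StubModel(small_vocab)
        n_a = min(5, len(candidates))
        out = rank_by_context(candidates, windows, model, n_a, loss_fn=loss_fn)

        def brute_score(word):
            wid = small_vocab.index(word)
            per_window = []
            for w in windows:
                sub = w.with_center(wid)
                vals = [loss_fn(sub, i, model) for i in range(5) if not sub.padding[i]]
                per_window.append(sum(vals) / len(vals))
            return sum(per_window) / len(per_window)

        brute = sorted(candidates, key=lambda w: (brute_score(w), w))[:n_a]
        assert [c.word for c in out] == brute


class TestMergeStrategies:
    def _cands(self, words, source, y="c1"):
        return {y: [CandidateWord(w, 0.1, source, y) for w in words]}

    def test_union_with_provenance(self):
        cr = self._cands(["a", "b"], "concepts_retrieval")
        ci = self._cands(["b", "c"], "context_information")
        verb = merge_strategies(cr, ci)
        assert verb.label_words("c1") == ["a", "b", "c"]
        sources = {cw.word: cw.source for cw in verb.words["c1"]}
        assert sources == {
            "a": "concepts_retrieval",
            "b": "both",
            "c": "context_information",
        }

    def test_cross_class_duplicate_dropped_from_all(self):
        cr = {
            "c1": [CandidateWord("shared", 0.1, "concepts_retrieval", "c1"),
                   CandidateWord("only1", 0.1, "concepts_retrieval", "c1")],
            "c2": [CandidateWord("shared", 0.1, "concepts_retrieval", "c2"),
                   CandidateWord("only2", 0.1, "concepts_retrieval", "c2")],
        }
        verb = merge_strategies(cr, {"c1": [], "c2": []})
        assert verb.label_words("c1") == ["only1"]
        assert verb.label_words("c2") == ["only2"]

    def test_single_strategy_ablations(self):
        cr = self._cands(["a", "b"], "concepts_retrieval")
        ci = self._cands(["c"], "context_information")
        assert merge_strategies(cr, {"c1": []}).label_words("c1") == ["a", "b"]
        assert merge_strategies({"c1": []}, ci).label_words("c1") == ["c"]

    def test_class_emptied_by_dedup_raises_with_class_name(self):
        cr = {
            "c1": [CandidateWord("shared", 0.1, "concepts_retrieval", "c1")],
            "c2": [CandidateWord("shared", 0.1, "concepts_retrieval", "c2"),
                   CandidateWord("extra", 0.1, "concepts_retrieval", "c2")],
        }
        with pytest.raises(ValueError, match="c1"):
            merge_strategies(cr, {"c1": [], "c2": []})


class TestVerbalizerContainer:
    def test_json_round_trip(self, tmp_path):
        verb = merge_strategies(
            {"c1": [CandidateWord("a", 0.2, "concepts_retrieval", "c1")]},
            {"c1": [CandidateWord("b", 0.4, "context_information", "c1")]},
        )
        path = tmp_path / "verb.json"
        verb.to_json(path)
        loaded = Verbalizer.from_json(path)
        assert loaded.classes == verb.classes
        assert loaded.label_words("c1") == verb.label_words("c1")

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Verbalizer(["c1"], {"c1": []})

    def test_singleton_baseline(self):
        verb = Verbalizer.singleton(["neurology", "oncology"])
        assert verb.label_words("neurology") == ["neurology"]
        assert verb.label_words("oncology") == ["oncology"]


class TestBuildVerbalizerPipeline:
    def test_full_build_on_study_fixture(self, study_model, study_kb, study_vocab, study_pool):
        from softverb.fixtures import kshot_episodes

        ep = kshot_episodes(study_pool, 10, repetitions=1, seed=77)[0]
        verb = build_verbalizer(
            ep.tokenized_train(study_vocab), study_model, kb=study_kb, strategy="both"
        )
        assert sorted(verb.classes) == sorted({y for _t, y in study_pool})
        all_words: list[str] = []
        for y in verb.classes:
            words = verb.label_words(y)
            assert 0 < len(words) <= 2 * verb.n_a
            all_words.extend(words)
        assert len(all_words) == len(set(all_words))  # disjoint across classes

    def test_cr_requires_knowledge_base(self, study_model, study_vocab, study_pool):
        from softverb.fixtures import kshot_episodes

        ep = kshot_episodes(study_pool, 5, repetitions=1, seed=78)[0]
        with pytest.raises(ValueError, match="knowledge base"):
            build_verbalizer(ep.tokenized_train(study_vocab), study_model, kb=None, strategy="cr")
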