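"""Shortest dependency paths, vocabulary, splitting, metrics and ROC."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxomine.candidates import INTERVAL, TAXON, Span, generate_candidates
from taxomine.corpus import Document, Sentence, Token
from taxomine.errors import PathFailure, TaxomineError
from taxomine.relation import (
    DOWN, UP,
    Metrics,
    build_vocab,
    evaluate,
    roc_curve,
    select_boundary,
    shortest_dependency_path,
    span_anchor,
    split_by_document,
)
from taxomine.synthgen import (
    IntervalMention,
    POSITIVE_TEMPLATES,
    TaxonMention,
    _instantiate,
)


def _span(sentence: Sentence, start: int, end: int, etype: str = TAXON) -> Span:
    return Span(
        sentence.doc_id, sentence.sent_index, start, end, etype,
        " ".join(t.text for t in sentence.tokens[start - 1 : end - 1]), None,
    )


class TestShortestDependencyPath:
    def test_linear_chain(self):
        # A -> B -> C(root)
        sentence = Sentence("d", 0, [
            Token(1, "A", 2, "dep"), Token(2, "B", 3, "dep"), Token(3, "C", 0, "root"),
        ])
        path = shortest_dependency_path(sentence, _span(sentence, 1, 2), _span(sentence, 3, 4))
        assert [s.text for s in path.steps] == ["A", "B", "C"]
        assert [s.direction for s in path.steps] == [None, UP, UP]
        assert len(path) == 3

    def test_template_sentence_passes_through_verb(self):
        sentence, spans = _instantiate(
            POSITIVE_TEMPLATES[0], "d", 0,
            TaxonMention("Setosellina", "roulei", abbreviated=False, uncertain=True),
            {"int": IntervalMention("Serravallian", None)},
        )
        taxon = next(s for s in spans if s.entity_type == TAXON)
        interval = next(s for s in spans if s.entity_type == INTERVAL)
        path = shortest_dependency_path(sentence, taxon, interval)
        assert "found" in path.token_texts()
        assert path.token_texts()[0] == "Setosellina"
        assert path.token_texts()[-1] == "Serravallian"

    def test_anchor_is_leftmost_token_with_outside_head(self):
        # span tokens 1-2 where token 2 heads token 1 and token 2 attaches out
        sentence = Sentence("d", 0, [
            Token(1, "lower", 2, "amod"),
            Token(2, "Miocene", 3, "obl"),
            Token(3, "found", 0, "root"),
        ])
        assert span_anchor(sentence, _span(sentence, 1, 3, INTERVAL)) == 2

    def test_random_trees_match_bfs_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(3, 13))
            # random tree: token i+1 attaches to a random earlier token or root
            heads = [0]
            for i in range(1, n):
                heads.append(int(rng.integers(0, i)) + 1 if rng.random() < 0.9 else 0)
            # ensure single component for the oracle: attach extra roots to 1
            heads = [h if i == 0 else (h or 1) for i, h in enumerate(heads)]
            tokens = [Token(i + 1, f"w{i + 1}", heads[i], "dep" if heads[i] else "root")
                      for i in range(n)]
            sentence = Sentence("d", 0, tokens)
            g = nx.Graph()
            g.add_nodes_from(range(1, n + 1))
            g.add_edges_from((t.index, t.head) for t in tokens if t.head)
            a, b = rng.choice(np.arange(1, n + 1), size=2, replace=False)
            a, b = int(a), int(b)
            path = shortest_dependency_path(
                sentence, _span(sentence, a, a + 1), _span(sentence, b, b + 1)
            )
            oracle = nx.shortest_path(g, a, b)
            assert len(path) == len(oracle)
            assert [s.text for s in path.steps] == [f"w{i}" for i in oracle]

    def test_directions_follow_head_links(self):
        sentence = Sentence("d", 0, [
            Token(1, "A", 3, "nsubj"), Token(2, "B", 3, "obj"), Token(3, "R", 0, "root"),
        ])
        path = shortest_dependency_path(sentence, _span(sentence, 1, 2), _span(sentence, 2, 3))
        assert [(s.deprel, s.direction) for s in path.steps] == [
            (None, None), ("nsubj", UP), ("obj", DOWN),
        ]

    def test_disconnected_parse_raises_path_failure(self):
        # two roots: two components
        sentence = Sentence("d", 0, [
            Token(1, "A", 0, "root"), Token(2, "B", 0, "root"),
        ])
        with pytest.raises(PathFailure):
            shortest_dependency_path(sentence, _span(sentence, 1, 2), _span(sentence, 2, 3))


class TestBuildVocab:
    def test_min_count_keeps_frequent_tokens(self):
        vocab = build_vocab([["found", "the"], ["found", "the", "found"], ["the"]], 2)
        assert "found" in vocab and "the" in vocab

    def test_rare_token_maps_to_oov(self):
        vocab = build_vocab([["found", "rare"], ["found"]], 2)
        assert "rare" not in vocab
        assert vocab["<pad>"] == 0 and vocab["<oov>"] == 1

    def test_deterministic_given_corpus(self):
        seqs = [["b", "a"], ["a", "c"], ["c", "b", "a"]]
        assert build_vocab(seqs, 1) == build_vocab(list(seqs), 1)
        # frequency then lexicographic ordering
        assert list(build_vocab(seqs, 1)) == ["<pad>", "<oov>", "a", "b", "c"]


def _fake_candidates(doc_sizes: dict[str, int]):
    sentence = Sentence("d", 0, [Token(1, "x", 0, "root")])
    out = []
    for doc_id, size in doc_sizes.items():
        for i in range(size):
            span_t = Span(doc_id, 0, 1, 2, TAXON, "x", "X")
            span_i = Span(doc_id, 0, 1, 2, INTERVAL, "y", "Y")
            from taxomine.candidates import Candidate

            out.append(Candidate(f"{doc_id}-{i}", span_t, span_i, sentence, "X"))
    return out


class TestSplitByDocument:
    def test_ten_equal_docs_split_8_1_1(self):
        candidates = _fake_candidates({f"doc{i}": 5 for i in range(10)})
        split = split_by_document(candidates, seed=0)
        from collections import Counter

        counts = Counter(split.assignment.values())
        assert counts == {"train": 8, "validation": 1, "test": 1}

    def test_no_document_in_two_splits(self):
        candidates = _fake_candidates({f"doc{i}": i + 1 for i in range(7)})
        split = split_by_document(candidates, seed=3)
        parts = split.partition(candidates)
        doc_sets = [
            {c.taxon.doc_id for c in part} for part in parts.values()
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not doc_sets[i] & doc_sets[j]

    def test_realized_fractions_near_targets(self):
        rng = np.random.default_rng(2)
        for trial in range(50):
            sizes = {f"doc{i}": int(rng.integers(1, 30)) for i in range(20)}
            candidates = _fake_candidates(sizes)
            split = split_by_document(candidates, seed=trial)
            total = sum(sizes.values())
            heaviest = max(sizes.values())
            parts = split.partition(candidates)
            for name, target in zip(("train", "validation", "test"), (0.8, 0.1, 0.1)):
                realized = len(parts[name]) / total
                assert abs(realized - target) <= heaviest / total + 1e-9

    def test_deterministic_given_seed(self):
        candidates = _fake_candidates({f"doc{i}": 3 for i in range(6)})
        assert (
            split_by_document(candidates, seed=5).assignment
            == split_by_document(candidates, seed=5).assignment
        )

    def test_too_few_documents_rejected(self):
        with pytest.raises(TaxomineError):
            split_by_document(_fake_candidates({"a": 2, "b": 2}))


class TestEvaluate:
    def test_perfect_confusion(self):
        metrics = evaluate([0.9, 0.8, 0.1, 0.2], ["POS", "POS", "NEG", "NEG"])
        assert (metrics.tp, metrics.fp, metrics.tn, metrics.fn) == (2, 0, 2, 0)
        assert metrics.accuracy == 1.0 and metrics.f1 == 1.0 and metrics.fpr == 0.0

    def test_f1_is_harmonic_mean_of_precision_and_recall(self):
        # counts with precision 207/250 = 0.828 and recall 0.880 exactly
        metrics = Metrics(tp=1035, fp=215, tn=0, fn=1035 * 120 // 880)
        assert metrics.precision == pytest.approx(0.828)
        assert metrics.f1 == pytest.approx(
            2 * metrics.precision * metrics.recall / (metrics.precision + metrics.recall)
        )

    def test_random_scores_match_brute_force_tally(self):
        rng = np.random.default_rng(11)
        probs = rng.random(200)
        gold = ["POS" if x else "NEG" for x in rng.integers(0, 2, 200)]
        metrics = evaluate(probs, gold, boundary=0.4)
        tp = sum(1 for p, g in zip(probs, gold) if p >= 0.4 and g == "POS")
        fp = sum(1 for p, g in zip(probs, gold) if p >= 0.4 and g == "NEG")
        tn = sum(1 for p, g in zip(probs, gold) if p < 0.4 and g == "NEG")
        fn = sum(1 for p, g in zip(probs, gold) if p < 0.4 and g == "POS")
        assert (metrics.tp, metrics.fp, metrics.tn, metrics.fn) == (tp, fp, tn, fn)

    def test_boundary_ties_classify_positive(self):
        metrics = evaluate([0.5], ["POS"], boundary=0.5)
        assert metrics.tp == 1 and metrics.fn == 0

    def test_undefined_ratios_are_none(self):
        metrics = evaluate([0.1, 0.2], ["NEG", "NEG"])
        assert metrics.precision is None and metrics.recall is None
        assert metrics.f1 is None
        assert metrics.accuracy == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(TaxomineError):
            evaluate([], [])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1), st.booleans()), min_size=1, max_size=60))
    def test_metric_identities_hold(self, pairs):
        probs = [p for p, _ in pairs]
        gold = ["POS" if g else "NEG" for _, g in pairs]
        m = evaluate(probs, gold)
        total = m.tp + m.fp + m.tn + m.fn
        assert total == len(pairs)
        assert m.accuracy == (m.tp + m.tn) / total
        if m.precision is not None:
            assert m.precision == m.tp / (m.tp + m.fp)
        if m.recall is not None:
            assert m.recall == m.tp / (m.tp + m.fn)
        if m.fpr is not None:
            assert m.fpr == m.fp / (m.fp + m.tn)
        if m.f1 is not None:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall)
            )


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], ["POS", "POS", "NEG", "NEG"])
        assert curve.auc == 1.0

    def test_constant_scores_give_diagonal(self):
        curve = roc_curve([0.5] * 10, ["POS"] * 5 + ["NEG"] * 5)
        assert curve.auc == pytest.approx(0.5)
        assert (curve.points[0][1], curve.points[0][2]) == (0.0, 0.0)
        assert (curve.points[-1][1], curve.points[-1][2]) == (1.0, 1.0)

    def test_auc_equals_pairwise_concordance(self):
        rng = np.random.default_rng(13)
        probs = np.round(rng.random(300), 2)  # rounding forces ties
        gold = ["POS" if x else "NEG" for x in rng.integers(0, 2, 300)]
        curve = roc_curve(probs, gold)
        pos = [p for p, g in zip(probs, gold) if g == "POS"]
        neg = [p for p, g in zip(probs, gold) if g == "NEG"]
        concordant = sum(
            1.0 if pp > pn else (0.5 if pp == pn else 0.0) for pp in pos for pn in neg
        )
        assert curve.auc == pytest.approx(concordant / (len(pos) * len(neg)), abs=1e-12)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(14)
        probs = rng.random(250)
        gold = ["POS" if x else "NEG" for x in rng.integers(0, 2, 250)]
        curve = roc_curve(probs, gold)
        assert curve.auc == pytest.approx(
            roc_auc_score([g == "POS" for g in gold], probs), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(15)
        probs = rng.random(100)
        gold = ["POS" if x else "NEG" for x in rng.integers(0, 2, 100)]
        transformed = probs**3  # strictly monotone on [0, 1]
        assert roc_curve(probs, gold).auc == pytest.approx(
            roc_curve(transformed, gold).auc
        )

    def test_single_class_rejected(self):
        with pytest.raises(TaxomineError):
            roc_curve([0.1, 0.9], ["POS", "POS"])

    def test_rates_monotone_in_boundary(self):
        rng = np.random.default_rng(16)
        probs = rng.random(200)
        gold = ["POS" if x else "NEG" for x in rng.integers(0, 2, 200)]
        prev_fpr, prev_recall = 1.0, 1.0
        for b in np.linspace(0, 1, 21):
            m = evaluate(probs, gold, boundary=float(b))
            assert m.fpr <= prev_fpr + 1e-12
            assert m.recall <= prev_recall + 1e-12
            prev_fpr, prev_recall = m.fpr, m.recall


class TestSelectBoundary:
    def test_separated_scores_reach_zero_fpr(self):
        sel = select_boundary([0.9, 0.8, 0.2, 0.1], ["POS", "POS", "NEG", "NEG"], 0.05)
        assert sel.fpr == 0.0 and sel.recall == 1.0
        assert 0.2 < sel.boundary <= 0.8

    def test_vacuous_target_takes_smallest_score(self):
        probs = [0.9, 0.3, 0.6, 0.2]
        sel = select_boundary(probs, ["POS", "NEG", "POS", "NEG"], 1.0)
        assert sel.boundary == 0.2 and sel.recall == 1.0

    def test_agrees_with_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(19)
        for trial in range(20):
            probs = np.round(rng.random(80), 2)
            gold = ["POS" if x else "NEG" for x in rng.integers(0, 2, 80)]
            if len(set(gold)) < 2:
                continue
            target = float(rng.uniform(0.05, 0.5))
            sel = select_boundary(probs, gold, target)
            feasible = []
            for b in np.unique(probs):
                m = evaluate(probs, gold, boundary=float(b))
                if m.fpr <= target:
                    feasible.append(float(b))
            assert sel.boundary == min(feasible)
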