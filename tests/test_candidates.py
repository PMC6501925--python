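"""Span recognition, candidate algebra and genus de-abbreviation."""

from __future__ import annotations

import numpy as np
import pytest

from taxomine.candidates import (
    INTERVAL,
    TAXON,
    UNRESOLVED,
    deabbreviate,
    dedupe_candidates,
    generate_candidates,
    match_spans,
    read_candidates_jsonl,
    write_candidates_jsonl,
)
from taxomine.corpus import Document, Sentence, Token
from taxomine.errors import TaxomineError
from taxomine.gazetteer import GeoInterval, IntervalGazetteer


def flat_sentence(words: list[str], doc_id: str = "d", sent_index: int = 0) -> Sentence:
    """All tokens hang off a final root; enough structure for span matching."""
    n = len(words)
    tokens = [Token(i + 1, w, n if i + 1 != n else 0, "dep" if i + 1 != n else "root")
              for i, w in enumerate(words)]
    return Sentence(doc_id, sent_index, tokens)


class TestMatchSpans:
    def test_binomial_with_qualifier_and_two_intervals(self, toy_taxa, toy_intervals):
        sentence = flat_sentence(
            "colonies of Setosellina cf. roulei have been found encrusting "
            "corals from the late Burdigalian and the Serravallian .".split()
        )
        spans = match_spans(sentence, toy_taxa, toy_intervals)
        assert [s.entity_type for s in spans] == [TAXON, INTERVAL, INTERVAL]
        taxon, burdigalian, serravallian = spans
        assert taxon.normalized == "Setosellina roulei"
        assert taxon.uncertain and not taxon.abbreviated
        assert burdigalian.surface == "late Burdigalian"
        assert burdigalian.end - burdigalian.start == 2
        assert serravallian.surface == "Serravallian"

    def test_longest_match_absorbs_modifier(self, toy_taxa, toy_intervals):
        spans = match_spans(
            flat_sentence("the lower Miocene beds".split()), toy_taxa, toy_intervals
        )
        assert len(spans) == 1
        assert spans[0].surface == "lower Miocene"
        assert spans[0].end - spans[0].start == 2

    def test_binomial_preferred_over_bare_genus(self, toy_taxa, toy_intervals):
        spans = match_spans(
            flat_sentence("Cribrilina punctata occurs here .".split()),
            toy_taxa, toy_intervals,
        )
        assert [s.normalized for s in spans] == ["Cribrilina punctata"]

    def test_synonym_genus_normalized(self, toy_taxa, toy_intervals):
        spans = match_spans(
            flat_sentence("Lepralia occurs here .".split()), toy_taxa, toy_intervals
        )
        assert spans[0].normalized == "Cribrilina"

    def test_abbreviated_mention_recognized(self, toy_taxa, toy_intervals):
        spans = match_spans(
            flat_sentence("C. punctata from the Serravallian .".split()),
            toy_taxa, toy_intervals,
        )
        assert spans[0].abbreviated and spans[0].normalized is None
        assert spans[1].entity_type == INTERVAL

    def test_planted_spans_recovered_exactly(self, gaz_bundle, corpus_bundle):
        checked = 0
        for document in corpus_bundle.documents:
            if checked >= 200:
                break
            for sentence in document.sentences:
                planted = [
                    s for s in corpus_bundle.planted_spans
                    if s.doc_id == document.doc_id and s.sent_index == sentence.sent_index
                ]
                got = match_spans(sentence, gaz_bundle.taxa, gaz_bundle.intervals)
                assert got == sorted(planted, key=lambda s: s.start)
                checked += 1

    def test_spans_nonoverlapping_and_sorted(self, gaz_bundle, corpus_bundle):
        for document in corpus_bundle.documents[:5]:
            for sentence in document.sentences:
                spans = match_spans(sentence, gaz_bundle.taxa, gaz_bundle.intervals)
                for a, b in zip(spans, spans[1:]):
                    assert a.start < b.start
                    assert a.end <= b.start


class TestGenerateCandidates:
    @pytest.mark.parametrize(
        "words,expected",
        [
            ("Cribrilina punctata from the Serravallian and the Miocene .", 2),
            ("Cribrilina and Setosellina from the Serravallian and the Miocene .", 4),
            ("Cribrilina punctata is a bryozoan .", 0),
        ],
    )
    def test_cartesian_counts(self, toy_taxa, toy_intervals, words, expected):
        doc = Document("d", [flat_sentence(words.split())])
        assert len(generate_candidates(doc, toy_taxa, toy_intervals)) == expected

    def test_count_identity_on_synthetic_corpus(self, gaz_bundle, corpus_bundle):
        for document in corpus_bundle.documents[:10]:
            for sentence in document.sentences:
                spans = match_spans(sentence, gaz_bundle.taxa, gaz_bundle.intervals)
                n_taxa = sum(1 for s in spans if s.entity_type == TAXON)
                n_intervals = sum(1 for s in spans if s.entity_type == INTERVAL)
                doc_one = Document(document.doc_id, [
                    Sentence(document.doc_id, 0, sentence.tokens)
                ])
                got = generate_candidates(doc_one, gaz_bundle.taxa, gaz_bundle.intervals)
                assert len(got) == n_taxa * n_intervals

    def test_candidate_ids_deterministic(self, toy_taxa, toy_intervals):
        doc = Document("d", [flat_sentence(
            "Cribrilina punctata from the Serravallian .".split()
        )])
        first = generate_candidates(doc, toy_taxa, toy_intervals)
        second = generate_candidates(doc, toy_taxa, toy_intervals)
        assert [c.candidate_id for c in first] == [c.candidate_id for c in second]


def _two_sentence_doc(first_words: str, second_words: str) -> Document:
    return Document("d", [
        flat_sentence(first_words.split(), sent_index=0),
        flat_sentence(second_words.split(), sent_index=1),
    ])


class TestDeabbreviate:
    def test_full_mention_resolves_nearby_abbreviation(self, toy_taxa, toy_intervals):
        doc = _two_sentence_doc(
            "Cribrilina punctata is described here .",
            "C. punctata occurs in the Serravallian .",
        )
        candidates = generate_candidates(doc, toy_taxa, toy_intervals)
        result = deabbreviate(doc, candidates, taxa=toy_taxa)
        assert result.n_abbreviated == 1 and result.n_resolved == 1
        (resolved,) = [c for c in result.candidates if c.taxon.abbreviated]
        assert resolved.genus == "Cribrilina"
        assert resolved.taxon.normalized == "Cribrilina punctata"

    def test_no_same_initial_mention_stays_unresolved(self, toy_taxa, toy_intervals):
        doc = _two_sentence_doc(
            "Setosellina roulei is described here .",
            "C. punctata occurs in the Serravallian .",
        )
        candidates = generate_candidates(doc, toy_taxa, toy_intervals)
        result = deabbreviate(doc, candidates, taxa=toy_taxa)
        (unresolved,) = [c for c in result.candidates if c.taxon.abbreviated]
        assert unresolved.genus == UNRESOLVED
        assert "unresolved_abbreviation" in unresolved.flags

    def test_window_bounds_lookback(self, toy_taxa, toy_intervals):
        filler = [flat_sentence("nothing here .".split(), sent_index=i) for i in range(1, 17)]
        doc = Document("d", [
            flat_sentence("Cribrilina punctata is described here .".split(), sent_index=0),
            *filler,
            flat_sentence("C. punctata occurs in the Serravallian .".split(), sent_index=17),
        ])
        candidates = generate_candidates(doc, toy_taxa, toy_intervals)
        result = deabbreviate(doc, candidates, window=15, taxa=toy_taxa)
        (c,) = [c for c in result.candidates if c.taxon.abbreviated]
        assert c.genus == UNRESOLVED

    def test_nearest_of_two_same_initial_genera_wins(self, toy_taxa, toy_intervals):
        # Cribrilina mentioned first, then the same-initial synonym target again
        doc = Document("d", [
            flat_sentence("Cribrilina punctata is described here .".split(), sent_index=0),
            flat_sentence("Membranipora also occurs .".split(), sent_index=1),
            flat_sentence("C. punctata occurs in the Serravallian .".split(), sent_index=2),
        ])
        candidates = generate_candidates(doc, toy_taxa, toy_intervals)
        result = deabbreviate(doc, candidates, taxa=toy_taxa)
        (c,) = [c for c in result.candidates if c.taxon.abbreviated]
        assert c.genus == "Cribrilina"

    def test_matches_backward_scan_oracle_on_synthetic_docs(
        self, gaz_bundle, corpus_bundle
    ):
        from taxomine.candidates import generate_candidates as gen

        rng = np.random.default_rng(3)
        docs = [corpus_bundle.documents[i]
                for i in rng.choice(len(corpus_bundle.documents), size=20, replace=False)]
        for document in docs:
            candidates = gen(document, gaz_bundle.taxa, gaz_bundle.intervals)
            result = deabbreviate(document, candidates, taxa=gaz_bundle.taxa)
            # oracle: literal backward scan over raw tokens
            for c in result.candidates:
                if not c.taxon.abbreviated:
                    continue
                initial = c.taxon.surface[0]
                expected = UNRESOLVED
                done = False
                for sent in reversed(document.sentences[: c.taxon.sent_index + 1]):
                    if done or sent.sent_index < c.taxon.sent_index - 15:
                        break
                    limit = (
                        c.taxon.start if sent.sent_index == c.taxon.sent_index
                        else len(sent.tokens) + 1
                    )
                    for t in reversed(sent.tokens[: limit - 1]):
                        name = t.text
                        if name in gaz_bundle.taxa.synonyms:
                            name = gaz_bundle.taxa.synonyms[name]
                        if name in gaz_bundle.taxa.genera and name[0] == initial:
                            expected = name
                            done = True
                            break
                assert c.genus == expected

    def test_never_alters_full_mentions(self, gaz_bundle, corpus_bundle, pipeline_candidates):
        document = corpus_bundle.documents[0]
        candidates = generate_candidates(document, gaz_bundle.taxa, gaz_bundle.intervals)
        result = deabbreviate(document, candidates, taxa=gaz_bundle.taxa)
        for before, after in zip(candidates, result.candidates):
            if not before.taxon.abbreviated:
                assert after is before

    def test_window_must_be_positive(self, toy_taxa, toy_intervals):
        doc = _two_sentence_doc("a b .", "c d .")
        with pytest.raises(TaxomineError):
            deabbreviate(doc, [], window=0)


class TestDedupe:
    def test_identical_candidates_collapse(self, toy_taxa, toy_intervals):
        doc = Document("d", [
            flat_sentence("Cribrilina punctata from the Serravallian .".split(), sent_index=0),
            flat_sentence("Cribrilina punctata from the Serravallian .".split(), sent_index=1),
        ])
        candidates = generate_candidates(doc, toy_taxa, toy_intervals)
        assert len(candidates) == 2
        assert len(dedupe_candidates(candidates)) == 1

    def test_different_sentence_text_kept(self, toy_taxa, toy_intervals):
        doc = Document("d", [
            flat_sentence("Cribrilina punctata from the Serravallian .".split(), sent_index=0),
            flat_sentence("Cribrilina punctata in the Serravallian .".split(), sent_index=1),
        ])
        candidates = generate_candidates(doc, toy_taxa, toy_intervals)
        assert len(dedupe_candidates(candidates)) == 2

    def test_idempotent_on_synthetic_candidates(self, pipeline_candidates):
        once = dedupe_candidates(pipeline_candidates)
        assert dedupe_candidates(once) == once


def test_jsonl_roundtrip(tmp_path, pipeline_candidates):
    path = tmp_path / "candidates.jsonl"
    subset = pipeline_candidates[:50]
    write_candidates_jsonl(subset, path)
    loaded = read_candidates_jsonl(path)
    assert len(loaded) == 50
    for a, b in zip(subset, loaded):
        assert a.candidate_id == b.candidate_id
        assert a.taxon == b.taxon and a.interval == b.interval
        assert a.genus == b.genus and a.species == b.species
        assert a.sentence.tokens == b.sentence.tokens
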