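"""Shared fixtures: toy gazetteers and one session-scoped synthetic study.

The expensive pieces (corpus generation, extraction, classifier training)
run once per session and are reused by the classifier, richness and
acceptance tests.
"""

from __future__ import annotations

import pytest

from taxomine.candidates import deabbreviate, generate_candidates
from taxomine.gazetteer import GeoInterval, IntervalGazetteer, TaxonGazetteer
from taxomine.relation import (
    TRAIN, TEST, VALIDATION,
    ClassifierConfig,
    candidate_sdpath,
    split_by_document,
    train_classifier,
)
from taxomine.synthgen import SynthSpec, make_corpus, make_gazetteers


@pytest.fixture()
def toy_taxa() -> TaxonGazetteer:
    return TaxonGazetteer(
        genera={"Cribrilina", "Setosellina", "Membranipora"},
        binomials={"Cribrilina punctata", "Setosellina roulei"},
        synonyms={"Lepralia": "Cribrilina"},
    )


@pytest.fixture()
def toy_intervals() -> IntervalGazetteer:
    return IntervalGazetteer(
        intervals={
            "Serravallian": GeoInterval("Serravallian", 14.0, 11.0),
            "Burdigalian": GeoInterval("Burdigalian", 20.0, 16.0),
            "Miocene": GeoInterval("Miocene", 23.0, 5.0),
            "Cretaceous": GeoInterval("Cretaceous", 145.0, 66.0),
        }
    )


@pytest.fixture(scope="session")
def synth_spec() -> SynthSpec:
    return SynthSpec()


@pytest.fixture(scope="session")
def gaz_bundle(synth_spec):
    return make_gazetteers(synth_spec)


@pytest.fixture(scope="session")
def corpus_bundle(synth_spec, gaz_bundle):
    return make_corpus(synth_spec, gaz_bundle)


@pytest.fixture(scope="session")
def pipeline_candidates(gaz_bundle, corpus_bundle):
    """Extracted, de-abbreviated candidates with template gold labels attached."""
    out = []
    for document in corpus_bundle.documents:
        extracted = generate_candidates(document, gaz_bundle.taxa, gaz_bundle.intervals)
        result = deabbreviate(document, extracted, taxa=gaz_bundle.taxa)
        out.extend(result.candidates)
    corpus_bundle.attach_gold(out)
    return out


@pytest.fixture(scope="session")
def labelled_split(pipeline_candidates):
    labelled = [c for c in pipeline_candidates if c.gold is not None]
    split = split_by_document(labelled, seed=0)
    parts = split.partition(labelled)
    out = {}
    for name in (TRAIN, VALIDATION, TEST):
        out[name] = [(candidate_sdpath(c), c.gold) for c in parts[name]]
    out["assignment"] = split
    return out


@pytest.fixture(scope="session")
def trained_model(labelled_split):
    config = ClassifierConfig(seed=0)
    return train_classifier(labelled_split[TRAIN], labelled_split[VALIDATION], config)
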