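"""Rule-based entity recognition and taxon-interval candidate generation.

Spans are recognized by longest-match, leftmost-first gazetteer scanning:
binomial taxon matches ("Setosellina roulei", optionally with an open
nomenclature qualifier "cf."/"aff." absorbed into the span) beat bare genus
matches at the same start, which beat interval matches; interval matching
tries a modifier-prefixed name ("lower Miocene") before the bare name.
Abbreviated genus mentions ("C. punctata") are recognized structurally and
resolved later by a 15-sentence lookback (:func:`deabbreviate`).

Every (taxon span, interval span) pair within one sentence becomes a
Candidate — the unit of relation classification. Candidates are independent
records; no cross-sentence pairing or coreference is attempted.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

from taxomine.corpus import Document, Sentence, Token
from taxomine.errors import TaxomineError
from taxomine.gazetteer import (
    IntervalGazetteer,
    TaxonGazetteer,
    resolve_interval,
    standardize_genus,
)
from taxomine.errors import IntervalLookupError

#: Sentinel genus for abbreviated mentions the lookback could not resolve.
UNRESOLVED = "UNRESOLVED"

_ABBREV_RE = re.compile(r"^[A-Z]\.$")
_EPITHET_RE = re.compile(r"^[a-z][a-z-]+$")
_UNCERTAIN_TOKENS = {"cf.", "aff."}
_UNCERTAIN_BARE = {"cf", "aff"}

TAXON = "TAXON"
INTERVAL = "INTERVAL"


@dataclass(frozen=True)
class Span:
    """One or more consecutive tokens denoting a single entity.

    ``start``/``end`` are half-open over 1-based token indices. ``normalized``
    holds the canonical genus/binomial for taxon spans (None while an
    abbreviated genus is unresolved) or the interval name as written for
    interval spans (resolvable through the interval gazetteer, possibly via
    modifier-stripping fallback).
    """

    doc_id: str
    sent_index: int
    start: int
    end: int
    entity_type: str
    surface: str
    normalized: str | None
    abbreviated: bool = False
    uncertain: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise TaxomineError(f"span start {self.start} must precede end {self.end}")


@dataclass
class Candidate:
    """A (taxon span, interval span) pair co-occurring in one sentence."""

    candidate_id: str
    taxon: Span
    interval: Span
    sentence: Sentence
    genus: str
    species: str | None = None
    gold: str | None = None      # "POS" / "NEG" / None
    prob: float | None = None
    flags: tuple[str, ...] = ()


def _candidate_id(taxon: Span, interval: Span) -> str:
    key = "|".join(
        [
            taxon.doc_id,
            str(taxon.sent_index),
            f"{taxon.start}:{taxon.end}",
            f"{interval.start}:{interval.end}",
            taxon.normalized or taxon.surface,
            interval.normalized or interval.surface,
        ]
    )
    return hashlib.sha1(key.encode("utf-8")).hexdigest()[:16]


def _consume_uncertainty(tokens: list[Token], j: int) -> int:
    """Number of tokens of an open-nomenclature qualifier at position j (0 if none)."""
    if j < len(tokens) and tokens[j].text in _UNCERTAIN_TOKENS:
        return 1
    if (
        j + 1 < len(tokens)
        and tokens[j].text in _UNCERTAIN_BARE
        and tokens[j + 1].text == "."
    ):
        return 2
    return 0


class _Match(NamedTuple):
    length: int
    priority: int  # lower is better at equal length
    span: Span


def _taxon_matches(
    sentence: Sentence, i: int, taxa: TaxonGazetteer
) -> list[_Match]:
    tokens = sentence.tokens
    word = tokens[i].text
    out: list[_Match] = []
    known_genus = word in taxa.genera or word in taxa.synonyms
    if known_genus:
        canonical = standardize_genus(word, taxa).genus
        # binomial: genus [cf.] epithet
        unc = _consume_uncertainty(tokens, i + 1)
        j = i + 1 + unc
        if j < len(tokens):
            epithet = tokens[j].text
            if f"{canonical} {epithet}" in taxa.binomials or f"{word} {epithet}" in taxa.binomials:
                end = j + 1
                out.append(
                    _Match(
                        end - i,
                        0,
                        Span(
                            sentence.doc_id,
                            sentence.sent_index,
                            i + 1,
                            end + 1,
                            TAXON,
                            " ".join(t.text for t in tokens[i:end]),
                            f"{canonical} {epithet}",
                            uncertain=unc > 0,
                        ),
                    )
                )
        out.append(
            _Match(
                1,
                1,
                Span(
                    sentence.doc_id,
                    sentence.sent_index,
                    i + 1,
                    i + 2,
                    TAXON,
                    word,
                    canonical,
                ),
            )
        )
    elif _ABBREV_RE.match(word):
        unc = _consume_uncertainty(tokens, i + 1)
        j = i + 1 + unc
        if j < len(tokens) and _EPITHET_RE.match(tokens[j].text):
            end = j + 1
            out.append(
                _Match(
                    end - i,
                    1,
                    Span(
                        sentence.doc_id,
                        sentence.sent_index,
                        i + 1,
                        end + 1,
                        TAXON,
                        " ".join(t.text for t in tokens[i:end]),
                        None,
                        abbreviated=True,
                        uncertain=unc > 0,
                    ),
                )
            )
    return out


def _interval_matches(
    sentence: Sentence, i: int, intervals: IntervalGazetteer
) -> list[_Match]:
    tokens = sentence.tokens
    out: list[_Match] = []
    # widest window: optional modifier + longest gazetteer name
    widest = intervals.max_name_tokens + 1
    for width in range(min(widest, len(tokens) - i), 0, -1):
        surface = " ".join(t.text for t in tokens[i : i + width])
        try:
            resolve_interval(surface, intervals)
        except (IntervalLookupError, TaxomineError):
            continue
        out.append(
            _Match(
                width,
                2,
                Span(
                    sentence.doc_id,
                    sentence.sent_index,
                    i + 1,
                    i + 1 + width,
                    INTERVAL,
                    surface,
                    surface,
                ),
            )
        )
        break  # widths below the longest hit are shadowed by longest-match
    return out


def match_spans(
    sentence: Sentence, taxa: TaxonGazetteer, intervals: IntervalGazetteer
) -> list[Span]:
    """Recognize taxon and interval spans, longest-match and leftmost-first.

    Output spans are pairwise non-overlapping and sorted by start; at equal
    start and length a taxon binomial beats a bare genus beats an interval.
    """
    spans: list[Span] = []
    i = 0
    n = len(sentence.tokens)
    while i < n:
        matches = _taxon_matches(sentence, i, taxa) + _interval_matches(sentence, i, intervals)
        if not matches:
            i += 1
            continue
        best = max(matches, key=lambda m: (m.length, -m.priority))
        spans.append(best.span)
        i = best.span.end - 1  # end is 1-based exclusive -> next 0-based position
    return spans


def generate_candidates(
    document: Document, taxa: TaxonGazetteer, intervals: IntervalGazetteer
) -> list[Candidate]:
    """Cartesian taxon x interval candidate pairs, one sentence at a time."""
    out: list[Candidate] = []
    for sentence in document.sentences:
        spans = match_spans(sentence, taxa, intervals)
        taxon_spans = [s for s in spans if s.entity_type == TAXON]
        interval_spans = [s for s in spans if s.entity_type == INTERVAL]
        for t in taxon_spans:
            for iv in interval_spans:
                if t.abbreviated:
                    genus = UNRESOLVED
                    species = t.surface.split(" ")[-1]
                else:
                    parts = (t.normalized or t.surface).split(" ")
                    genus = parts[0]
                    species = parts[1] if len(parts) > 1 else None
                out.append(
                    Candidate(
                        candidate_id=_candidate_id(t, iv),
                        taxon=t,
                        interval=iv,
                        sentence=sentence,
                        genus=genus,
                        species=species,
                    )
                )
    return out


class DeabbreviationResult(NamedTuple):
    candidates: list[Candidate]
    n_abbreviated: int
    n_resolved: int

    @property
    def resolved_fraction(self) -> float | None:
        if self.n_abbreviated == 0:
            return None
        return self.n_resolved / self.n_abbreviated


def _full_genus_mentions(
    document: Document,
    candidates: Iterable[Candidate],
    taxa: TaxonGazetteer | None,
) -> list[tuple[int, int, str]]:
    """(sent_index, token position, canonical genus) of every full mention."""
    mentions: list[tuple[int, int, str]] = []
    if taxa is not None:
        for sentence in document.sentences:
            for t in sentence.tokens:
                if t.text in taxa.genera or t.text in taxa.synonyms:
                    mentions.append(
                        (sentence.sent_index, t.index, standardize_genus(t.text, taxa).genus)
                    )
    else:
        seen = set()
        for c in candidates:
            if not c.taxon.abbreviated:
                key = (c.taxon.sent_index, c.taxon.start, c.genus)
                if key not in seen:
                    seen.add(key)
                    mentions.append(key)
    mentions.sort()
    return mentions


def deabbreviate(
    document: Document,
    candidates: list[Candidate],
    window: int = 15,
    taxa: TaxonGazetteer | None = None,
) -> DeabbreviationResult:
    """Resolve abbreviated genus mentions by lookback over full mentions.

    For each candidate whose taxon span is abbreviated ("C. punctata"), the
    nearest preceding full genus mention beginning with the same capital
    letter, within the previous ``window`` sentences (same-sentence mentions
    earlier in the token stream also qualify), supplies the genus. Unresolved
    candidates keep genus=UNRESOLVED and are flagged. When a taxon gazetteer
    is supplied, full mentions are scanned from all document tokens and the
    abbreviated epithet is checked against the resolved genus's known
    binomials (mismatches are accepted but flagged "epithet_mismatch").
    """
    if window < 1:
        raise TaxomineError(f"lookback window must be >= 1, got {window}")
    mentions = _full_genus_mentions(document, candidates, taxa)
    out: list[Candidate] = []
    n_abbrev = n_resolved = 0
    for c in candidates:
        if not c.taxon.abbreviated or c.taxon.doc_id != document.doc_id:
            out.append(c)
            continue
        n_abbrev += 1
        initial = c.taxon.surface[0]
        here = (c.taxon.sent_index, c.taxon.start)
        best: tuple[int, int, str] | None = None
        for sent, pos, genus in mentions:
            if (sent, pos) >= here or sent < c.taxon.sent_index - window:
                continue
            if genus[0] != initial:
                continue
            if best is None or (sent, pos) > best[:2]:
                best = (sent, pos, genus)
        if best is None:
            out.append(replace(c, flags=c.flags + ("unresolved_abbreviation",)))
            continue
        n_resolved += 1
        genus = best[2]
        flags = c.flags
        if taxa is not None and c.species is not None:
            known = taxa.epithets_of(genus)
            if known and c.species not in known:
                flags = flags + ("epithet_mismatch",)
        out.append(
            replace(
                c,
                genus=genus,
                taxon=replace(c.taxon, normalized=f"{genus} {c.species}" if c.species else genus),
                flags=flags,
            )
        )
    return DeabbreviationResult(out, n_abbrev, n_resolved)


def dedupe_candidates(candidates: list[Candidate]) -> list[Candidate]:
    """Collapse repeats of the same normalized relation in the same sentence text.

    Key: (doc_id, genus+species, normalized interval, sentence text); the
    first occurrence wins and output order is stable.
    """
    seen: set[tuple] = set()
    out: list[Candidate] = []
    for c in candidates:
        key = (
            c.taxon.doc_id,
            c.genus,
            c.species,
            c.interval.normalized or c.interval.surface,
            c.sentence.text(),
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# JSON-lines serialization (one object per candidate, sentence inlined)


def candidate_to_dict(c: Candidate) -> dict:
    def span_d(s: Span) -> dict:
        return {
            "start": s.start,
            "end": s.end,
            "entity_type": s.entity_type,
            "surface": s.surface,
            "normalized": s.normalized,
            "abbreviated": s.abbreviated,
            "uncertain": s.uncertain,
        }

    return {
        "candidate_id": c.candidate_id,
        "doc_id": c.taxon.doc_id,
        "sent_index": c.taxon.sent_index,
        "taxon": span_d(c.taxon),
        "interval": span_d(c.interval),
        "genus": c.genus,
        "species": c.species,
        "gold": c.gold,
        "prob": c.prob,
        "flags": list(c.flags),
        "sentence": {
            "tokens": [
                {"index": t.index, "text": t.text, "head": t.head, "deprel": t.deprel, "pos": t.pos}
                for t in c.sentence.tokens
            ],
        },
    }


def candidate_from_dict(d: dict) -> Candidate:
    doc_id, sent_index = d["doc_id"], d["sent_index"]

    def span(s: dict, etype: str) -> Span:
        return Span(
            doc_id, sent_index, s["start"], s["end"], etype,
            s["surface"], s["normalized"], s["abbreviated"], s["uncertain"],
        )

    sentence = Sentence(
        doc_id,
        sent_index,
        [Token(t["index"], t["text"], t["head"], t["deprel"], t.get("pos")) for t in d["sentence"]["tokens"]],
    )
    return Candidate(
        candidate_id=d["candidate_id"],
        taxon=span(d["taxon"], TAXON),
        interval=span(d["interval"], INTERVAL),
        sentence=sentence,
        genus=d["genus"],
        species=d.get("species"),
        gold=d.get("gold"),
        prob=d.get("prob"),
        flags=tuple(d.get("flags", ())),
    )


def write_candidates_jsonl(candidates: Iterable[Candidate], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in candidates:
            fh.write(json.dumps(candidate_to_dict(c), sort_keys=True) + "\n")


def read_candidates_jsonl(path: str | Path) -> list[Candidate]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(candidate_from_dict(json.loads(line)))
    return out
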