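"""Download-free synthetic fixtures for the whole pipeline.

The generator emits everything the pipeline consumes: Latin-like taxon and
interval gazetteers, templated positive/negative relation sentences with
hand-authored dependency trees (so shortest-path ground truth is exact and
no live parser is involved), planted span/candidate manifests with gold
labels, simulated two-annotator label noise, and OCR-like token corruption.

Positive templates state or strongly imply that the taxon occurred in the
interval; negative templates mention both entities without asserting an
occurrence, including the classic hard case where the interval modifies a
family-authority context ("... the type species of the <INTERVAL> to Recent
family ..."). Because the two polarities use disjoint connective
vocabulary, the classes are separable from path tokens alone — by design,
so classifier tests have a known ceiling.

All outputs are deterministic functions of :class:`SynthSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from taxomine.candidates import INTERVAL, TAXON, Candidate, Span
from taxomine.corpus import Document, Sentence, Token
from taxomine.errors import TaxomineError
from taxomine.gazetteer import GeoInterval, IntervalGazetteer, TaxonGazetteer
from taxomine.goldlabels import NEG, POS, Annotation


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic data set.

    Defaults give ~2000 candidate pairs across 50 documents; the annotator
    error rate of 0.087 makes the expected two-annotator agreement
    (1-e)^2 + e^2 ~ 0.84, in line with observed human repeatability on this
    kind of labelling task.
    """

    n_taxa: int = 60
    n_intervals: int = 24
    n_docs: int = 50
    sentences_per_doc: int = 45
    p_positive: float = 0.5
    n_positive_templates: int = 7
    n_negative_templates: int = 7
    abbrev_rate: float = 0.25
    annotator_error_rate: float = 0.087
    ocr_noise_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.p_positive, self.abbrev_rate,
            self.annotator_error_rate, self.ocr_noise_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise TaxomineError("all rates must lie in [0, 1]")
        counts = (
            self.n_taxa, self.n_intervals, self.n_docs, self.sentences_per_doc,
            self.n_positive_templates, self.n_negative_templates,
        )
        if any(c <= 0 for c in counts):
            raise TaxomineError("all counts must be positive")
        if self.n_positive_templates > len(POSITIVE_TEMPLATES):
            raise TaxomineError(f"at most {len(POSITIVE_TEMPLATES)} positive templates exist")
        if self.n_negative_templates > len(NEGATIVE_TEMPLATES):
            raise TaxomineError(f"at most {len(NEGATIVE_TEMPLATES)} negative templates exist")


# ---------------------------------------------------------------------------
# Name generation

_ONSETS = ["b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v", "cr", "pl", "st", "th"]
_VOWELS = ["a", "e", "i", "o", "u"]
_CODAS = ["", "n", "r", "s", "x", "ll", "tt"]

# words that appear literally in templates; generated names must avoid them
_BANNED = {
    "Colonies", "We", "The", "Specimens", "Unlike", "Whether", "Previous",
    "Recent", "Material",
}


def _syllable(rng: np.random.Generator) -> str:
    return (
        _ONSETS[rng.integers(len(_ONSETS))]
        + _VOWELS[rng.integers(len(_VOWELS))]
        + _CODAS[rng.integers(len(_CODAS))]
    )


def _word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables)).replace("xx", "x")


def _fresh_name(rng: np.random.Generator, taken: set[str], suffix: str = "", capital: bool = True) -> str:
    while True:
        base = _word(rng, int(rng.integers(2, 4))) + suffix
        name = base.capitalize() if capital else base
        if name not in taken and name not in _BANNED:
            taken.add(name)
            return name


# ---------------------------------------------------------------------------
# Gazetteer generation


@dataclass
class GazetteerManifest:
    genera: list[str]
    binomials: list[str]
    synonyms: dict[str, str]
    extant_genera: list[str]
    intervals: list[GeoInterval]


@dataclass
class GazetteerBundle:
    taxa: TaxonGazetteer
    intervals: IntervalGazetteer
    manifest: GazetteerManifest


def make_gazetteers(spec: SynthSpec) -> GazetteerBundle:
    """Non-colliding Latin-like taxa plus nested interval bins over 160-0 Ma."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    taken: set[str] = set()
    genera = [_fresh_name(rng, taken) for _ in range(spec.n_taxa)]
    binomials: list[str] = []
    for genus in genera:
        for _ in range(int(rng.integers(1, 4))):
            epithet = _fresh_name(rng, taken, capital=False)
            binomials.append(f"{genus} {epithet}")
    n_syn = max(1, spec.n_taxa // 10)
    synonyms = {
        _fresh_name(rng, taken): genera[int(rng.integers(len(genera)))]
        for _ in range(n_syn)
    }
    extant = sorted(
        genera[i] for i in rng.choice(len(genera), size=max(1, spec.n_taxa * 3 // 10), replace=False)
    )

    # contiguous "stage" bins partitioning 160-0 Ma, plus coarse super-intervals
    n_stages = spec.n_intervals
    weights = rng.dirichlet(np.full(n_stages, 3.0))
    widths = 160.0 * (0.5 / n_stages + 0.5 * weights)  # min width keeps bins nonzero
    edges = np.concatenate([[160.0], 160.0 - np.cumsum(widths)])
    edges[-1] = 0.0
    edges = np.round(edges, 2)
    intervals: list[GeoInterval] = []
    for i in range(n_stages):
        name = _fresh_name(rng, taken, suffix="ian")
        intervals.append(GeoInterval(name, float(edges[i]), float(edges[i + 1])))
    if n_stages >= 3:
        n_super = min(max(2, n_stages // 6), n_stages - 1)
        bounds = sorted(rng.choice(n_stages - 1, size=n_super, replace=False))
        lo = 0
        for hi in list(bounds) + [n_stages - 1]:
            if hi > lo:  # super-interval spanning stages lo..hi (nested bins)
                name = _fresh_name(rng, taken, suffix="cene")
                intervals.append(GeoInterval(name, float(edges[lo]), float(edges[hi + 1])))
            lo = hi + 1

    taxa = TaxonGazetteer(genera=set(genera), binomials=set(binomials), synonyms=synonyms)
    interval_gaz = IntervalGazetteer(intervals={iv.name: iv for iv in intervals})
    manifest = GazetteerManifest(
        genera=genera, binomials=binomials, synonyms=synonyms,
        extant_genera=extant, intervals=intervals,
    )
    return GazetteerBundle(taxa=taxa, intervals=interval_gaz, manifest=manifest)


# ---------------------------------------------------------------------------
# Sentence templates with hand-authored dependency trees
#
# A template is a list of (id, form, head_id, deprel); head_id "" = root.
# Forms "<TAXON>" and "<INTERVAL>"/"<INTERVAL2>" are slots; the slot node is
# the span's syntactic base token, and extra span tokens (epithet, "cf.",
# modifier) attach to it during expansion.

TemplateNode = tuple[str, str, str, str]
Template = list[TemplateNode]

POSITIVE_TEMPLATES: list[Template] = [
    [  # Colonies of X have been found in the I .
        ("col", "Colonies", "found", "nsubj:pass"),
        ("of", "of", "tax", "case"),
        ("tax", "<TAXON>", "col", "nmod"),
        ("have", "have", "found", "aux"),
        ("been", "been", "found", "aux:pass"),
        ("found", "found", "", "root"),
        ("in", "in", "int", "case"),
        ("the", "the", "int", "det"),
        ("int", "<INTERVAL>", "found", "obl"),
        ("p", ".", "found", "punct"),
    ],
    [  # X occurs in I deposits .
        ("tax", "<TAXON>", "occ", "nsubj"),
        ("occ", "occurs", "", "root"),
        ("in", "in", "dep", "case"),
        ("int", "<INTERVAL>", "dep", "compound"),
        ("dep", "deposits", "occ", "obl"),
        ("p", ".", "occ", "punct"),
    ],
    [  # We recorded X from the I of the basin .
        ("we", "We", "rec", "nsubj"),
        ("rec", "recorded", "", "root"),
        ("tax", "<TAXON>", "rec", "obj"),
        ("from", "from", "int", "case"),
        ("the1", "the", "int", "det"),
        ("int", "<INTERVAL>", "rec", "obl"),
        ("of", "of", "bas", "case"),
        ("the2", "the", "bas", "det"),
        ("bas", "basin", "int", "nmod"),
        ("p", ".", "rec", "punct"),
    ],
    [  # X is known from the I .
        ("tax", "<TAXON>", "kn", "nsubj:pass"),
        ("is", "is", "kn", "aux:pass"),
        ("kn", "known", "", "root"),
        ("from", "from", "int", "case"),
        ("the", "the", "int", "det"),
        ("int", "<INTERVAL>", "kn", "obl"),
        ("p", ".", "kn", "punct"),
    ],
    [  # The species X persists into the I .
        ("the", "The", "sp", "det"),
        ("sp", "species", "per", "nsubj"),
        ("tax", "<TAXON>", "sp", "appos"),
        ("per", "persists", "", "root"),
        ("into", "into", "int", "case"),
        ("the2", "the", "int", "det"),
        ("int", "<INTERVAL>", "per", "obl"),
        ("p", ".", "per", "punct"),
    ],
    [  # Specimens of X were collected from I strata .
        ("spec", "Specimens", "coll", "nsubj:pass"),
        ("of", "of", "tax", "case"),
        ("tax", "<TAXON>", "spec", "nmod"),
        ("were", "were", "coll", "aux:pass"),
        ("coll", "collected", "", "root"),
        ("from", "from", "str", "case"),
        ("int", "<INTERVAL>", "str", "compound"),
        ("str", "strata", "coll", "obl"),
        ("p", ".", "coll", "punct"),
    ],
    [  # X ranges from the I to the I2 .
        ("tax", "<TAXON>", "rng", "nsubj"),
        ("rng", "ranges", "", "root"),
        ("from", "from", "int", "case"),
        ("the1", "the", "int", "det"),
        ("int", "<INTERVAL>", "rng", "obl"),
        ("to", "to", "int2", "case"),
        ("the2", "the", "int2", "det"),
        ("int2", "<INTERVAL2>", "rng", "obl"),
        ("p", ".", "rng", "punct"),
    ],
]

NEGATIVE_TEMPLATES: list[Template] = [
    [  # X is the type species of the I to Recent family .  (authority context)
        ("tax", "<TAXON>", "sp", "nsubj"),
        ("is", "is", "sp", "cop"),
        ("the1", "the", "sp", "det"),
        ("type", "type", "sp", "compound"),
        ("sp", "species", "", "root"),
        ("of", "of", "fam", "case"),
        ("the2", "the", "fam", "det"),
        ("int", "<INTERVAL>", "fam", "amod"),
        ("to", "to", "rec", "case"),
        ("rec", "Recent", "int", "nmod"),
        ("fam", "family", "sp", "nmod"),
        ("p", ".", "sp", "punct"),
    ],
    [  # The I fauna described here does not include X .
        ("the", "The", "fau", "det"),
        ("int", "<INTERVAL>", "fau", "compound"),
        ("fau", "fauna", "inc", "nsubj"),
        ("desc", "described", "fau", "acl"),
        ("here", "here", "desc", "advmod"),
        ("does", "does", "inc", "aux"),
        ("not", "not", "inc", "advmod"),
        ("inc", "include", "", "root"),
        ("tax", "<TAXON>", "inc", "obj"),
        ("p", ".", "inc", "punct"),
    ],
    [  # X differs from congeners reported from the I .
        ("tax", "<TAXON>", "dif", "nsubj"),
        ("dif", "differs", "", "root"),
        ("from1", "from", "con", "case"),
        ("con", "congeners", "dif", "obl"),
        ("rep", "reported", "con", "acl"),
        ("from2", "from", "int", "case"),
        ("the", "the", "int", "det"),
        ("int", "<INTERVAL>", "rep", "obl"),
        ("p", ".", "dif", "punct"),
    ],
    [  # Unlike X , most species here are restricted to the I .
        ("unl", "Unlike", "tax", "case"),
        ("tax", "<TAXON>", "res", "obl"),
        ("c", ",", "res", "punct"),
        ("most", "most", "sp", "amod"),
        ("sp", "species", "res", "nsubj:pass"),
        ("here", "here", "res", "advmod"),
        ("are", "are", "res", "aux:pass"),
        ("res", "restricted", "", "root"),
        ("to", "to", "int", "case"),
        ("the", "the", "int", "det"),
        ("int", "<INTERVAL>", "res", "obl"),
        ("p", ".", "res", "punct"),
    ],
    [  # Whether X survived into the I remains doubtful .
        ("wh", "Whether", "sur", "mark"),
        ("tax", "<TAXON>", "sur", "nsubj"),
        ("sur", "survived", "rem", "csubj"),
        ("into", "into", "int", "case"),
        ("the", "the", "int", "det"),
        ("int", "<INTERVAL>", "sur", "obl"),
        ("rem", "remains", "", "root"),
        ("dbt", "doubtful", "rem", "xcomp"),
        ("p", ".", "rem", "punct"),
    ],
    [  # Previous reports of X from the I are considered erroneous .
        ("prev", "Previous", "rep", "amod"),
        ("rep", "reports", "cons", "nsubj:pass"),
        ("of", "of", "tax", "case"),
        ("tax", "<TAXON>", "rep", "nmod"),
        ("from", "from", "int", "case"),
        ("the", "the", "int", "det"),
        ("int", "<INTERVAL>", "rep", "nmod"),
        ("are", "are", "cons", "aux:pass"),
        ("cons", "considered", "", "root"),
        ("err", "erroneous", "cons", "xcomp"),
        ("p", ".", "cons", "punct"),
    ],
    [  # The I sections lack any trace of X .
        ("the", "The", "sec", "det"),
        ("int", "<INTERVAL>", "sec", "compound"),
        ("sec", "sections", "lack", "nsubj"),
        ("lack", "lack", "", "root"),
        ("any", "any", "tr", "det"),
        ("tr", "trace", "lack", "obj"),
        ("of", "of", "tax", "case"),
        ("tax", "<TAXON>", "tr", "nmod"),
        ("p", ".", "lack", "punct"),
    ],
]

# taxon-only sentences that plant full genus mentions for later abbreviations
MENTION_TEMPLATE: Template = [
    ("tax", "<TAXON>", "com", "nsubj"),
    ("is", "is", "com", "cop"),
    ("com", "common", "", "root"),
    ("in", "in", "coll", "case"),
    ("this", "this", "coll", "det"),
    ("coll", "collection", "com", "nmod"),
    ("p", ".", "com", "punct"),
]

_MENTION_SENTENCE_RATE = 0.15
_GENUS_ONLY_RATE = 0.15
_UNCERTAIN_RATE = 0.08
_MODIFIER_RATE = 0.3
_MODIFIER_CHOICES = ["early", "middle", "late"]


def _validate_template(template: Template) -> None:
    ids = [n[0] for n in template]
    if len(set(ids)) != len(ids):
        raise TaxomineError("template node ids must be unique")
    roots = [n for n in template if n[2] == ""]
    if len(roots) != 1:
        raise TaxomineError("template must have exactly one root")
    known = set(ids)
    for node_id, _, head, _ in template:
        if head and head not in known:
            raise TaxomineError(f"template head {head!r} of {node_id!r} undefined")
        if head == node_id:
            raise TaxomineError(f"template node {node_id!r} is its own head")


for _t in POSITIVE_TEMPLATES + NEGATIVE_TEMPLATES + [MENTION_TEMPLATE]:
    _validate_template(_t)


@dataclass(frozen=True)
class TaxonMention:
    genus: str
    species: str | None          # epithet, if the mention carries one
    abbreviated: bool
    uncertain: bool

    def tokens(self) -> list[str]:
        head = f"{self.genus[0]}." if self.abbreviated else self.genus
        out = [head]
        if self.species is not None:
            if self.uncertain:
                out.append("cf.")
            out.append(self.species)
        return out


@dataclass(frozen=True)
class IntervalMention:
    name: str
    modifier: str | None

    def tokens(self) -> list[str]:
        return ([self.modifier] if self.modifier else []) + [self.name]

    @property
    def surface(self) -> str:
        return " ".join(self.tokens())


def _instantiate(
    template: Template,
    doc_id: str,
    sent_index: int,
    taxon: TaxonMention | None,
    intervals_by_slot: dict[str, IntervalMention],
) -> tuple[Sentence, list[Span]]:
    """Expand slots into tokens, renumber heads, and report planted spans."""
    token_rows: list[tuple[str, str, str]] = []   # (owner node id, text, deprel-or-"")
    spans_raw: list[tuple[int, int, str, TaxonMention | IntervalMention]] = []
    for node_id, form, _, _ in template:
        start = len(token_rows) + 1
        if form == "<TAXON>":
            assert taxon is not None
            toks = taxon.tokens()
            token_rows.append((node_id, toks[0], ""))
            for extra in toks[1:]:
                deprel = "fixed" if extra == "cf." else "flat"
                token_rows.append((node_id + "+", extra, deprel))
            spans_raw.append((start, start + len(toks), TAXON, taxon))
        elif form.startswith("<INTERVAL"):
            mention = intervals_by_slot[node_id]
            toks = mention.tokens()
            if mention.modifier:
                token_rows.append((node_id + "+", toks[0], "amod"))
                token_rows.append((node_id, toks[1], ""))
            else:
                token_rows.append((node_id, toks[0], ""))
            spans_raw.append((start, start + len(toks), INTERVAL, mention))
        else:
            token_rows.append((node_id, form, ""))

    position = {owner: i + 1 for i, (owner, _, _) in enumerate(token_rows) if not owner.endswith("+")}
    head_of = {n[0]: n[2] for n in template}
    deprel_of = {n[0]: n[3] for n in template}
    tokens: list[Token] = []
    for i, (owner, text, extra_deprel) in enumerate(token_rows):
        index = i + 1
        if owner.endswith("+"):
            tokens.append(Token(index, text, position[owner[:-1]], extra_deprel))
        else:
            head_id = head_of[owner]
            head = position[head_id] if head_id else 0
            tokens.append(Token(index, text, head, deprel_of[owner]))
    sentence = Sentence(doc_id, sent_index, tokens)

    spans: list[Span] = []
    for start, end, etype, mention in spans_raw:
        if etype == TAXON:
            assert isinstance(mention, TaxonMention)
            normalized = None if mention.abbreviated else (
                f"{mention.genus} {mention.species}" if mention.species else mention.genus
            )
            spans.append(Span(
                doc_id, sent_index, start, end, TAXON,
                " ".join(t.text for t in tokens[start - 1 : end - 1]),
                normalized,
                abbreviated=mention.abbreviated,
                uncertain=mention.uncertain,
            ))
        else:
            assert isinstance(mention, IntervalMention)
            spans.append(Span(
                doc_id, sent_index, start, end, INTERVAL,
                mention.surface, mention.surface,
            ))
    return sentence, spans


# ---------------------------------------------------------------------------
# Corpus generation


@dataclass(frozen=True)
class PlantedCandidate:
    doc_id: str
    sent_index: int
    taxon_start: int
    taxon_end: int
    interval_start: int
    interval_end: int
    gold: str
    genus: str                    # true genus, even when abbreviated in text
    species: str | None
    interval_surface: str
    abbreviated: bool

    @property
    def key(self) -> tuple:
        return (
            self.doc_id, self.sent_index,
            self.taxon_start, self.taxon_end,
            self.interval_start, self.interval_end,
        )


@dataclass
class CorpusBundle:
    documents: list[Document]
    planted_spans: list[Span]
    planted_candidates: list[PlantedCandidate]
    #: latent true stratigraphic range per genus, (fad_ma, lad_ma)
    true_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    gold: dict[tuple, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gold:
            self.gold = {pc.key: pc.gold for pc in self.planted_candidates}

    def gold_for(self, candidate: Candidate) -> str | None:
        key = (
            candidate.taxon.doc_id, candidate.taxon.sent_index,
            candidate.taxon.start, candidate.taxon.end,
            candidate.interval.start, candidate.interval.end,
        )
        return self.gold.get(key)

    def attach_gold(self, candidates: Iterable[Candidate]) -> list[Candidate]:
        """Set .gold on pipeline candidates that match a planted pair."""
        out = []
        for c in candidates:
            c.gold = self.gold_for(c)
            out.append(c)
        return out


def _pick_binomial(rng: np.random.Generator, manifest: GazetteerManifest) -> tuple[str, str]:
    binomial = manifest.binomials[int(rng.integers(len(manifest.binomials)))]
    genus, epithet = binomial.split(" ")
    return genus, epithet


def _latent_ranges(
    rng: np.random.Generator, manifest: GazetteerManifest
) -> dict[str, tuple[float, float]]:
    """True stratigraphic range per genus: origination uniform over the axis,
    duration roughly exponential (mean 15 Myr), extant genera reaching 0."""
    ranges: dict[str, tuple[float, float]] = {}
    extant = set(manifest.extant_genera)
    for genus in manifest.genera:
        fad = float(rng.uniform(10.0, 160.0))
        duration = float(np.clip(rng.exponential(15.0), 2.0, fad))
        lad = 0.0 if genus in extant else fad - duration
        ranges[genus] = (fad, lad)
    return ranges


def make_corpus(spec: SynthSpec, gazetteers: GazetteerBundle) -> CorpusBundle:
    """Templated documents with exact planted spans, candidates and labels.

    Each genus carries a latent true stratigraphic range; positive sentences
    draw their interval from the stages overlapping that range, while
    negative sentences draw any interval (they assert nothing about
    occurrence). Abbreviated taxon mentions are only emitted when the same
    genus was mentioned in full within the previous 15 sentences of the
    document, so every planted abbreviation is resolvable in principle.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    manifest = gazetteers.manifest
    pos_templates = POSITIVE_TEMPLATES[: spec.n_positive_templates]
    neg_templates = NEGATIVE_TEMPLATES[: spec.n_negative_templates]
    stages = manifest.intervals[: spec.n_intervals]
    stage_names = [iv.name for iv in manifest.intervals]
    true_ranges = _latent_ranges(rng, manifest)

    def overlapping_stages(genus: str) -> list[str]:
        fad, lad = true_ranges[genus]
        names = [s.name for s in stages if min(s.max_ma, fad) - max(s.min_ma, lad) > 0]
        return names or stage_names

    documents: list[Document] = []
    planted_spans: list[Span] = []
    planted_candidates: list[PlantedCandidate] = []

    for d in range(spec.n_docs):
        doc_id = f"doc{d:03d}"
        sentences: list[Sentence] = []
        full_mentions: list[tuple[int, str]] = []  # (sent_index, genus)

        for s in range(spec.sentences_per_doc):
            if rng.random() < _MENTION_SENTENCE_RATE:
                genus, epithet = _pick_binomial(rng, manifest)
                mention = TaxonMention(genus, epithet, abbreviated=False, uncertain=False)
                sentence, spans = _instantiate(MENTION_TEMPLATE, doc_id, s, mention, {})
                sentences.append(sentence)
                planted_spans.extend(spans)
                full_mentions.append((s, genus))
                continue

            positive = rng.random() < spec.p_positive
            templates = pos_templates if positive else neg_templates
            template = templates[int(rng.integers(len(templates)))]
            genus, epithet = _pick_binomial(rng, manifest)
            genus_only = rng.random() < _GENUS_ONLY_RATE
            recent = {g for t, g in full_mentions if t >= s - 15}
            abbreviated = (
                not genus_only
                and rng.random() < spec.abbrev_rate
                and genus in recent
            )
            uncertain = not genus_only and rng.random() < _UNCERTAIN_RATE
            mention = TaxonMention(
                genus,
                None if genus_only else epithet,
                abbreviated=abbreviated,
                uncertain=uncertain,
            )
            slots = [n[0] for n in template if n[1].startswith("<INTERVAL")]
            pool = overlapping_stages(genus) if positive else stage_names
            intervals_by_slot: dict[str, IntervalMention] = {}
            for slot in slots:
                name = pool[int(rng.integers(len(pool)))]
                modifier = (
                    _MODIFIER_CHOICES[int(rng.integers(len(_MODIFIER_CHOICES)))]
                    if rng.random() < _MODIFIER_RATE
                    else None
                )
                intervals_by_slot[slot] = IntervalMention(name, modifier)
            sentence, spans = _instantiate(template, doc_id, s, mention, intervals_by_slot)
            sentences.append(sentence)
            planted_spans.extend(spans)
            if not abbreviated:
                full_mentions.append((s, genus))
            taxon_span = next(sp for sp in spans if sp.entity_type == TAXON)
            for interval_span in (sp for sp in spans if sp.entity_type == INTERVAL):
                planted_candidates.append(
                    PlantedCandidate(
                        doc_id=doc_id,
                        sent_index=s,
                        taxon_start=taxon_span.start,
                        taxon_end=taxon_span.end,
                        interval_start=interval_span.start,
                        interval_end=interval_span.end,
                        gold=POS if positive else NEG,
                        genus=genus,
                        species=mention.species,
                        interval_surface=interval_span.surface,
                        abbreviated=abbreviated,
                    )
                )
        documents.append(
            Document(doc_id=doc_id, sentences=sentences, source_ref=f"Synthetic corpus {doc_id}")
        )
    return CorpusBundle(documents, planted_spans, planted_candidates, true_ranges)


# ---------------------------------------------------------------------------
# Annotator simulation


def simulate_annotators(
    gold: dict[str, str], error_rate: float, seed: int
) -> tuple[list[Annotation], list[Annotation]]:
    """Two annotators who each independently flip every gold label with
    probability ``error_rate``."""
    if not 0.0 <= error_rate <= 1.0:
        raise TaxomineError(f"error_rate must be in [0, 1], got {error_rate}")
    rng = np.random.default_rng(seed)
    out: tuple[list[Annotation], list[Annotation]] = ([], [])
    for annotator, annotations in zip(("A", "B"), out):
        for cid in sorted(gold):
            label = gold[cid]
            if rng.random() < error_rate:
                label = NEG if label == POS else POS
            annotations.append(Annotation(cid, annotator, label))
    return out


# ---------------------------------------------------------------------------
# OCR-like corruption

_CONFUSABLE = {
    "o": "0", "l": "1", "e": "c", "a": "u", "i": "l", "n": "m",
    "t": "f", "s": "z", "r": "n", "O": "0", "S": "5", "B": "8",
}


@dataclass(frozen=True)
class CorruptionRecord:
    sent_index: int
    token_index: int      # index in the ORIGINAL sentence
    operation: str        # substitute / split / drop


def _substitute(text: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(text)))
    replacement = _CONFUSABLE.get(text[pos], "x")
    return text[:pos] + replacement + text[pos + 1 :]


def perturb_ocr(
    document: Document, rate: float, seed: int
) -> tuple[Document, list[CorruptionRecord]]:
    """Corrupt tokens like a noisy OCR layer.

    Per token, with probability ``rate``, one of: substitute a confusable
    character; split the token in half (the tail becomes a ``goeswith``
    dependent of the head half); or drop it (children re-anchor to the
    dropped token's head; a dropped root promotes its leftmost child). Drops
    that cannot apply (single-token sentence) and splits of one-character
    tokens fall back to substitution.
    """
    if not 0.0 <= rate <= 1.0:
        raise TaxomineError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    new_sentences: list[Sentence] = []
    records: list[CorruptionRecord] = []
    for sentence in document.sentences:
        nodes = [
            {"text": t.text, "deprel": t.deprel, "pos": t.pos, "orig": t.index}
            for t in sentence.tokens
        ]
        by_orig = {n["orig"]: n for n in nodes}
        for n, t in zip(nodes, sentence.tokens):
            n["head"] = by_orig[t.head] if t.head else None
        for t in sentence.tokens:
            if rng.random() >= rate:
                continue
            op = ("substitute", "split", "drop")[int(rng.integers(3))]
            node = by_orig[t.index]
            if op == "split" and len(node["text"]) < 2:
                op = "substitute"
            if op == "drop" and len(nodes) < 2:
                op = "substitute"
            if op == "substitute":
                node["text"] = _substitute(node["text"], rng)
            elif op == "split":
                cut = len(node["text"]) // 2
                tail = {
                    "text": node["text"][cut:], "deprel": "goeswith",
                    "pos": None, "orig": None, "head": node,
                }
                node["text"] = node["text"][:cut]
                nodes.insert(nodes.index(node) + 1, tail)
            else:  # drop
                children = [n for n in nodes if n.get("head") is node]
                if node["head"] is None:  # root: promote leftmost child
                    if not children:
                        node["text"] = _substitute(node["text"], rng)
                        records.append(CorruptionRecord(sentence.sent_index, t.index, "substitute"))
                        continue
                    promoted = children[0]
                    promoted["head"] = None
                    promoted["deprel"] = "root"
                    for child in children[1:]:
                        child["head"] = promoted
                    for n in nodes:
                        if n.get("head") is node:
                            n["head"] = promoted
                else:
                    for child in children:
                        child["head"] = node["head"]
                nodes.remove(node)
            records.append(CorruptionRecord(sentence.sent_index, t.index, op))
        index_of = {id(n): i + 1 for i, n in enumerate(nodes)}
        tokens = [
            Token(
                i + 1,
                n["text"],
                index_of[id(n["head"])] if n["head"] is not None else 0,
                n["deprel"],
                n["pos"],
            )
            for i, n in enumerate(nodes)
        ]
        new_sentences.append(
            Sentence(sentence.doc_id, sentence.sent_index, tokens, comments=dict(sentence.comments))
        )
    return (
        Document(doc_id=document.doc_id, sentences=new_sentences, source_ref=document.source_ref),
        records,
    )
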