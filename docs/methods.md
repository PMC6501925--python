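# Methods

This note documents the models, conventions and design decisions behind
`taxomine`, in the order data flows through the pipeline. Everything stated
here is implemented and exercised by the test suite; no empirical claim is
made beyond what the tests and `scripts/acceptance.py` themselves compute.

## Scope and assumptions

The pipeline extracts taxon–age occurrence assertions from *single,
grammatically parsed sentences*. It deliberately ignores tables, figures,
lists, typographic layout and cross-sentence context (coreference,
taxonomic-treatment headlines). Documents enter as CoNLL-U dependency
parses; parsing itself is external. A live parser can be registered as a
hook (`corpus.register_parser`), but no parser is bundled and nothing
downstream depends on which parser produced a tree — this keeps the test
suite download-free and the pipeline parser-agnostic.

Ages are megaannums before present (Ma) throughout: larger numbers are
older. Token span positions are half-open `[start, end)` over 1-based token
indices.

## Gazetteers

*Taxon gazetteer*: canonical genera, binomials, and a genus synonym map.
Synonym chains may pass through other synonyms but must terminate in an
accepted genus; cycles are a load-time error (accepted-name maps are
acyclic by definition). `standardize_genus` applies the chain transitively
and is idempotent; unknown names are returned unchanged with a flag rather
than failing, so downstream code can count them.

*Interval gazetteer*: case-insensitive name → (max_ma, min_ma) lookup with
the modifier prefixes early/middle/late/lower/upper. A modified query
("lower Miocene") first tries a literal row; only if none exists is the
modifier stripped and the full interval returned, flagged as a fallback.
The inclusive fallback is deliberate: it can only widen an interval, which
is conservative for range-through counts (a genus is never pushed *out* of
a bin by the fallback).

## Entity recognition and candidates

Span matching is longest-match, leftmost-first over gazetteer hits. At an
equal start the longer match wins; at equal length a taxon binomial beats
a bare genus beats an interval. Open-nomenclature qualifiers ("cf.",
"aff.") between genus and epithet are absorbed into the span and flagged
`uncertain`. An abbreviated mention is a single capital letter plus period
followed by an epithet-shaped token; it is recognized structurally (no
gazetteer hit is possible yet) and flagged `abbreviated`.

Every (taxon span × interval span) pair within one sentence becomes one
candidate; the per-sentence candidate count is exactly the product of the
span counts. Candidates are independent records — no cross-sentence
pairing.

*De-abbreviation*: an abbreviated genus resolves to the nearest preceding
full genus mention with the same initial letter, looking back 15 sentences
(sentence records are counted; mentions earlier in the same sentence also
qualify). "Nearest preceding wins" is the tie-break when several genera
share the initial. When the gazetteer knows binomials for the resolved
genus and the abbreviated epithet matches none of them, the resolution is
kept but flagged `epithet_mismatch` — this limits silently wrong
resolutions without discarding data. Unresolvable abbreviations keep the
sentinel genus `UNRESOLVED` and are dropped only at the occurrence stage,
where the drop is logged.

*Deduplication* collapses candidates identical in (document, normalized
genus+species, normalized interval, sentence text), keeping the first;
the operation is idempotent and order-stable.

## Shortest dependency paths

The path between two spans runs between their *anchors* — the span token
whose head lies outside the span (leftmost on ties). Head links are
traversed as undirected edges by breadth-first search; each step records
the token, the dependency label of the traversed edge, and the direction
(UP child→head, DOWN head→child). A disconnected parse raises a distinct
path-failure signal; callers skip the candidate and log it rather than
crash. On trees the BFS path is unique, and its length equals the BFS
distance plus one (property-tested against an independent graph-library
oracle).

## Relation classifier

Architecture: token embedding ⊕ learned label embedding per path step →
bidirectional LSTM over the step sequence → ReLU hidden layer (optional
inverted dropout) → 2-way softmax. One shared encoder reads the whole
anchor-to-anchor path; a two-branch encoder joined at the common ancestor
was considered and rejected as needless complexity at these path lengths.
Dependency labels enter the input encoding because the label sequence is
exactly what distinguishes, say, an `obl` attachment to an occurrence verb
from an `amod` inside a family-authority phrase.

Defaults (`ClassifierConfig`): token embedding 24, label embedding 8,
24 LSTM units per direction, 32 hidden units, dropout 0.1, Adam at
learning rate 0.005, batch 32, at most 60 epochs with early stopping after
6 epochs without validation-loss improvement (best-validation weights
restored), paths truncated to 12 steps keeping both endpoints (endpoints
carry the entities; middle tokens are trimmed), vocabulary minimum count 2
with PAD/OOV symbols, frequency-then-lexicographic index order. These were
hand-tuned on the synthetic corpus; every one is config-exposed.

Numerical choices: all arithmetic is float64 numpy; parameter
initialization (uniform embeddings, Glorot matrices, forget-gate bias 1),
minibatch order and dropout masks all draw from one seeded generator, so a
fixed seed reproduces training bit-for-bit. Cross-entropy loss; a
non-finite loss aborts with diagnostics rather than silently continuing.
Single-class training data is an error.

Evaluation: accuracy, precision, recall, FPR and F1 from the confusion
counts; ratios with zero denominators are reported as undefined (None),
never as 0. Ties at the decision boundary (prob == b) classify positive —
an arbitrary convention, fixed and stated. The ROC curve sweeps the unique
scores (trapezoid AUC; equal to the tie-aware pairwise concordance
statistic, which the tests verify). `select_boundary` returns the smallest
boundary whose empirical FPR is at or below the target, which maximizes
recall subject to the FPR constraint because both rates are non-increasing
in the boundary.

Splitting is by document: documents are shuffled by seed and greedily
assigned to train/validation/test (targets 80/10/10 of candidates), each
document to the split with the largest remaining deficit. Realized
fractions therefore deviate from the targets by at most one document's
weight. Repeated fitting (`repeat_fit`, default 100 repeats) reruns
training with seeds `seed+i` and reports per-metric mean ± sample s.d. on
the test split.

## Richness

Occurrence filtering keeps scored candidates with prob ≥ b, resolves
interval ages, standardizes genera, and drops (with per-reason logs)
candidates lacking a probability, below the boundary, with unresolved
genus, or with an interval unknown to the gazetteer.

FAD = maximum occurrence `max_ma`, LAD = minimum occurrence `min_ma` —
inclusive interval bounds, not midpoints, matching the "through"
semantics of range-through counting and keeping the result deterministic.
Genera on the extant register get LAD = 0; extant genera with no
text-mined occurrences are carried as fad = lad = 0 records.

Bins are caller-supplied edges, strictly decreasing in Ma, half-open
`[older, younger)`. A genus is counted in a bin when its closed
[LAD, FAD] range overlaps the bin with *nonzero measure*: touching at a
single shared edge does not count, so nothing double-counts at bin
boundaries. A consequence is that zero-length ranges (extant-only genera)
fall in no bin. Range-through counts per bin are never below counts from
the sampled occurrences alone, and raising the decision boundary can only
lower them (both property-tested). `span_outliers` reports the fraction of
genera whose FAD−LAD span is strictly under a threshold (default 25 Myr)
and lists the longest-ranged genera as plausibility flags.

## Synthetic data generator

The generator emulates the *structure* of the task, not the texture of
real literature: Latin-like non-colliding taxon names and synonym chains;
geologic stages partitioning 160–0 Ma plus nested coarser intervals;
templated sentences whose dependency trees are authored by hand (7
positive and 7 negative templates, including the hard negative where the
interval modifies a family-authority phrase and a two-interval "ranges
from X to Y" positive); abbreviated mentions only where a full same-genus
mention occurred within the 15-sentence window; two annotators who flip
each gold label independently at a configurable rate; and an OCR model
that substitutes confusable characters, splits tokens (`goeswith` tail) or
drops them (children re-anchor to the dropped token's head; a dropped root
promotes its leftmost child).

Each genus carries a latent true range — origination uniform on the time
axis, duration roughly exponential with mean 15 Myr, extant genera
reaching the present — and positive sentences draw their interval from
stages overlapping that range, so richness output has realistic shape.
Negative sentences draw any interval, as they assert nothing.

Default study conditions: 50 documents × 45 sentences (≈ 2000 candidate
pairs), positive fraction 0.5, abbreviation rate 0.25, annotator error
rate 0.087 (chosen so the expected two-annotator agreement
(1−e)² + e² ≈ 0.84 matches observed human repeatability on this kind of
labelling), OCR rate 0.02. All outputs are deterministic functions of the
spec, including its seed.

What passing tests therefore show — and what they do not: the positive and
negative templates use disjoint connective vocabulary, so the classes are
separable from path tokens and a correct implementation should reach
near-perfect held-out scores; high synthetic accuracy validates the
machinery (paths, encoding, training, evaluation), not performance on real
literature, where class overlap, parser errors and annotation ambiguity
dominate. Conversely, annotator noise propagates into resolved training
labels, which is why pipeline-level metrics in `scripts/acceptance.py`
(evaluated against noisy resolved labels) sit visibly below the clean
template-recovery ceiling.

## Problem sizes

Tests train on the default ≈ 2000-candidate corpus (one shared fit per
session plus one same-seed refit for the reproducibility check, a few
seconds each); oracle comparisons use 300 random trees / score sets and 50
random range sets or corpora; the acceptance script runs 5 repeated fits
rather than the default 100 — chosen as comfortable sizes for a laptop
run, and stated here so they can be scaled up freely.

## Known limitations

- Homonym genera (the same name validly used in different higher taxa)
  cannot be disambiguated without authority names, which are not parsed.
- The de-abbreviation window counts sentence records; paragraph breaks are
  invisible to it.
- Modified interval names resolve to the full interval unless the
  gazetteer defines the sub-interval row; the fallback is flagged but the
  bounds are wider than a stage-resolved lookup would give.
- Species-level synonymy is out of scope; occurrences aggregate to genus.
- The OCR corruption model is a caricature (three operation types, one
  confusion table); it supports degradation experiments, not OCR research.
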