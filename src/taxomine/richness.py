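"""From positive predictions to range-through genus richness curves.

Scored candidates at or above the decision boundary become occurrence
records (genus, interval age bounds, provenance). Per genus, the oldest
occurrence bound is its first appearance datum (FAD) and the youngest its
last appearance datum (LAD); genera in a present-day register get LAD = 0
(extant supplementation). Range-through binning counts a genus in every
time bin its closed [LAD, FAD] range overlaps with nonzero measure:
presence is implied everywhere between the endpoints, regardless of
sampled gaps.

Ages are Ma before present (larger = older). Bins are half-open
[older, younger) and supplied by the caller, oldest first.
"""

from __future__ import annotations

import csv
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from taxomine.candidates import UNRESOLVED, Candidate
from taxomine.errors import IntervalLookupError, TaxomineError
from taxomine.gazetteer import (
    IntervalGazetteer,
    TaxonGazetteer,
    resolve_interval,
    standardize_genus,
)


@dataclass(frozen=True)
class Occurrence:
    """One positive taxon-interval extraction with resolved ages."""

    genus: str
    species: str | None
    interval: str
    max_ma: float
    min_ma: float
    doc_id: str
    candidate_id: str
    prob: float

    def __post_init__(self) -> None:
        if self.genus == UNRESOLVED:
            raise TaxomineError("occurrences must carry a resolved genus")
        if not self.max_ma > self.min_ma >= 0:
            raise TaxomineError(
                f"{self.genus}: need max_ma > min_ma >= 0, got ({self.max_ma}, {self.min_ma})"
            )


@dataclass(frozen=True)
class GenusRange:
    """FAD/LAD summary per genus; extant genera have lad_ma = 0."""

    genus: str
    fad_ma: float
    lad_ma: float
    n_occurrences: int
    extant: bool = False

    def __post_init__(self) -> None:
        if self.fad_ma < self.lad_ma:
            raise TaxomineError(f"{self.genus}: FAD {self.fad_ma} older-check failed vs LAD {self.lad_ma}")
        if self.n_occurrences < 1 and not self.extant:
            raise TaxomineError(f"{self.genus}: no occurrences and not extant")

    @property
    def span_myr(self) -> float:
        return self.fad_ma - self.lad_ma


@dataclass(frozen=True)
class RichnessCurve:
    """Contiguous half-open bins [older, younger) with genus counts."""

    bins: tuple[tuple[float, float], ...]
    counts: tuple[int, ...]


class OccurrenceFilterResult(NamedTuple):
    occurrences: list[Occurrence]
    dropped: dict[str, int]     # reason -> count


def candidates_to_occurrences(
    candidates: Sequence[Candidate],
    b: float,
    interval_gaz: IntervalGazetteer,
    taxon_gaz: TaxonGazetteer,
) -> OccurrenceFilterResult:
    """Keep candidates with prob >= b, resolve ages, standardize genera.

    Candidates without a probability (failed dependency path), below the
    boundary, with an unresolved abbreviated genus or an interval unknown to
    the gazetteer are dropped; drops are tallied per reason, never fatal.
    """
    kept: list[Occurrence] = []
    dropped: Counter[str] = Counter()
    for c in candidates:
        if c.prob is None:
            dropped["no_probability"] += 1
            continue
        if c.prob < b:
            dropped["below_boundary"] += 1
            continue
        if c.genus == UNRESOLVED:
            dropped["unresolved_genus"] += 1
            continue
        try:
            resolution = resolve_interval(c.interval.normalized or c.interval.surface, interval_gaz)
        except (IntervalLookupError, TaxomineError):
            dropped["unknown_interval"] += 1
            continue
        genus = standardize_genus(c.genus, taxon_gaz).genus
        kept.append(
            Occurrence(
                genus=genus,
                species=c.species,
                interval=resolution.interval.name,
                max_ma=resolution.interval.max_ma,
                min_ma=resolution.interval.min_ma,
                doc_id=c.taxon.doc_id,
                candidate_id=c.candidate_id,
                prob=c.prob,
            )
        )
    return OccurrenceFilterResult(kept, dict(dropped))


def genus_ranges(
    occurrences: Sequence[Occurrence], extant_genera: Iterable[str] = ()
) -> list[GenusRange]:
    """FAD = oldest occurrence bound, LAD = youngest, per genus.

    Genera in ``extant_genera`` get LAD overridden to 0; extant genera with
    no text-mined occurrences still appear as fad = lad = 0 records so the
    youngest bins reflect the living fauna.
    """
    extant = set(extant_genera)
    grouped: dict[str, list[Occurrence]] = defaultdict(list)
    for occ in occurrences:
        grouped[occ.genus].append(occ)
    out: list[GenusRange] = []
    for genus in sorted(set(grouped) | extant):
        occs = grouped.get(genus, [])
        is_extant = genus in extant
        if occs:
            fad = max(o.max_ma for o in occs)
            lad = 0.0 if is_extant else min(o.min_ma for o in occs)
        else:
            fad = lad = 0.0
        out.append(
            GenusRange(
                genus=genus,
                fad_ma=fad,
                lad_ma=lad,
                n_occurrences=len(occs),
                extant=is_extant,
            )
        )
    return out


def range_through_richness(
    ranges: Sequence[GenusRange], bin_edges: Sequence[float]
) -> RichnessCurve:
    """Count genera per bin, range-through.

    ``bin_edges`` must be strictly decreasing in Ma (oldest first); bin i is
    [edges[i], edges[i+1]). A genus is counted in every bin its closed
    [lad, fad] range overlaps with nonzero measure — touching an edge at a
    single point does not count, so a genus never double-counts at shared
    edges.
    """
    edges = list(bin_edges)
    if len(edges) < 2:
        raise TaxomineError("need at least two bin edges")
    if any(a <= b for a, b in zip(edges, edges[1:])):
        raise TaxomineError("bin edges must be strictly decreasing in Ma")
    bins = [(older, younger) for older, younger in zip(edges, edges[1:])]
    counts = []
    for older, younger in bins:
        n = sum(
            1
            for r in ranges
            if min(r.fad_ma, older) - max(r.lad_ma, younger) > 0
        )
        counts.append(n)
    return RichnessCurve(bins=tuple(bins), counts=tuple(counts))


class OutlierReport(NamedTuple):
    fraction_under_threshold: float | None
    flagged: list[GenusRange]       # spans >= threshold, longest first


def span_outliers(
    ranges: Sequence[GenusRange], threshold_myr: float = 25.0
) -> OutlierReport:
    """Fraction of genera with a range span strictly under ``threshold_myr``
    and the suspiciously long-ranged genera, longest span first."""
    if not ranges:
        return OutlierReport(None, [])
    under = sum(1 for r in ranges if r.span_myr < threshold_myr)
    flagged = sorted(
        (r for r in ranges if r.span_myr >= threshold_myr),
        key=lambda r: (-r.span_myr, r.genus),
    )
    return OutlierReport(under / len(ranges), flagged)


# ---------------------------------------------------------------------------
# Tabular I/O


def write_occurrences_csv(occurrences: Sequence[Occurrence], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["genus", "species", "interval", "max_ma", "min_ma", "doc_id", "candidate_id", "prob"]
        )
        for o in occurrences:
            writer.writerow(
                [o.genus, o.species or "", o.interval, o.max_ma, o.min_ma,
                 o.doc_id, o.candidate_id, f"{o.prob:.6f}"]
            )


def write_richness_tsv(curve: RichnessCurve, path: str | Path) -> None:
    rows = ["bin_older\tbin_younger\tcount"]
    for (older, younger), count in zip(curve.bins, curve.counts):
        rows.append(f"{older:g}\t{younger:g}\t{count}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_bin_edges_tsv(path: str | Path) -> list[float]:
    """Bin edges from a one-column TSV (header ``edge_ma``), oldest first."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != "edge_ma":
        raise TaxomineError(f"{path}: expected single-column TSV with header 'edge_ma'")
    return [float(line) for line in lines[1:] if line.strip()]
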