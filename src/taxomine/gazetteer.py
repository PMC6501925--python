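"""Reference lists of taxon names and geologic time intervals.

Two gazetteers drive the rule-based entity recognition: a taxon gazetteer
(canonical genera, Linnaean binomials and a genus synonym map used for
nomenclatural standardization) and an interval gazetteer mapping geologic
time-interval names to their older/younger age bounds in Ma before present
(larger = older, everywhere in this package).

TSV dialects (UTF-8, tab-separated, header row required):

* taxon:    ``name  rank  accepted_name`` with rank ``genus`` or ``species``
* interval: ``name  max_ma  min_ma``
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from taxomine.errors import GazetteerError, IntervalLookupError

_GENUS_RE = re.compile(r"^[A-Z][a-z]+$")

#: Interval-name prefix tokens recognized as modifiers ("lower Miocene").
MODIFIERS = frozenset({"early", "middle", "late", "lower", "upper"})


@dataclass(frozen=True)
class GeoInterval:
    """A named geologic time interval with bounds in Ma before present."""

    name: str
    max_ma: float
    min_ma: float

    def __post_init__(self) -> None:
        if not self.min_ma >= 0:
            raise GazetteerError(f"{self.name}: min_ma must be >= 0, got {self.min_ma}")
        if not self.max_ma > self.min_ma:
            raise GazetteerError(
                f"{self.name}: max_ma ({self.max_ma}) must exceed min_ma ({self.min_ma})"
            )


class IntervalResolution(NamedTuple):
    """Result of an interval lookup.

    ``fallback`` is True when the queried name carried a modifier prefix
    that had to be stripped because the gazetteer defines no sub-interval
    row, so the full interval's bounds are returned (conservative for
    range-through counts).
    """

    interval: GeoInterval
    fallback: bool


class GenusResolution(NamedTuple):
    """Result of genus standardization; ``known`` is False for names
    absent from the gazetteer (returned unchanged, flagged not failed)."""

    genus: str
    known: bool


@dataclass
class TaxonGazetteer:
    """Canonical genera, binomials and an acyclic genus synonym map."""

    genera: set[str] = field(default_factory=set)
    binomials: set[str] = field(default_factory=set)
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.genera:
            if not _GENUS_RE.match(name):
                raise GazetteerError(f"genus {name!r} is not capitalized-Latin shaped")
        for binomial in self.binomials:
            parts = binomial.split(" ")
            if len(parts) != 2 or parts[0] not in self.genera:
                raise GazetteerError(f"binomial {binomial!r} has no known genus part")
        self._check_chains()

    def _check_chains(self) -> None:
        # chains may pass through other synonyms but must terminate in an
        # accepted genus without revisiting a name
        for start in self.synonyms:
            seen = {start}
            node = start
            while node in self.synonyms:
                node = self.synonyms[node]
                if node in seen:
                    raise GazetteerError(f"synonym cycle involving {start!r}")
                seen.add(node)
            if node not in self.genera:
                raise GazetteerError(
                    f"synonym chain from {start!r} ends at unknown genus {node!r}"
                )

    def epithets_of(self, genus: str) -> set[str]:
        """Known species epithets for ``genus`` (empty if none recorded)."""
        prefix = genus + " "
        return {b[len(prefix):] for b in self.binomials if b.startswith(prefix)}


@dataclass
class IntervalGazetteer:
    """Case-insensitive name -> GeoInterval lookup with modifier stripping."""

    intervals: dict[str, GeoInterval] = field(default_factory=dict)
    modifiers: frozenset[str] = MODIFIERS

    def __post_init__(self) -> None:
        lowered: dict[str, GeoInterval] = {}
        for name, interval in self.intervals.items():
            key = name.lower()
            if key in lowered:
                raise GazetteerError(f"duplicate interval name {name!r}")
            if key in self.modifiers:
                raise GazetteerError(f"modifier {name!r} cannot be an interval name")
            lowered[key] = interval
        self._by_lower = lowered

    def get(self, name: str) -> GeoInterval | None:
        return self._by_lower.get(name.lower())

    @property
    def max_name_tokens(self) -> int:
        return max((len(n.split()) for n in self._by_lower), default=1)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._by_lower

    def __len__(self) -> int:
        return len(self.intervals)


def load_taxon_gazetteer(path: str | Path) -> TaxonGazetteer:
    """Load a taxon gazetteer from TSV with columns (name, rank, accepted_name).

    Rows with ``rank=genus`` whose accepted_name differs from name populate
    the synonym map; ``rank=species`` rows carry full binomials. Conflicting
    duplicate synonym rows are an error naming the offending line.
    """
    genera: set[str] = set()
    binomials: set[str] = set()
    synonyms: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        return TaxonGazetteer()
    header = lines[0].split("\t")
    if header[:3] != ["name", "rank", "accepted_name"]:
        raise GazetteerError(f"{path}: expected header name/rank/accepted_name, got {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GazetteerError(f"{path}:{lineno}: expected 3 tab-separated fields")
        name, rank, accepted = (p.strip() for p in parts)
        if rank == "genus":
            genera.add(accepted)
            if name != accepted:
                if name in synonyms and synonyms[name] != accepted:
                    raise GazetteerError(
                        f"{path}:{lineno}: conflicting synonym for {name!r}: "
                        f"{synonyms[name]!r} vs {accepted!r}"
                    )
                synonyms[name] = accepted
            else:
                genera.add(name)
        elif rank == "species":
            if len(name.split(" ")) != 2:
                raise GazetteerError(f"{path}:{lineno}: binomial {name!r} must be two words")
            binomials.add(name)
            genera.add(name.split(" ")[0])
        else:
            raise GazetteerError(f"{path}:{lineno}: unknown rank {rank!r}")
    return TaxonGazetteer(genera=genera, binomials=binomials, synonyms=synonyms)


def save_taxon_gazetteer(gaz: TaxonGazetteer, path: str | Path) -> None:
    """Write the canonical TSV form (sorted rows; load/save round-trips)."""
    rows = ["name\trank\taccepted_name"]
    plain = gaz.genera - set(gaz.synonyms)
    for genus in sorted(plain):
        rows.append(f"{genus}\tgenus\t{genus}")
    for raw in sorted(gaz.synonyms):
        rows.append(f"{raw}\tgenus\t{gaz.synonyms[raw]}")
    for binomial in sorted(gaz.binomials):
        rows.append(f"{binomial}\tspecies\t{binomial}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def load_interval_gazetteer(path: str | Path) -> IntervalGazetteer:
    """Load an interval gazetteer from TSV with columns (name, max_ma, min_ma)."""
    intervals: dict[str, GeoInterval] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        return IntervalGazetteer()
    header = lines[0].split("\t")
    if header[:3] != ["name", "max_ma", "min_ma"]:
        raise GazetteerError(f"{path}: expected header name/max_ma/min_ma, got {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GazetteerError(f"{path}:{lineno}: expected 3 tab-separated fields")
        name = parts[0].strip()
        try:
            max_ma, min_ma = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise GazetteerError(f"{path}:{lineno}: non-numeric age bound") from exc
        if name in intervals:
            raise GazetteerError(f"{path}:{lineno}: duplicate interval {name!r}")
        intervals[name] = GeoInterval(name, max_ma, min_ma)
    return IntervalGazetteer(intervals=intervals)


def save_interval_gazetteer(gaz: IntervalGazetteer, path: str | Path) -> None:
    """Write the canonical TSV form (sorted by older bound then name)."""
    rows = ["name\tmax_ma\tmin_ma"]
    for iv in sorted(gaz.intervals.values(), key=lambda i: (-i.max_ma, i.name)):
        rows.append(f"{iv.name}\t{iv.max_ma:g}\t{iv.min_ma:g}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def resolve_interval(name: str, gaz: IntervalGazetteer) -> IntervalResolution:
    """Resolve an interval name, possibly carrying a modifier prefix, to ages.

    A literal gazetteer row ("lower Miocene" as its own entry) wins; otherwise
    the modifier is stripped and the bare name looked up, flagged as a
    fallback. Unknown names raise :class:`IntervalLookupError`.
    """
    if not isinstance(name, str) or not name.strip():
        raise GazetteerError(f"malformed interval query: {name!r}")
    query = " ".join(name.split())
    hit = gaz.get(query)
    if hit is not None:
        return IntervalResolution(hit, fallback=False)
    parts = query.split(" ")
    if len(parts) > 1 and parts[0].lower() in gaz.modifiers:
        hit = gaz.get(" ".join(parts[1:]))
        if hit is not None:
            return IntervalResolution(hit, fallback=True)
    raise IntervalLookupError(query)


def standardize_genus(raw: str, gaz: TaxonGazetteer) -> GenusResolution:
    """Map a genus name through the synonym chain to its accepted name.

    The synonym map is applied transitively (it is acyclic by construction).
    A name that is neither accepted nor a synonym is returned unchanged
    with ``known=False``.
    """
    node = raw
    while node in gaz.synonyms:
        node = gaz.synonyms[node]
    if node in gaz.genera:
        return GenusResolution(node, known=True)
    return GenusResolution(raw, known=False)
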