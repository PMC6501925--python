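"""Human annotations, inter-annotator accuracy and disagreement resolution.

Gold labels are POS/NEG judgments of whether a sentence asserts that the
taxon occurred in the interval. Two annotators may label an overlapping
candidate set; agreement over the intersection measures annotation
repeatability, and disagreements are resolved by a seeded fair coin so the
resulting gold-label set is reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from taxomine.errors import TaxomineError

POS = "POS"
NEG = "NEG"
_LABELS = {POS, NEG}


@dataclass(frozen=True)
class Annotation:
    candidate_id: str
    annotator_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise TaxomineError(f"label must be POS or NEG, got {self.label!r}")


@dataclass
class GoldLabelSet:
    """Resolved candidate_id -> label map with per-candidate provenance.

    Provenance is one of ``single`` (one annotator), ``agreed`` (both agree)
    or ``random-resolved`` (seeded coin flip on disagreement).
    """

    labels: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"seed": self.seed, "labels": self.labels, "provenance": self.provenance},
                sort_keys=True,
                indent=1,
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GoldLabelSet":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(labels=d["labels"], provenance=d["provenance"], seed=d["seed"])


def _as_map(annotations: list[Annotation] | dict[str, str]) -> dict[str, str]:
    if isinstance(annotations, dict):
        return annotations
    out: dict[str, str] = {}
    for a in annotations:
        if a.candidate_id in out and out[a.candidate_id] != a.label:
            raise TaxomineError(
                f"annotator gave two labels for candidate {a.candidate_id}"
            )
        out[a.candidate_id] = a.label
    return out


def inter_annotator_accuracy(
    a: list[Annotation] | dict[str, str], b: list[Annotation] | dict[str, str]
) -> float:
    """Fraction of commonly annotated candidates on which both agree."""
    ma, mb = _as_map(a), _as_map(b)
    common = set(ma) & set(mb)
    if not common:
        raise TaxomineError("annotators share no candidates; accuracy undefined")
    agree = sum(1 for cid in common if ma[cid] == mb[cid])
    return agree / len(common)


def resolve_disagreements(
    a: list[Annotation] | dict[str, str],
    b: list[Annotation] | dict[str, str],
    seed: int,
) -> GoldLabelSet:
    """Merge two annotators into one gold-label set.

    Agreements are kept; disagreements get POS or NEG from a seeded fair
    coin; candidates seen by only one annotator keep that label with
    provenance ``single``. Deterministic given the seed.
    """
    ma, mb = _as_map(a), _as_map(b)
    rng = np.random.default_rng(seed)
    labels: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for cid in sorted(set(ma) | set(mb)):
        in_a, in_b = cid in ma, cid in mb
        if in_a and in_b:
            if ma[cid] == mb[cid]:
                labels[cid] = ma[cid]
                provenance[cid] = "agreed"
            else:
                labels[cid] = POS if rng.random() < 0.5 else NEG
                provenance[cid] = "random-resolved"
        else:
            labels[cid] = ma[cid] if in_a else mb[cid]
            provenance[cid] = "single"
    return GoldLabelSet(labels=labels, provenance=provenance, seed=seed)


def read_annotations_csv(path: str | Path) -> list[Annotation]:
    """Read (candidate_id, annotator_id, label) rows, header required."""
    out: list[Annotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"candidate_id", "annotator_id", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TaxomineError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            out.append(Annotation(row["candidate_id"], row["annotator_id"], row["label"]))
    return out


def write_annotations_csv(annotations: list[Annotation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["candidate_id", "annotator_id", "label"])
        for a in annotations:
            writer.writerow([a.candidate_id, a.annotator_id, a.label])
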