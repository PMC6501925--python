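"""Dependency-parsed documents and CoNLL-U interchange.

The pipeline is parser-agnostic: documents arrive as CoNLL-U files (one per
document), and a live parser is only ever an optional registered hook. Token
span positions elsewhere in the package are half-open ``[start, end)`` over
1-based token indices.

Document metadata travels in ``# doc_id =`` and ``# source_ref =`` comment
lines of the first sentence block; other comments are kept per sentence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from taxomine.errors import ConlluParseError, ParserHookError, ParserUnavailableError


@dataclass(frozen=True)
class Token:
    """One token of a dependency parse; ``head`` 0 marks the root."""

    index: int          # 1-based position within the sentence
    text: str
    head: int           # index of governing token, 0 = root
    deprel: str
    pos: str | None = None

    def __post_init__(self) -> None:
        if self.head == self.index:
            raise ConlluParseError(f"token {self.index} ({self.text!r}) is its own head")
        if self.head < 0:
            raise ConlluParseError(f"token {self.index}: negative head {self.head}")


@dataclass
class Sentence:
    doc_id: str
    sent_index: int     # 0-based position within the document
    tokens: list[Token]
    comments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.tokens)
        indices = [t.index for t in self.tokens]
        if indices != list(range(1, n + 1)):
            raise ConlluParseError(
                f"{self.doc_id} sentence {self.sent_index}: token indices not contiguous 1..{n}"
            )
        for t in self.tokens:
            if t.head > n:
                raise ConlluParseError(
                    f"{self.doc_id} sentence {self.sent_index}: head {t.head} out of range"
                )
        if n and not any(t.head == 0 for t in self.tokens):
            raise ConlluParseError(
                f"{self.doc_id} sentence {self.sent_index}: no root token"
            )
        self._check_rooted()

    def _check_rooted(self) -> None:
        # every token must reach a root by following head links (no cycles)
        n = len(self.tokens)
        heads = {t.index: t.head for t in self.tokens}
        for start in range(1, n + 1):
            node, hops = start, 0
            while node != 0:
                node = heads[node]
                hops += 1
                if hops > n:
                    raise ConlluParseError(
                        f"{self.doc_id} sentence {self.sent_index}: "
                        f"head cycle reachable from token {start}"
                    )

    def text(self) -> str:
        return " ".join(t.text for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Document:
    doc_id: str
    sentences: list[Sentence]
    source_ref: str = ""

    def __post_init__(self) -> None:
        got = [s.sent_index for s in self.sentences]
        if got != list(range(len(self.sentences))):
            raise ConlluParseError(f"{self.doc_id}: sent_index values not contiguous 0..m-1")


_RESERVED_COMMENTS = ("doc_id", "source_ref")


def read_conllu(path: str | Path) -> Document:
    """Read one document from a CoNLL-U file.

    Sentence blocks are blank-line separated; multiword-token range lines
    (``1-2``) and empty-node lines (``1.1``) are skipped; comment lines are
    preserved as sentence metadata. An empty file yields an empty Document
    whose doc_id falls back to the file stem.
    """
    path = Path(path)
    doc_id: str | None = None
    source_ref = ""
    sentences: list[Sentence] = []
    block_comments: dict[str, str] = {}
    block_rows: list[tuple[int, str, int, str, str | None]] = []

    def flush() -> None:
        nonlocal block_comments, block_rows
        if not block_rows and not block_comments:
            return
        sent_no = len(sentences)
        tokens = [Token(*row) for row in block_rows]
        try:
            sentences.append(
                Sentence(doc_id or path.stem, sent_no, tokens, comments=block_comments)
            )
        except ConlluParseError as exc:
            raise ConlluParseError(f"{path} sentence block {sent_no + 1}: {exc}") from exc
        block_comments, block_rows = {}, []

    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key, value = key.strip(), value.strip()
                if key == "doc_id":
                    doc_id = doc_id or value
                elif key == "source_ref":
                    source_ref = source_ref or value
                else:
                    block_comments[key] = value
            else:
                block_comments[body] = ""
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ConlluParseError(f"{path}:{lineno}: expected 10 columns, got {len(cols)}")
        if "-" in cols[0] or "." in cols[0]:
            continue  # multiword-token range or empty node
        try:
            index, head = int(cols[0]), int(cols[6])
        except ValueError as exc:
            raise ConlluParseError(f"{path}:{lineno}: non-integer ID or HEAD") from exc
        pos = None if cols[3] == "_" else cols[3]
        block_rows.append((index, cols[1], head, cols[7], pos))
    flush()
    return Document(doc_id=doc_id or path.stem, sentences=sentences, source_ref=source_ref)


def write_conllu(document: Document, path: str | Path) -> None:
    """Write a document in canonical 10-column CoNLL-U."""
    lines: list[str] = []
    for sentence in document.sentences:
        if sentence.sent_index == 0:
            lines.append(f"# doc_id = {document.doc_id}")
            if document.source_ref:
                lines.append(f"# source_ref = {document.source_ref}")
        for key, value in sentence.comments.items():
            if key in _RESERVED_COMMENTS:
                continue
            lines.append(f"# {key} = {value}" if value else f"# {key}")
        for t in sentence.tokens:
            pos = t.pos if t.pos is not None else "_"
            lines.append(
                f"{t.index}\t{t.text}\t_\t{pos}\t_\t_\t{t.head}\t{t.deprel}\t_\t_"
            )
        lines.append("")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_corpus_dir(directory: str | Path, pattern: str = "*.conllu") -> list[Document]:
    """Read every CoNLL-U file in a directory, sorted by filename."""
    return [read_conllu(p) for p in sorted(Path(directory).glob(pattern))]


# ---------------------------------------------------------------------------
# Live-parser hook registry (optional; CoNLL-U input never needs it)

ParserHook = Callable[[str, str], Document]
_PARSERS: dict[str, ParserHook] = {}


def register_parser(name: str, hook: ParserHook) -> None:
    """Register a parser hook: ``hook(text, doc_id) -> Document``."""
    _PARSERS[name] = hook


def parse_text(text: str, parser: str | ParserHook | None = None, doc_id: str = "doc") -> Document:
    """Parse plain text through a registered hook.

    The pipeline never depends on which parser produced a Document; with no
    hook registered this raises :class:`ParserUnavailableError` advising
    CoNLL-U input instead.
    """
    if callable(parser):
        hook = parser
    else:
        if parser is None and len(_PARSERS) == 1:
            parser = next(iter(_PARSERS))
        if parser is None or parser not in _PARSERS:
            raise ParserUnavailableError(
                "no dependency parser hook registered; supply documents as "
                "CoNLL-U files (read_conllu) or register_parser() a hook"
            )
        hook = _PARSERS[parser]
    try:
        return hook(text, doc_id)
    except Exception as exc:  # noqa: BLE001 - wrap with document context
        raise ParserHookError(f"parser hook failed for document {doc_id!r}: {exc}") from exc
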