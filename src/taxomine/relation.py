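"""Shortest dependency paths, the relation classifier, metrics and ROC.

The semantic link between a taxon span and an interval span is read off the
sentence's dependency tree: the shortest path between the two span anchors
(head links traversed as undirected edges, with the traversal direction and
dependency label recorded per step) is the classifier's input sequence. A
bidirectional LSTM over that path predicts POS/NEG with a two-way softmax;
evaluation uses the standard binary-classification metrics, an ROC sweep
over the score distribution, and a boundary selector that trades recall
against a target false positive rate.

Document-grouped splitting keeps all candidates of one document inside one
of train/validation/test, so near-duplicate sentences from a single source
cannot leak across splits.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from taxomine._bilstm import Adam, BiLSTMNet
from taxomine.candidates import Candidate, Span
from taxomine.corpus import Sentence
from taxomine.errors import PathFailure, TaxomineError, TrainingError
from taxomine.goldlabels import NEG, POS

PAD = "<pad>"
OOV = "<oov>"
ENDPOINT_LABEL = "<e>"

UP = "UP"
DOWN = "DOWN"


class PathStep(NamedTuple):
    """One token on the path; deprel/direction describe the edge *into* it
    (None for the first step)."""

    text: str
    deprel: str | None
    direction: str | None


@dataclass(frozen=True)
class SDPath:
    """Shortest dependency path between the two span anchors."""

    steps: tuple[PathStep, ...]
    taxon_anchor: int
    interval_anchor: int

    def __post_init__(self) -> None:
        if len(self.steps) < 2:
            raise TaxomineError("a dependency path needs at least two steps")

    def token_texts(self) -> list[str]:
        return [s.text for s in self.steps]

    def label_texts(self) -> list[str]:
        return [
            ENDPOINT_LABEL if s.deprel is None else f"{s.deprel}|{s.direction}"
            for s in self.steps
        ]

    def __len__(self) -> int:
        return len(self.steps)


def span_anchor(sentence: Sentence, span: Span) -> int:
    """The span token whose head lies outside the span (leftmost on ties)."""
    inside = range(span.start, span.end)
    for t in sentence.tokens[span.start - 1 : span.end - 1]:
        if t.head not in inside:
            return t.index
    return span.start


def shortest_dependency_path(sentence: Sentence, a: Span, b: Span) -> SDPath:
    """BFS over the undirected head graph from a's anchor to b's anchor.

    Traversing child->head is recorded as UP with the child's deprel;
    head->child as DOWN with that child's deprel. A disconnected parse
    raises :class:`PathFailure` (callers skip the candidate and log).
    """
    heads = {t.index: t.head for t in sentence.tokens}
    texts = {t.index: t.text for t in sentence.tokens}
    deprels = {t.index: t.deprel for t in sentence.tokens}
    adj: dict[int, list[int]] = {t.index: [] for t in sentence.tokens}
    for t in sentence.tokens:
        if t.head != 0:
            adj[t.index].append(t.head)
            adj[t.head].append(t.index)
    start = span_anchor(sentence, a)
    goal = span_anchor(sentence, b)
    parent: dict[int, int] = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        if node == goal:
            break
        for nxt in adj[node]:
            if nxt not in parent:
                parent[nxt] = node
                queue.append(nxt)
    if goal not in parent:
        raise PathFailure(
            f"{sentence.doc_id} sentence {sentence.sent_index}: "
            f"no dependency path between tokens {start} and {goal}"
        )
    nodes = [goal]
    while nodes[-1] != start:
        nodes.append(parent[nodes[-1]])
    nodes.reverse()
    steps = [PathStep(texts[nodes[0]], None, None)]
    for u, v in zip(nodes, nodes[1:]):
        if heads[u] == v:
            steps.append(PathStep(texts[v], deprels[u], UP))
        else:  # heads[v] == u
            steps.append(PathStep(texts[v], deprels[v], DOWN))
    return SDPath(steps=tuple(steps), taxon_anchor=start, interval_anchor=goal)


def candidate_sdpath(candidate: Candidate) -> SDPath:
    return shortest_dependency_path(candidate.sentence, candidate.taxon, candidate.interval)


# ---------------------------------------------------------------------------
# Vocabulary


def build_vocab(sequences: Iterable[Sequence[str]], min_count: int = 1) -> dict[str, int]:
    """Frequency-then-lexicographic vocabulary with PAD=0 and OOV=1.

    Tokens seen fewer than ``min_count`` times map to OOV. Deterministic for
    a given input multiset.
    """
    counts: Counter[str] = Counter()
    for seq in sequences:
        counts.update(seq)
    vocab = {PAD: 0, OOV: 1}
    kept = [(tok, n) for tok, n in counts.items() if n >= min_count]
    kept.sort(key=lambda kv: (-kv[1], kv[0]))
    for tok, _ in kept:
        vocab[tok] = len(vocab)
    return vocab


# ---------------------------------------------------------------------------
# Document-grouped splitting

TRAIN, VALIDATION, TEST = "train", "validation", "test"
_SPLITS = (TRAIN, VALIDATION, TEST)


@dataclass
class SplitAssignment:
    assignment: dict[str, str]      # doc_id -> train/validation/test
    fractions: tuple[float, float, float]
    seed: int

    def of(self, doc_id: str) -> str:
        return self.assignment[doc_id]

    def partition(self, candidates: Sequence[Candidate]) -> dict[str, list[Candidate]]:
        out: dict[str, list[Candidate]] = {s: [] for s in _SPLITS}
        for c in candidates:
            out[self.assignment[c.taxon.doc_id]].append(c)
        return out


def split_by_document(
    candidates: Sequence[Candidate],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Shuffle documents, then greedily fill splits toward candidate-count targets.

    Each shuffled document goes to the split with the largest remaining
    candidate deficit (ties favour train, then validation). All candidates
    of a document land in exactly one split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise TaxomineError(f"fractions must sum to 1, got {fractions}")
    counts: Counter[str] = Counter(c.taxon.doc_id for c in candidates)
    doc_ids = sorted(counts)
    if len(doc_ids) < 3:
        raise TaxomineError(f"need at least 3 documents to split, got {len(doc_ids)}")
    rng = np.random.default_rng(seed)
    order = [doc_ids[i] for i in rng.permutation(len(doc_ids))]
    total = sum(counts.values())
    deficit = [f * total for f in fractions]
    assignment: dict[str, str] = {}
    for doc in order:
        k = max(range(3), key=lambda i: (deficit[i], -i))
        assignment[doc] = _SPLITS[k]
        deficit[k] -= counts[doc]
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


# ---------------------------------------------------------------------------
# Classifier configuration and model


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the relation classifier.

    Defaults are hand-tuned on the synthetic corpus and deliberately small:
    dependency paths are short (a dozen steps covers virtually all of them),
    so modest embeddings and state sizes suffice.
    """

    embedding_dim: int = 24
    label_embedding_dim: int = 8
    lstm_units: int = 24
    hidden_units: int = 32
    dropout: float = 0.1
    learning_rate: float = 0.005
    batch_size: int = 32
    max_epochs: int = 60
    patience: int = 6
    max_path_len: int = 12
    vocab_min_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            self.embedding_dim, self.label_embedding_dim, self.lstm_units,
            self.hidden_units, self.learning_rate, self.batch_size,
            self.max_epochs, self.patience, self.vocab_min_count,
        )
        if any(v <= 0 for v in positive):
            raise TaxomineError("all classifier dimensions/rates must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise TaxomineError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.max_path_len < 2:
            raise TaxomineError("max_path_len must be >= 2")


def _truncate(items: list[str], max_len: int) -> list[str]:
    # keep both endpoints, trim middle
    if len(items) <= max_len:
        return items
    head = max_len - max_len // 2
    tail = max_len // 2
    return items[:head] + items[-tail:]


class RelationModel:
    """Trained classifier: network weights plus vocabularies and config."""

    def __init__(
        self,
        net: BiLSTMNet,
        token_vocab: dict[str, int],
        label_vocab: dict[str, int],
        config: ClassifierConfig,
        history: dict[str, list[float]] | None = None,
        best_epoch: int | None = None,
    ) -> None:
        self.net = net
        self.token_vocab = token_vocab
        self.label_vocab = label_vocab
        self.config = config
        self.history = history or {"train_loss": [], "val_loss": []}
        self.best_epoch = best_epoch

    # -- encoding ----------------------------------------------------------

    def encode(self, paths: Sequence[SDPath]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        max_len = self.config.max_path_len
        tok_rows, lab_rows, lengths = [], [], []
        for p in paths:
            toks = _truncate(p.token_texts(), max_len)
            labs = _truncate(p.label_texts(), max_len)
            tok_rows.append([self.token_vocab.get(t, 1) for t in toks])
            lab_rows.append([self.label_vocab.get(l, 1) for l in labs])
            lengths.append(len(toks))
        T = max(lengths) if lengths else 1
        n = len(tok_rows)
        tok_ids = np.zeros((n, T), dtype=np.intp)
        lab_ids = np.zeros((n, T), dtype=np.intp)
        mask = np.zeros((n, T))
        for r, (trow, lrow, L) in enumerate(zip(tok_rows, lab_rows, lengths)):
            tok_ids[r, :L] = trow
            lab_ids[r, :L] = lrow
            mask[r, :L] = 1.0
        return tok_ids, lab_ids, mask

    def predict_proba(self, paths: Sequence[SDPath], batch_size: int = 256) -> np.ndarray:
        """Positive-class probability per path (softmax pair sums to 1)."""
        out = np.empty(len(paths))
        for lo in range(0, len(paths), batch_size):
            chunk = paths[lo : lo + batch_size]
            tok_ids, lab_ids, mask = self.encode(chunk)
            probs, _ = self.net.forward(tok_ids, lab_ids, mask)
            out[lo : lo + len(chunk)] = probs[:, 1]
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "token_vocab": self.token_vocab,
            "label_vocab": self.label_vocab,
            "config": self.config.__dict__,
            "history": self.history,
            "best_epoch": self.best_epoch,
        }
        np.savez(
            path,
            meta=np.array(json.dumps(meta)),
            **{f"param_{k}": v for k, v in self.net.params.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "RelationModel":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            params = {
                k[len("param_"):]: archive[k] for k in archive.files if k.startswith("param_")
            }
        config = ClassifierConfig(**meta["config"])
        net = BiLSTMNet(
            n_tokens=params["Et"].shape[0],
            n_labels=params["El"].shape[0],
            token_dim=config.embedding_dim,
            label_dim=config.label_embedding_dim,
            lstm_units=config.lstm_units,
            hidden_units=config.hidden_units,
            rng=np.random.default_rng(0),
        )
        net.set_params(params)
        return cls(
            net, meta["token_vocab"], meta["label_vocab"], config,
            history=meta["history"], best_epoch=meta["best_epoch"],
        )


LabelledPath = tuple[SDPath, str]


def _labels_to_y(labelled: Sequence[LabelledPath]) -> np.ndarray:
    return np.array([1 if lab == POS else 0 for _, lab in labelled], dtype=np.intp)


def train_classifier(
    train: Sequence[LabelledPath],
    val: Sequence[LabelledPath],
    config: ClassifierConfig = ClassifierConfig(),
) -> RelationModel:
    """Fit the BiLSTM on labelled paths with early stopping on validation loss.

    Stops once validation loss has not improved for ``config.patience``
    epochs and restores the best-validation weights. Reproducible given
    ``config.seed``. Raises on single-class training data or a non-finite
    loss.
    """
    if not train or not val:
        raise TrainingError("training and validation sets must both be non-empty")
    y_train = _labels_to_y(train)
    if len(set(y_train.tolist())) < 2:
        raise TrainingError("training data contain a single class; cannot fit")
    y_val = _labels_to_y(val)

    token_vocab = build_vocab((p.token_texts() for p, _ in train), config.vocab_min_count)
    label_vocab = build_vocab((p.label_texts() for p, _ in train), 1)
    rng = np.random.default_rng(config.seed)
    net = BiLSTMNet(
        n_tokens=len(token_vocab),
        n_labels=len(label_vocab),
        token_dim=config.embedding_dim,
        label_dim=config.label_embedding_dim,
        lstm_units=config.lstm_units,
        hidden_units=config.hidden_units,
        rng=rng,
    )
    model = RelationModel(net, token_vocab, label_vocab, config)
    tok_tr, lab_tr, mask_tr = model.encode([p for p, _ in train])
    tok_va, lab_va, mask_va = model.encode([p for p, _ in val])
    optimizer = Adam(net.params, lr=config.learning_rate)

    best_val = np.inf
    best_params = net.copy_params()
    best_epoch = 0
    stale = 0
    n = len(train)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            _, cache = net.forward(
                tok_tr[idx], lab_tr[idx], mask_tr[idx],
                dropout=config.dropout, rng=rng,
            )
            loss, grads = net.loss_and_grads(cache, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={config.learning_rate}, batch={config.batch_size})"
                )
            optimizer.step(net.params, grads)
            epoch_loss += loss * len(idx)
        probs_val, cache_val = net.forward(tok_va, lab_va, mask_va)
        eps = 1e-12
        val_loss = -np.mean(
            np.log(probs_val[np.arange(len(y_val)), y_val] + eps)
        )
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        model.history["train_loss"].append(epoch_loss / n)
        model.history["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = net.copy_params()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    net.set_params(best_params)
    model.best_epoch = best_epoch
    return model


def predict(
    model: RelationModel, paths: Sequence[SDPath | None], batch_size: int = 256
) -> list[float | None]:
    """Positive-class probability per item; None passes through for
    candidates whose dependency path could not be computed."""
    valid = [(i, p) for i, p in enumerate(paths) if p is not None]
    out: list[float | None] = [None] * len(paths)
    if valid:
        probs = model.predict_proba([p for _, p in valid], batch_size=batch_size)
        for (i, _), prob in zip(valid, probs):
            out[i] = float(prob)
    return out


# ---------------------------------------------------------------------------
# Metrics, ROC, boundary selection


@dataclass(frozen=True)
class Metrics:
    """Confusion counts with the standard derived rates.

    Ratios with a zero denominator are None (reported as undefined, never
    silently 0).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float | None:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def fpr(self) -> float | None:
        d = self.fp + self.tn
        return self.fp / d if d else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "fpr": self.fpr, "f1": self.f1,
        }


def _check_aligned(probs: Sequence[float], gold: Sequence[str]) -> np.ndarray:
    if len(probs) == 0:
        raise TaxomineError("cannot evaluate an empty prediction set")
    if len(probs) != len(gold):
        raise TaxomineError(f"{len(probs)} probabilities vs {len(gold)} gold labels")
    if any(p is None for p in probs):
        raise TaxomineError("probabilities contain None; filter failed-path candidates first")
    arr = np.asarray(probs, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise TaxomineError("probabilities must lie in [0, 1]")
    return arr


def evaluate(probs: Sequence[float], gold: Sequence[str], boundary: float = 0.5) -> Metrics:
    """Confusion-matrix metrics at decision boundary ``boundary``.

    Ties (prob == boundary) classify POS.
    """
    arr = _check_aligned(probs, gold)
    pos = np.array([g == POS for g in gold])
    pred = arr >= boundary
    return Metrics(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


@dataclass(frozen=True)
class ROCCurve:
    """(threshold, fpr, recall) sweep with trapezoid AUC."""

    points: tuple[tuple[float, float, float], ...]
    auc: float


def roc_curve(probs: Sequence[float], gold: Sequence[str]) -> ROCCurve:
    """Threshold sweep over the unique scores, highest first.

    The first point (threshold +inf) pins (fpr, recall) = (0, 0); the last
    (threshold = lowest score, everything predicted POS) pins (1, 1). AUC by
    the trapezoid rule; requires both classes.
    """
    arr = _check_aligned(probs, gold)
    pos = np.array([g == POS for g in gold])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise TaxomineError("ROC needs both classes present")
    order = np.argsort(-arr, kind="stable")
    sorted_scores = arr[order]
    sorted_pos = pos[order]
    points = [(np.inf, 0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(arr)
    while i < n:
        threshold = sorted_scores[i]
        while i < n and sorted_scores[i] == threshold:
            if sorted_pos[i]:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((float(threshold), fp / n_neg, tp / n_pos))
    fprs = np.array([p[1] for p in points])
    recalls = np.array([p[2] for p in points])
    auc = float(np.trapezoid(recalls, fprs))
    return ROCCurve(points=tuple(points), auc=auc)


class BoundarySelection(NamedTuple):
    boundary: float
    fpr: float
    recall: float


def select_boundary(
    probs: Sequence[float], gold: Sequence[str], target_fpr: float
) -> BoundarySelection:
    """Smallest boundary whose empirical FPR is at or below ``target_fpr``.

    Smaller boundaries admit more positives, so the smallest feasible one
    maximizes recall subject to the FPR constraint. If even predicting
    nothing positive cannot reach the target (degenerate ties), returns
    b = 1 - ulp with a warning.
    """
    if not 0.0 < target_fpr < 1.0 and target_fpr != 1.0:
        raise TaxomineError(f"target_fpr must be in (0, 1], got {target_fpr}")
    arr = _check_aligned(probs, gold)
    pos = np.array([g == POS for g in gold])
    if pos.all() or not pos.any():
        raise TaxomineError("boundary selection needs both classes present")
    best: BoundarySelection | None = None
    for b in np.unique(arr):
        m = evaluate(arr, gold, boundary=float(b))
        if m.fpr is not None and m.fpr <= target_fpr:
            best = BoundarySelection(float(b), m.fpr, m.recall if m.recall is not None else 0.0)
            break  # unique() ascends; the first feasible b is the smallest
    if best is None:
        b = float(np.nextafter(1.0, 0.0))
        m = evaluate(arr, gold, boundary=b)
        warnings.warn(
            f"no boundary attains FPR <= {target_fpr}; returning b just below 1",
            stacklevel=2,
        )
        best = BoundarySelection(b, m.fpr or 0.0, m.recall if m.recall is not None else 0.0)
    return best


# ---------------------------------------------------------------------------
# Repeated fitting


def repeat_fit(
    n: int,
    train: Sequence[LabelledPath],
    val: Sequence[LabelledPath],
    test: Sequence[LabelledPath],
    config: ClassifierConfig = ClassifierConfig(),
) -> dict[str, tuple[float, float]]:
    """Fit ``n`` times with seeds config.seed, config.seed+1, ... and report
    per-metric mean and sample s.d. on the test set at b = 0.5."""
    if n < 2:
        raise TaxomineError(f"repeat_fit needs n >= 2, got {n}")
    test_paths = [p for p, _ in test]
    test_gold = [lab for _, lab in test]
    collected: dict[str, list[float]] = {
        k: [] for k in ("accuracy", "precision", "recall", "fpr", "f1")
    }
    for i in range(n):
        cfg = replace(config, seed=config.seed + i)
        try:
            model = train_classifier(train, val, cfg)
            probs = model.predict_proba(test_paths)
            metrics = evaluate(probs, test_gold)
        except TaxomineError as exc:
            raise TrainingError(f"repeat_fit run {i} (seed {cfg.seed}) failed: {exc}") from exc
        for k in collected:
            value = getattr(metrics, k)
            collected[k].append(np.nan if value is None else value)
    return {
        k: (float(np.mean(v)), float(np.std(v, ddof=1))) for k, v in collected.items()
    }
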