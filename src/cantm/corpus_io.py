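"""Corpus reading, tokenisation, vocabulary construction and fold splitting.

Documents are short claim/explanation texts carrying an optional categorical
label.  Normalisation (lowercasing, stripping non-alphanumerics, dropping
single-character tokens and English stop words) happens once, at
:class:`Document` construction, so every downstream consumer sees the same
token stream.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "Document",
    "Vocabulary",
    "CorpusSplit",
    "tokenize",
    "build_vocabulary",
    "vectorize",
    "vectorize_corpus",
    "read_corpus",
    "write_corpus",
    "make_folds",
]

_TOKEN_RE = re.compile(r"[^a-z0-9]+")


def tokenize(text: str, *, drop_stopwords: bool = True, min_len: int = 2) -> list[str]:
    """Lowercase, strip non-alphanumerics, drop short tokens and stop words."""
    raw = _TOKEN_RE.split(text.lower())
    out = []
    for tok in raw:
        if len(tok) < min_len:
            continue
        if drop_stopwords and tok in ENGLISH_STOP_WORDS:
            continue
        out.append(tok)
    return out


@dataclass
class Document:
    """One text unit: raw text, derived tokens, optional gold label and metadata."""

    id: str
    text: str
    label: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)
    tokens: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.tokens is None:
            self.tokens = tokenize(self.text)


@dataclass(frozen=True)
class Vocabulary:
    """Dense token -> index map (indices 0..size-1)."""

    index: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.index)

    @property
    def tokens(self) -> list[str]:
        inv = sorted(self.index.items(), key=lambda kv: kv[1])
        return [t for t, _ in inv]

    def __contains__(self, token: str) -> bool:
        return token in self.index


@dataclass(frozen=True)
class CorpusSplit:
    """k-fold assignment: document id -> fold index, with the seed that made it."""

    k: int
    assignments: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [d for d, f in self.assignments.items() if f == fold]


def build_vocabulary(
    docs: list[Document], max_size: int = 2000, min_count: int = 1
) -> Vocabulary:
    """The `max_size` most frequent tokens; frequency ties broken lexicographically.

    Tokens come from the documents' normalised token streams (stop words are
    already gone).  Deterministic for a given corpus.
    """
    if not docs:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    if max_size < 1:
        raise ValueError(f"max_size must be >= 1, got {max_size}")
    counts: dict[str, int] = {}
    for doc in docs:
        for tok in doc.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    ranked = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    return Vocabulary({t: i for i, t in enumerate(ranked[:max_size])})


def vectorize(doc: Document, vocab: Vocabulary) -> np.ndarray:
    """Bag-of-words count vector; out-of-vocabulary tokens are ignored."""
    counts = np.zeros(vocab.size, dtype=np.int64)
    for tok in doc.tokens:
        i = vocab.index.get(tok)
        if i is not None:
            counts[i] += 1
    return counts


def vectorize_corpus(docs: list[Document], vocab: Vocabulary) -> np.ndarray:
    """Stacked (n_docs, |V|) count matrix."""
    mat = np.zeros((len(docs), vocab.size), dtype=np.int64)
    for r, doc in enumerate(docs):
        mat[r] = vectorize(doc, vocab)
    return mat


def read_corpus(
    path,
    format: str = "jsonl",
    *,
    label_set: list[str] | None = None,
    text_fields: list[str] | None = None,
) -> list[Document]:
    """Read documents from JSON-lines or CSV.

    `text_fields` joins several columns with a space (e.g. claim + explanation);
    default is the single field ``text``.  When `label_set` is given, unknown
    labels are rejected with the offending line number.
    """
    fields = text_fields or ["text"]
    docs: list[Document] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as e:
                    raise ValueError(f"{path}: malformed record at line {lineno}: {e}") from e
                docs.append(_record_to_doc(rec, lineno, fields, label_set, path))
    elif format == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        for row_idx, rec in enumerate(frame.to_dict(orient="records")):
            docs.append(_record_to_doc(rec, row_idx + 2, fields, label_set, path))
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    return docs


def _record_to_doc(rec, lineno, fields, label_set, path) -> Document:
    text = " ".join(str(rec[f]) for f in fields if f in rec and rec[f] != "")
    label = rec.get("label")
    if label in ("", None):
        label = None
    elif label_set is not None and label not in label_set:
        raise ValueError(f"{path}: unknown label {label!r} at line {lineno}")
    doc_id = str(rec.get("id", lineno))
    meta = rec.get("metadata") or {}
    if not isinstance(meta, dict):
        meta = {}
    return Document(id=doc_id, text=text, label=label, metadata=meta)


def write_corpus(docs: list[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = {"id": d.id, "text": d.text}
            if d.label is not None:
                rec["label"] = d.label
            if d.metadata:
                rec["metadata"] = d.metadata
            fh.write(json.dumps(rec) + "\n")


def make_folds(
    docs: list[Document], k: int = 5, seed: int = 0, stratified: bool = True
) -> CorpusSplit:
    """Deterministic k-fold split; stratified by label when labels are present."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(docs):
        raise ValueError(f"k={k} exceeds corpus size {len(docs)}")
    ids = [d.id for d in docs]
    if stratified and all(d.label is not None for d in docs):
        labels = [d.label for d in docs]
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(ids, labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(ids)
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(split_iter):
        for i in test_idx:
            assignments[ids[i]] = fold
    return CorpusSplit(k=k, assignments=assignments, seed=seed)
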