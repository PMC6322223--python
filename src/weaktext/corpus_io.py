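"""Corpus, label-set and word-vector I/O.

The document model here is deliberately small: a clinical snippet is a
:class:`Document` (id, text, optional gold label, free-form metadata), an
ordered collection of them is a :class:`Corpus`, and the categories of a
classification task form a :class:`LabelSet` with a designated default
category (the label assigned when no extraction rule fires).

Corpora are exchanged as JSON Lines (one object per line, UTF-8) with the
schema ``{"id": str, "text": str, "label": str|absent, "meta": obj|absent}``.
Word vectors are read from the whitespace-delimited text format (one token
followed by its components per line, with an optional ``"<vocab> <dim>"``
header line).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence

import numpy as np

__all__ = [
    "Document",
    "Corpus",
    "LabelSet",
    "EmbeddingTable",
    "read_corpus",
    "write_corpus",
    "read_word_vectors",
    "write_word_vectors",
]


class CorpusFormatError(ValueError):
    """Raised for malformed corpus or word-vector files."""


@dataclass
class Document:
    """One clinical text snippet with an optional gold-standard label."""

    id: str
    text: str
    gold_label: Optional[str] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Document id must be a non-empty string")


@dataclass
class Corpus:
    """An ordered collection of documents for one classification task."""

    documents: List[Document]
    task_name: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for doc in self.documents:
            if doc.id in seen:
                raise ValueError(f"duplicate document id: {doc.id!r}")
            seen.add(doc.id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]

    def gold_labels(self) -> List[Optional[str]]:
        return [d.gold_label for d in self.documents]


@dataclass(frozen=True)
class LabelSet:
    """Ordered category names plus the default assigned when no rule fires."""

    categories: tuple
    default_category: str

    def __post_init__(self) -> None:
        cats = tuple(self.categories)
        object.__setattr__(self, "categories", cats)
        if len(set(cats)) != len(cats):
            raise ValueError("categories must be unique")
        if len(cats) < 2:
            raise ValueError("a label set needs at least 2 categories")
        if self.default_category not in cats:
            raise ValueError(
                f"default {self.default_category!r} not among categories {cats}"
            )

    def __contains__(self, category: str) -> bool:
        return category in self.categories

    def __len__(self) -> int:
        return len(self.categories)


class EmbeddingTable:
    """Token -> k-dimensional vector lookup with case-folded vocabulary.

    Lookup is total over the stored vocabulary and fails closed elsewhere:
    ``table[token]`` raises ``KeyError`` for out-of-vocabulary tokens, and
    ``get`` returns ``None``.
    """

    def __init__(self, vectors: Dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding table must not be empty")
        folded: Dict[str, np.ndarray] = {}
        dim = None
        for tok, vec in vectors.items():
            v = np.asarray(vec, dtype=float)
            if v.ndim != 1:
                raise ValueError(f"vector for {tok!r} is not 1-D")
            if dim is None:
                dim = v.shape[0]
            elif v.shape[0] != dim:
                raise ValueError(
                    f"inconsistent dimension for {tok!r}: {v.shape[0]} != {dim}"
                )
            folded[tok.lower()] = v
        self._vectors = folded
        self.dimension = int(dim)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self._vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self._vectors[token.lower()]

    def get(self, token: str) -> Optional[np.ndarray]:
        return self._vectors.get(token.lower())

    def __len__(self) -> int:
        return len(self._vectors)

    @property
    def vocabulary(self) -> List[str]:
        return list(self._vectors.keys())

    def items(self):
        return self._vectors.items()


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------

def read_corpus(path: str, format: str = "jsonl", task_name: str = "") -> Corpus:
    """Read a corpus from ``path``.

    ``format="jsonl"`` expects one JSON object per non-blank line with at
    least ``id`` and ``text`` fields.  ``format="text-dir"`` reads every
    ``*.txt`` file in a directory as one unlabeled document (id = filename
    stem), in sorted filename order.
    """
    if format == "jsonl":
        return _read_jsonl(path, task_name)
    if format == "text-dir":
        return _read_text_dir(path, task_name)
    raise ValueError(f"unknown corpus format {format!r}; use 'jsonl' or 'text-dir'")


def _read_jsonl(path: str, task_name: str) -> Corpus:
    docs: List[Document] = []
    seen = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"{path}:{lineno}: malformed JSON line: {exc}"
                ) from exc
            if not isinstance(obj, dict) or "id" not in obj or "text" not in obj:
                raise CorpusFormatError(
                    f"{path}:{lineno}: each line needs 'id' and 'text' fields"
                )
            doc_id = str(obj["id"])
            if doc_id in seen:
                raise CorpusFormatError(
                    f"{path}:{lineno}: duplicate document id {doc_id!r}"
                )
            seen.add(doc_id)
            docs.append(
                Document(
                    id=doc_id,
                    text=str(obj["text"]),
                    gold_label=obj.get("label"),
                    meta=dict(obj.get("meta") or {}),
                )
            )
    return Corpus(docs, task_name=task_name)


def _read_text_dir(path: str, task_name: str) -> Corpus:
    if not os.path.isdir(path):
        raise CorpusFormatError(f"not a directory: {path}")
    docs = []
    for name in sorted(os.listdir(path)):
        if not name.endswith(".txt"):
            continue
        with open(os.path.join(path, name), "r", encoding="utf-8") as fh:
            docs.append(Document(id=name[:-4], text=fh.read()))
    return Corpus(docs, task_name=task_name)


def write_corpus(corpus: Corpus, path: str, format: str = "jsonl") -> None:
    """Write ``corpus`` as JSONL; round-trips field-for-field via read_corpus."""
    if format != "jsonl":
        raise ValueError("only the jsonl format is supported for writing")
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            obj: Dict[str, object] = {"id": doc.id, "text": doc.text}
            if doc.gold_label is not None:
                obj["label"] = doc.gold_label
            if doc.meta:
                obj["meta"] = doc.meta
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Word-vector I/O
# ---------------------------------------------------------------------------

def read_word_vectors(path: str) -> EmbeddingTable:
    """Parse a whitespace-delimited word-vector text file.

    Accepts both the headered dialect (first line ``"<vocab> <dim>"``) and
    the headerless one; raises :class:`CorpusFormatError` on inconsistent
    vector lengths (naming the offending token) or an empty file.
    """
    vectors: Dict[str, np.ndarray] = {}
    dim: Optional[int] = None
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    start = 0
    if lines:
        first = lines[0].split()
        # a two-int first line with no parseable float token is a header
        if len(first) == 2:
            try:
                int(first[0]), int(first[1])
                start = 1
            except ValueError:
                pass
    for lineno in range(start, len(lines)):
        parts = lines[lineno].split()
        if not parts:
            continue
        token, comps = parts[0], parts[1:]
        try:
            vec = np.array([float(x) for x in comps], dtype=float)
        except ValueError as exc:
            raise CorpusFormatError(
                f"{path}:{lineno + 1}: non-numeric component for token {token!r}"
            ) from exc
        if dim is None:
            if vec.size == 0:
                raise CorpusFormatError(
                    f"{path}:{lineno + 1}: token {token!r} has no components"
                )
            dim = vec.size
        elif vec.size != dim:
            raise CorpusFormatError(
                f"{path}:{lineno + 1}: token {token!r} has {vec.size} components, "
                f"expected {dim}"
            )
        vectors[token] = vec
    if not vectors:
        raise CorpusFormatError(f"{path}: no word vectors found")
    return EmbeddingTable(vectors)


def write_word_vectors(table: EmbeddingTable, path: str, header: bool = True) -> None:
    """Write an embedding table in the whitespace text format."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(table)} {table.dimension}\n")
        for tok, vec in table.items():
            fh.write(tok + " " + " ".join(f"{x:.6g}" for x in vec) + "\n")
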