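"""Coded document corpora: JSONL I/O, tokenization, label population tables.

A corpus is a list of documents, each carrying a gold label set and a split
tag (``train``/``dev``/``test``).  Label *population* means the number of
documents in a split that carry the label (labels are sets per document, so
population counts documents, not mentions).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd

from .errors import DuplicateIdError, MalformedRecordError
from .hierarchy import CodeId, parse_code

SPLITS = ("train", "dev", "test")

_TOKEN_RE = re.compile(r"[0-9a-z]+")


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    labels: frozenset[CodeId]
    split: str

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise MalformedRecordError(
                f"document {self.doc_id!r}: bad split {self.split!r}"
            )

    def with_(self, **changes) -> "Document":
        return replace(self, **changes)


@dataclass
class Corpus:
    """A collection of documents with unique ids and a provenance tag."""

    documents: list[Document]
    provenance: str = "real"  # real | synthetic | augmented

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise DuplicateIdError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def split(self, name: str) -> list[Document]:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return [d for d in self.documents if d.split == name]

    def codeset(self) -> set[CodeId]:
        out: set[CodeId] = set()
        for doc in self.documents:
            out |= doc.labels
        return out


def read_corpus(path, provenance: str = "real") -> Corpus:
    """Read a line-delimited JSON corpus.

    Each line is an object with fields ``doc_id``, ``text``, ``labels``
    (array of code strings, normalized on read) and ``split``.
    """
    documents = []
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                raise MalformedRecordError(f"line {lineno}: invalid JSON") from exc
            missing = {"doc_id", "text", "labels", "split"} - set(raw)
            if missing:
                raise MalformedRecordError(
                    f"line {lineno}: missing fields {sorted(missing)}"
                )
            documents.append(
                Document(
                    doc_id=str(raw["doc_id"]),
                    text=str(raw["text"]),
                    labels=frozenset(parse_code(c) for c in raw["labels"]),
                    split=str(raw["split"]),
                )
            )
    return Corpus(documents, provenance=provenance)


def write_corpus(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for doc in corpus.documents:
            handle.write(
                json.dumps(
                    {
                        "doc_id": doc.doc_id,
                        "text": doc.text,
                        "labels": sorted(doc.labels),
                        "split": doc.split,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def preprocess_text(text: str, max_tokens: int = 4000) -> list[str]:
    """Lowercase, split on non-alphanumeric runs, truncate to ``max_tokens``.

    Deterministic and idempotent on its own (re-joined) output.  The default
    cap of 4000 word tokens matches the document-length ceiling used
    throughout the pipeline.
    """
    tokens = _TOKEN_RE.findall(text.lower())
    return tokens[:max_tokens]


@dataclass(frozen=True)
class PopulationTable:
    """Per-code document counts per split, as a DataFrame indexed by code
    with integer columns ``train``/``dev``/``test``."""

    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(SPLITS):
            raise ValueError("population table needs columns train,dev,test")

    def count(self, code: CodeId, split: str) -> int:
        if code not in self.counts.index:
            return 0
        return int(self.counts.at[code, split])

    def codes(self) -> list[CodeId]:
        return list(self.counts.index)

    def total(self, split: str) -> int:
        return int(self.counts[split].sum())

    def few_shot_codes(self, max_count: int = 5) -> set[CodeId]:
        """Codes appearing at least once but no more than ``max_count`` times
        in the training split."""
        mask = (self.counts["train"] >= 1) & (self.counts["train"] <= max_count)
        return set(self.counts.index[mask])

    def zero_shot_codes(self) -> set[CodeId]:
        """Codes absent from training but present in the test split."""
        mask = (self.counts["train"] == 0) & (self.counts["test"] >= 1)
        return set(self.counts.index[mask])


def label_populations(corpus: Corpus) -> PopulationTable:
    """Exact per-code, per-split document counts."""
    rows: dict[CodeId, dict[str, int]] = {}
    for doc in corpus.documents:
        for code in doc.labels:
            rows.setdefault(code, {s: 0 for s in SPLITS})[doc.split] += 1
    frame = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(SPLITS), fill_value=0
    )
    frame = frame.fillna(0).astype(int).sort_index()
    return PopulationTable(frame)


def merge_corpora(base: Corpus, extra: Iterable[Document], provenance: str) -> Corpus:
    """Concatenate ``extra`` documents onto ``base`` under a new provenance."""
    return Corpus(list(base.documents) + list(extra), provenance=provenance)
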