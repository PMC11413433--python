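"""Silver-standard construction.

The silver standard is the set of algorithmically constructed label sets
used as generation requests.  For every few-shot generation code, its
source documents are cloned round-robin until the code's population reaches
``target_pop`` (default 100); clones randomly drop up to ``max_drop``
(default 5) of their non-relevant labels for variety.  For every zero-shot
generation code, each training document carrying a sibling of the code
yields one request with a random sibling replaced by the zero-shot code.
Duplicate label sets receive generation temperature 0.1 (so output can
vary); unique sets temperature 0.0 (deterministic generation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .corpus import Corpus, Document
from .errors import NoSiblingError, NoSourcesError
from .hierarchy import CodeId, Hierarchy, siblings_of
from .selection import SelectionResult

logger = logging.getLogger(__name__)

TEMP_UNIQUE = 0.0
TEMP_DUPLICATE = 0.1


@dataclass(frozen=True)
class SilverRecord:
    """One generation request: a label set built around a target code."""

    source_doc_id: str
    target_code: CodeId
    label_set: frozenset[CodeId]
    is_zero_shot: bool
    temperature: float = TEMP_UNIQUE
    clone_index: int = 0

    def __post_init__(self) -> None:
        if self.target_code not in self.label_set:
            raise ValueError(
                f"target {self.target_code} missing from its own label set"
            )
        if not self.label_set:
            raise ValueError("empty label set")

    def key(self) -> str:
        return f"{self.target_code}:{self.source_doc_id}:{self.clone_index}"


@dataclass
class SilverSet:
    records: list[SilverRecord]
    duplicate_flags: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class SilverConfig:
    target_pop: int = 100
    max_drop: int = 5
    #: Cap on substitution records per zero-shot code (uniform subsample of
    #: the sibling-bearing documents when more are available).  Defaults to
    #: the few-shot target population so every generation code receives a
    #: comparable number of synthetic examples; None disables the cap.
    zero_shot_cap: int | None = 100


def drop_nonrelevant(
    labels: frozenset[CodeId],
    relevant: frozenset[CodeId],
    max_drop: int,
    rng: np.random.Generator,
) -> frozenset[CodeId]:
    """Randomly drop up to ``max_drop`` non-relevant labels.

    The number of drops k is uniform on {0..min(max_drop, #nonrelevant)}
    (zero drops included), then k non-relevant labels are removed uniformly
    without replacement.  Relevant labels are always retained.
    """
    if not relevant <= labels:
        raise ValueError("relevant labels must be a subset of the label set")
    nonrelevant = sorted(labels - relevant)
    cap = min(max_drop, len(nonrelevant))
    k = int(rng.integers(0, cap + 1))
    if k == 0:
        return labels
    dropped = rng.choice(len(nonrelevant), size=k, replace=False)
    removed = {nonrelevant[i] for i in dropped}
    return labels - removed


def clone_to_population(
    sources: Sequence[Document],
    code: CodeId,
    relevant: frozenset[CodeId],
    cfg: SilverConfig,
    rng: np.random.Generator,
) -> list[SilverRecord]:
    """Clone ``sources`` round-robin until ``code``'s population reaches
    ``cfg.target_pop``.

    Originals (clone_index 0) keep their label sets unmodified; clones pass
    through :func:`drop_nonrelevant`.  If the population is already met the
    sources are returned unchanged (as clone_index-0 records).
    """
    if not sources:
        raise NoSourcesError(f"no source documents for {code}")
    for doc in sources:
        if code not in doc.labels:
            raise ValueError(f"source {doc.doc_id} does not carry {code}")
    records = [
        SilverRecord(
            source_doc_id=doc.doc_id,
            target_code=code,
            label_set=doc.labels,
            is_zero_shot=False,
            clone_index=0,
        )
        for doc in sources
    ]
    n_clones = cfg.target_pop - len(sources)
    if n_clones <= 0:
        return records
    for i in range(n_clones):
        doc = sources[i % len(sources)]
        labels = drop_nonrelevant(
            doc.labels, (relevant & doc.labels) | {code}, cfg.max_drop, rng
        )
        records.append(
            SilverRecord(
                source_doc_id=doc.doc_id,
                target_code=code,
                label_set=labels,
                is_zero_shot=False,
                clone_index=i // len(sources) + 1,
            )
        )
    return records


def substitute_zero_shot(
    doc: Document,
    zs_code: CodeId,
    codeset: Iterable[CodeId],
    hierarchy: Hierarchy,
    rng: np.random.Generator,
) -> SilverRecord:
    """Replace one uniformly chosen sibling of ``zs_code`` in ``doc``'s labels
    with ``zs_code`` itself."""
    sibs = sorted(siblings_of(zs_code, codeset) & doc.labels)
    if not sibs:
        raise NoSiblingError(f"{doc.doc_id} has no sibling of {zs_code}")
    victim = sibs[int(rng.integers(0, len(sibs)))]
    labels = (doc.labels - {victim}) | {zs_code}
    return SilverRecord(
        source_doc_id=doc.doc_id,
        target_code=zs_code,
        label_set=frozenset(labels),
        is_zero_shot=True,
        clone_index=0,
    )


def assign_temperatures(records: list[SilverRecord]) -> SilverSet:
    """Flag duplicates (exact label-set equality with any earlier record) and
    assign temperatures: duplicates 0.1, uniques 0.0.  Order-stable."""
    seen: set[frozenset[CodeId]] = set()
    out, flags = [], []
    for rec in records:
        dup = rec.label_set in seen
        seen.add(rec.label_set)
        flags.append(dup)
        out.append(replace(rec, temperature=TEMP_DUPLICATE if dup else TEMP_UNIQUE))
    return SilverSet(out, flags)


def build_silver_set(
    corpus: Corpus,
    selection: SelectionResult,
    hierarchy: Hierarchy,
    cfg: SilverConfig = SilverConfig(),
    rng: np.random.Generator | None = None,
) -> SilverSet:
    """Build the full silver standard from a corpus and a selection result."""
    if rng is None:
        rng = np.random.default_rng(0)
    train_docs = corpus.split("train")
    codeset = corpus.codeset()
    relevant = frozenset(selection.generation_codes)
    records: list[SilverRecord] = []

    for code in sorted(selection.few_shot_generation):
        sources = [d for d in train_docs if code in d.labels]
        if not sources:
            logger.warning("few-shot generation code %s has no sources", code)
            continue
        records.extend(clone_to_population(sources, code, relevant, cfg, rng))

    for code in sorted(selection.zero_shot_generation):
        sib_docs = [
            d for d in train_docs if siblings_of(code, codeset) & d.labels
        ]
        if not sib_docs:
            logger.warning("zero-shot code %s has no sibling-bearing docs", code)
        if cfg.zero_shot_cap is not None and len(sib_docs) > cfg.zero_shot_cap:
            keep = rng.choice(len(sib_docs), size=cfg.zero_shot_cap, replace=False)
            sib_docs = [sib_docs[i] for i in sorted(keep)]
        for doc in sib_docs:
            records.append(
                substitute_zero_shot(doc, code, codeset, hierarchy, rng)
            )

    return assign_temperatures(records)


def write_silver_set(silver: SilverSet, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for rec in silver.records:
            handle.write(
                json.dumps(
                    {
                        "source_doc_id": rec.source_doc_id,
                        "target_code": rec.target_code,
                        "labels": sorted(rec.label_set),
                        "is_zero_shot": rec.is_zero_shot,
                        "temperature": rec.temperature,
                        "clone_index": rec.clone_index,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_silver_set(path) -> SilverSet:
    records = []
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            raw = json.loads(line)
            records.append(
                SilverRecord(
                    source_doc_id=raw["source_doc_id"],
                    target_code=raw["target_code"],
                    label_set=frozenset(raw["labels"]),
                    is_zero_shot=bool(raw["is_zero_shot"]),
                    temperature=float(raw["temperature"]),
                    clone_index=int(raw["clone_index"]),
                )
            )
    seen: set[frozenset[str]] = set()
    flags = []
    for rec in records:
        flags.append(rec.label_set in seen)
        seen.add(rec.label_set)
    return SilverSet(records, flags)
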