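"""Code space representation: code grammar, families, ancestors, descriptions.

Codes follow the ICD-10 surface convention: an uppercase letter followed by
two alphanumerics forms the *category* (the "head" of the code, here called
the family), optionally extended by a subcategory suffix of up to four
alphanumerics, separated by at most one dot (``S02.63XA``) or written
plain (seven-character procedure codes carry no dot).  The three-character
head defines the code's family; by default the hierarchy is exactly one
level deep (leaf -> family), which is how within-family structure is used
throughout the pipeline.  A deeper hierarchy (e.g. an extra block layer
such as ``E08-E13``) can be supplied from a file for the depth-general
hierarchical metrics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import MalformedCodeError, UnknownLeafError

#: A parsed, normalized code token.  Kept as ``str`` for ergonomic set
#: operations; :func:`parse_code` is the only constructor.
CodeId = str

#: A three-character family head.
FamilyId = str

_CODE_RE = re.compile(r"^[A-Z][0-9A-Z]{2}(?:\.[0-9A-Z]{1,4}|[0-9A-Z]{1,4})?$")


def parse_code(text: str) -> CodeId:
    """Normalize and validate a code token.

    Uppercases, strips surrounding whitespace, and validates against the
    code grammar (leading letter, three-character head, at most one dot,
    at most four subcategory characters).

    Raises
    ------
    MalformedCodeError
        If the string does not scan as a code, naming the offender.
    """
    if text is None:
        raise MalformedCodeError("code is None")
    token = text.strip().upper()
    if not token:
        raise MalformedCodeError("empty code string")
    if not _CODE_RE.match(token):
        raise MalformedCodeError(f"malformed code: {text!r}")
    return token


def family_of(code: CodeId) -> FamilyId:
    """Return the three-character family head of ``code``."""
    return parse_code(code)[:3]


def siblings_of(code: CodeId, codeset: Iterable[CodeId]) -> set[CodeId]:
    """All members of ``codeset`` sharing ``code``'s family head, minus ``code``."""
    code = parse_code(code)
    head = code[:3]
    return {c for c in codeset if c != code and family_of(c) == head}


@dataclass(frozen=True)
class CodeTable:
    """Mapping of code -> long description, mirroring a diagnosis dictionary
    table with columns ``icd_code,long_title``."""

    entries: Mapping[CodeId, str]

    def __post_init__(self) -> None:
        for code, desc in self.entries.items():
            parse_code(code)
            if not str(desc).strip():
                raise ValueError(f"empty description for code {code}")

    def __contains__(self, code: CodeId) -> bool:
        return code in self.entries

    def __getitem__(self, code: CodeId) -> str:
        return self.entries[code]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path) -> "CodeTable":
        frame = pd.read_csv(path, dtype=str)
        if not {"icd_code", "long_title"} <= set(frame.columns):
            raise ValueError("code table needs columns icd_code,long_title")
        entries = {
            parse_code(row.icd_code): row.long_title
            for row in frame.itertuples(index=False)
        }
        if len(entries) != len(frame):
            raise ValueError("duplicate codes in code table")
        return cls(entries)

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(
            sorted(self.entries.items()), columns=["icd_code", "long_title"]
        )
        frame.to_csv(path, index=False)


@dataclass(frozen=True)
class Hierarchy:
    """Leaves plus ancestor links.

    ``depth_mode`` is ``"family-only"`` (every leaf's single ancestor is its
    three-character head) or ``"multi-level"`` (explicit parent links loaded
    from a file, e.g. family -> block -> chapter).
    """

    leaves: frozenset[CodeId]
    parent: Mapping[str, str] = field(default_factory=dict)
    depth_mode: str = "family-only"

    @classmethod
    def family_only(cls, leaves: Iterable[CodeId]) -> "Hierarchy":
        normalized = frozenset(parse_code(c) for c in leaves)
        return cls(leaves=normalized, parent={}, depth_mode="family-only")

    @classmethod
    def from_file(cls, path) -> "Hierarchy":
        """Load a multi-level hierarchy from ``node_id,parent_id,level`` CSV.

        Rows with ``level == "leaf"`` are leaves; parent chains terminate at
        nodes whose ``parent_id`` is empty.
        """
        frame = pd.read_csv(path, dtype=str).fillna("")
        leaves, parent = [], {}
        for row in frame.itertuples(index=False):
            node = row.node_id.strip()
            if row.level.strip().lower() == "leaf":
                leaves.append(parse_code(node))
            if row.parent_id.strip():
                parent[node] = row.parent_id.strip()
        hier = cls(frozenset(leaves), parent, depth_mode="multi-level")
        hier._check_acyclic()
        return hier

    def _check_acyclic(self) -> None:
        for start in self.parent:
            seen = {start}
            node = start
            while node in self.parent:
                node = self.parent[node]
                if node in seen:
                    raise ValueError(f"ancestor cycle through {node}")
                seen.add(node)

    def ancestors_of(self, code: CodeId) -> list[str]:
        """Chain of ancestor node ids from immediate parent upward.

        In family-only mode this is exactly ``[family_of(code)]``.
        """
        code = parse_code(code)
        if code not in self.leaves:
            raise UnknownLeafError(code)
        if self.depth_mode == "family-only":
            return [family_of(code)]
        chain = []
        node = code
        while node in self.parent:
            node = self.parent[node]
            chain.append(node)
        return chain


def ancestors_of(code: CodeId, hierarchy: Hierarchy) -> list[str]:
    """Functional alias for :meth:`Hierarchy.ancestors_of`."""
    return hierarchy.ancestors_of(code)
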