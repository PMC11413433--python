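"""Prompt rendering, document generation, code extraction and scrubbing.

Generation requests are rendered into prompts listing ``CODE: Description``
lines plus eight constraint blocks (length cap, social/family history,
anonymization, no in-text codes, explicit numeric values, specific concepts
for "other" umbrellas, omission of "unspecified", trailing bracketed
codes).  Documents come from a pluggable generator with the interface
``generator(prompt, temperature, seed) -> text``; the built-in generator is
a deterministic template engine that honours every constraint, so the whole
pipeline runs without any hosted model.  Post-processing extracts the
bracketed codes from the trailing discharge-diagnoses section and scrubs
every code mention from the body.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._lexicon import (
    FAMILY_HISTORY_SENTENCES,
    FILLER_SENTENCES,
    SOCIAL_HISTORY_SENTENCES,
    SPECIFIC_CONCEPTS,
)
from .errors import GeneratorFailureError, MalformedCodeError, MissingDescriptionError
from .hierarchy import CodeId, CodeTable, parse_code
from .silver import SilverRecord

logger = logging.getLogger(__name__)

MAX_WORDS = 4000

# A bare code token: leading uppercase letter, three-character head, at most
# one dot, up to four subcategory characters, and at least one digit (the
# digit requirement keeps ordinary uppercase words out of scrubbing).
CODE_PATTERN = re.compile(
    r"\b[A-Z](?=[0-9A-Z.]{2,7}\b)(?=[0-9A-Z.]*[0-9])"
    r"[0-9A-Z]{2}(?:\.[0-9A-Z]{1,4}|[0-9A-Z]{1,4})?\b"
)
BRACKETED_CODE = re.compile(
    r"\[([A-Z](?=[0-9A-Z.]*[0-9])[0-9A-Z]{2}(?:\.[0-9A-Z]{1,4}|[0-9A-Z]{1,4})?)\]"
)

DIAGNOSES_HEADER = "Discharge Diagnoses:"

#: The eight mandatory prompt constraint blocks, keyed by a stable name.
CONSTRAINT_BLOCKS: dict[str, str] = {
    "word_cap": f"Write at most {MAX_WORDS} words.",
    "social_family_history": "Include a social history and a family history section.",
    "anonymization": (
        "Anonymize all personal and location data; refer to the patient "
        "generically while keeping clinically relevant numeric information."
    ),
    "no_in_text_codes": "Do not mention any diagnosis codes within the main text.",
    "explicit_numerics": (
        "Prefer clear numeric values over ranges, especially for "
        "time-related conditions."
    ),
    "specific_for_other": (
        'For conditions described with the umbrella term "other", name a '
        "specific concept instead."
    ),
    "omit_unspecified": (
        'Omit the keyword "unspecified"; express the condition naturally.'
    ),
    "trailing_codes": (
        "End the document with a numbered list of discharge diagnoses, "
        "placing each code in square brackets after its diagnosis."
    ),
}


def render_prompt(
    record: SilverRecord,
    code_table: CodeTable,
    constraints: dict[str, str] | None = None,
) -> str:
    """Render the generation prompt for one silver record.

    Deterministic: one ``CODE: Description`` line per label (sorted), plus
    all eight constraint blocks.
    """
    blocks = CONSTRAINT_BLOCKS if constraints is None else constraints
    missing_blocks = set(CONSTRAINT_BLOCKS) - set(blocks)
    if missing_blocks:
        raise ValueError(f"missing constraint blocks: {sorted(missing_blocks)}")
    absent = sorted(c for c in record.label_set if c not in code_table)
    if absent:
        raise MissingDescriptionError(f"no description for: {absent}")
    lines = [
        "Write a discharge summary for a patient with the following "
        "conditions and procedures:",
        "",
    ]
    lines += [f"{code}: {code_table[code]}" for code in sorted(record.label_set)]
    lines += ["", "Constraints:"]
    lines += [f"- {blocks[name]}" for name in sorted(CONSTRAINT_BLOCKS)]
    return "\n".join(lines)


@dataclass(frozen=True)
class RawDocument:
    text: str
    requested_labels: frozenset[CodeId]
    generator_name: str
    seed: int
    temperature: float


@dataclass(frozen=True)
class CodingResponse:
    raw: str
    pairs: list[tuple[str, CodeId]]
    parse_mode: str  # structured | fallback | unparsed


# ---------------------------------------------------------------------------
# Built-in deterministic generator
# ---------------------------------------------------------------------------

_PROMPT_LABEL_RE = re.compile(r"^([A-Z][0-9A-Z.]{2,8}): (.+)$", re.MULTILINE)
_PLACEHOLDER_RE = re.compile(r"<N>")


def _rng_for(prompt: str, temperature: float, seed: int) -> np.random.Generator:
    # Temperature 0 mimics a deterministic decoder: the output depends only
    # on the prompt.  Positive temperature mixes in the seed.
    material = prompt if temperature == 0.0 else f"{prompt}\n::{temperature}::{seed}"
    digest = hashlib.sha256(material.encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def paraphrase_description(desc: str, rng: np.random.Generator) -> str:
    """Rewrite a code description for in-text use.

    Removes the token "unspecified", swaps "Other ..." umbrella phrasing for
    a concrete concept from the bundled lexicon, and instantiates ``<N>``
    numeric placeholders with concrete values.
    """
    text = desc.strip()
    if re.match(r"^other\b", text, flags=re.IGNORECASE):
        text = SPECIFIC_CONCEPTS[int(rng.integers(0, len(SPECIFIC_CONCEPTS)))]
    text = re.sub(r",?\s*\bunspecified\b", "", text, flags=re.IGNORECASE)
    text = _PLACEHOLDER_RE.sub(lambda _: str(int(rng.integers(1, 10))), text)
    text = re.sub(r"\s+", " ", text).strip(" ,")
    return text[:1].lower() + text[1:]


def mock_llm_generate(prompt: str, temperature: float, seed: int) -> str:
    """Deterministic template generator honouring the prompt constraints.

    Parses the ``CODE: Description`` lines out of its own prompt (so it can
    stand behind the generic generator interface), writes a sectioned
    summary mentioning each paraphrased condition, and closes with the
    numbered bracketed-code list.
    """
    rng = _rng_for(prompt, temperature, seed)
    labels = _PROMPT_LABEL_RE.findall(prompt)
    if not labels:
        raise ValueError("prompt contains no CODE: Description lines")
    paraphrases = {code: paraphrase_description(desc, rng) for code, desc in labels}

    hb = int(rng.integers(70, 160))
    bp_sys = int(rng.integers(95, 180))
    stay = int(rng.integers(2, 15))
    hgb = round(float(rng.uniform(7.0, 15.0)), 1)

    hpi = [
        "History of Present Illness:",
        "The patient presented with "
        + ", ".join(paraphrases[c] for c, _ in labels)
        + ".",
        f"On arrival the heart rate was {hb} beats per minute and systolic "
        f"blood pressure {bp_sys} mmHg.",
    ]
    course = [
        "Hospital Course:",
        f"Each condition was addressed over a {stay} day admission.",
        f"Admission hemoglobin was {hgb} g/dL.",
        str(FILLER_SENTENCES[int(rng.integers(0, len(FILLER_SENTENCES)))]),
    ]
    social = [
        "Social History:",
        SOCIAL_HISTORY_SENTENCES[int(rng.integers(0, len(SOCIAL_HISTORY_SENTENCES)))],
    ]
    family = [
        "Family History:",
        FAMILY_HISTORY_SENTENCES[int(rng.integers(0, len(FAMILY_HISTORY_SENTENCES)))],
    ]
    diagnoses = [DIAGNOSES_HEADER] + [
        f"{i}. {paraphrases[code].capitalize()} [{code}]"
        for i, (code, _) in enumerate(labels, start=1)
    ]
    text = "\n".join(
        ["\n".join(hpi), "", "\n".join(course), "", "\n".join(social), "",
         "\n".join(family), "", "\n".join(diagnoses)]
    )
    words = text.split()
    if len(words) > MAX_WORDS:
        text = " ".join(words[:MAX_WORDS])
    return text


#: Generator registry: name -> callable(prompt, temperature, seed) -> text.
GENERATORS: dict[str, Callable[[str, float, int], str]] = {
    "mock": mock_llm_generate,
}


def generate_document(
    record: SilverRecord,
    code_table: CodeTable,
    seed: int,
    generator: str | Callable[[str, float, int], str] = "mock",
) -> RawDocument:
    """Render the prompt for ``record`` and run it through a generator."""
    if isinstance(generator, str):
        name = generator
        try:
            fn = GENERATORS[generator]
        except KeyError:
            raise GeneratorFailureError(f"unknown generator {generator!r}") from None
    else:
        name, fn = getattr(generator, "__name__", "custom"), generator
    prompt = render_prompt(record, code_table)
    try:
        text = fn(prompt, record.temperature, seed)
    except Exception as exc:  # noqa: BLE001 - wrapped with record context
        raise GeneratorFailureError(
            f"generator {name!r} failed on record {record.key()}: {exc}"
        ) from exc
    return RawDocument(
        text=text,
        requested_labels=record.label_set,
        generator_name=name,
        seed=seed,
        temperature=record.temperature,
    )


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------

def extract_assigned_codes(raw: RawDocument | str) -> tuple[set[CodeId], str]:
    """Extract bracketed codes from the trailing discharge-diagnoses section.

    Returns the parsed code set and the document text with the code
    brackets removed.  Codes bracketed outside the trailing section are not
    extracted but logged.  If no section or no bracketed codes are found,
    returns an empty set with the text unchanged (plus a warning).
    """
    text = raw.text if isinstance(raw, RawDocument) else raw
    idx = text.rfind(DIAGNOSES_HEADER)
    if idx < 0:
        logger.warning("no discharge-diagnoses section found")
        return set(), text
    head, tail = text[:idx], text[idx:]
    stray = BRACKETED_CODE.findall(head)
    if stray:
        logger.warning("bracketed codes outside diagnoses section: %s", stray)
    codes = set()
    for token in BRACKETED_CODE.findall(tail):
        try:
            codes.add(parse_code(token))
        except MalformedCodeError:
            logger.warning("unparseable bracketed token %r", token)
    if not codes:
        logger.warning("no bracketed codes in diagnoses section")
        return set(), text
    body = head + re.sub(r"\s*" + BRACKETED_CODE.pattern, "", tail)
    return codes, body


def scrub_codes(text: str) -> str:
    """Remove every code mention (bare or bracketed); idempotent."""
    out = BRACKETED_CODE.sub("", text)
    out = CODE_PATTERN.sub("", out)
    out = re.sub(r"[ \t]+", " ", out)
    out = re.sub(r" +\n", "\n", out)
    return out.strip()


_FALLBACK_PAIR_RE = re.compile(
    r"diagnosis[\"'\s:=-]*([^\"',{}\n]+?)[\"'\s,;-]*"
    r"icd[_\s-]?code[\"'\s:=-]*([A-Za-z][0-9A-Za-z.]{2,8})",
    flags=re.IGNORECASE,
)
_FALLBACK_BRACKET_RE = re.compile(
    r"([^\[\]\n.;:]{3,}?)\s*\[([A-Za-z][0-9A-Za-z.]{2,8})\]"
)


def parse_coding_response(resp: str) -> CodingResponse:
    """Parse a coding-task response.

    Structured-first: if the response contains a JSON array of objects with
    keys ``diagnosis`` and ``icd_code``, extract those directly.  Otherwise
    fall back to a pattern scan over the raw text.  Codes are de-duplicated
    keeping the first diagnosis text; unparseable responses yield an empty
    pair list with ``parse_mode == "unparsed"``.
    """
    pairs = _try_structured(resp)
    if pairs is not None:
        return CodingResponse(resp, _dedupe(pairs), "structured")
    pairs = _FALLBACK_PAIR_RE.findall(resp)
    pairs += _FALLBACK_BRACKET_RE.findall(resp)
    valid = []
    for diagnosis, token in pairs:
        try:
            valid.append((diagnosis.strip(), parse_code(token)))
        except MalformedCodeError:
            continue
    if valid:
        return CodingResponse(resp, _dedupe(valid), "fallback")
    logger.info("coding response unparseable; returning empty pair list")
    return CodingResponse(resp, [], "unparsed")


def _try_structured(resp: str) -> list[tuple[str, str]] | None:
    start, end = resp.find("["), resp.rfind("]")
    if start < 0 or end <= start:
        return None
    try:
        payload = json.loads(resp[start : end + 1])
    except json.JSONDecodeError:
        return None
    if not isinstance(payload, list) or not payload:
        return None
    pairs = []
    for item in payload:
        if not (isinstance(item, dict) and "diagnosis" in item and "icd_code" in item):
            return None
        try:
            pairs.append((str(item["diagnosis"]).strip(), parse_code(str(item["icd_code"]))))
        except MalformedCodeError:
            continue
    return pairs


def _dedupe(pairs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    seen: set[str] = set()
    out = []
    for diagnosis, code in pairs:
        if code not in seen and diagnosis:
            seen.add(code)
            out.append((diagnosis, code))
    return out
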