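import re

import numpy as np
import pytest

from icdaug.docgen import (
    CODE_PATTERN,
    CONSTRAINT_BLOCKS,
    extract_assigned_codes,
    generate_document,
    mock_llm_generate,
    parse_coding_response,
    render_prompt,
    scrub_codes,
)
from icdaug.errors import GeneratorFailureError, MissingDescriptionError
from icdaug.hierarchy import CodeTable
from icdaug.silver import SilverRecord

TABLE = CodeTable(
    {
        "D64.9": "Anemia, unspecified",
        "E10.21": "Type 1 diabetes mellitus with diabetic nephropathy",
        "G43.909": "Migraine, unspecified, not intractable",
        "H35.89": "Other specified retinal disorders",
        "K21.9": "Gastro-esophageal reflux disease without esophagitis",
        "S02.63XA": "Fracture of mandible, <N> weeks healing, initial encounter",
    }
)


def _record(labels, target=None, temperature=0.0):
    labels = frozenset(labels)
    return SilverRecord(
        source_doc_id="src0",
        target_code=target or sorted(labels)[0],
        label_set=labels,
        is_zero_shot=False,
        temperature=temperature,
    )


class TestRenderPrompt:
    def test_contains_code_description_lines_and_blocks(self):
        prompt = render_prompt(_record({"D64.9", "K21.9"}), TABLE)
        assert "D64.9: Anemia, unspecified" in prompt
        for block in CONSTRAINT_BLOCKS.values():
            assert block in prompt

    def test_missing_description_raises(self):
        with pytest.raises(MissingDescriptionError, match="Z99.9"):
            render_prompt(_record({"Z99.9"}), TABLE)

    def test_all_blocks_mandatory(self):
        with pytest.raises(ValueError, match="constraint blocks"):
            render_prompt(_record({"D64.9"}), TABLE, constraints={})

    def test_deterministic(self):
        rec = _record({"D64.9", "E10.21"})
        assert render_prompt(rec, TABLE) == render_prompt(rec, TABLE)


class TestMockGenerator:
    def test_temperature_zero_bit_reproducible(self):
        rec = _record({"D64.9", "K21.9"})
        a = generate_document(rec, TABLE, seed=7)
        b = generate_document(rec, TABLE, seed=7)
        assert a.text == b.text

    def test_temperature_positive_varies_with_seed_same_codes(self):
        rec = _record({"D64.9", "K21.9"}, temperature=0.1)
        a = generate_document(rec, TABLE, seed=1)
        b = generate_document(rec, TABLE, seed=2)
        assert a.text != b.text
        assert extract_assigned_codes(a)[0] == extract_assigned_codes(b)[0]

    def test_unspecified_token_absent_from_body(self):
        rec = _record({"D64.9"})
        raw = generate_document(rec, TABLE, seed=0)
        assert "anemia" in raw.text.lower()
        assert "unspecified" not in raw.text.lower()

    def test_other_umbrella_replaced_by_concrete_concept(self):
        rec = _record({"H35.89"})
        raw = generate_document(rec, TABLE, seed=0)
        body = raw.text.lower()
        assert "other specified retinal" not in body

    def test_numeric_placeholder_instantiated(self):
        rec = _record({"S02.63XA"})
        raw = generate_document(rec, TABLE, seed=0)
        assert "<N>" not in raw.text
        assert re.search(r"\b\d+ weeks healing", raw.text)

    def test_no_code_tokens_outside_brackets(self):
        rec = _record(set(TABLE.entries))
        raw = generate_document(rec, TABLE, seed=0)
        without_brackets = re.sub(r"\[[^\]]*\]", "", raw.text)
        assert not CODE_PATTERN.search(without_brackets)

    def test_word_cap_respected(self):
        rec = _record(set(TABLE.entries))
        raw = generate_document(rec, TABLE, seed=0)
        assert len(raw.text.split()) <= 4000

    def test_has_required_sections(self):
        raw = generate_document(_record({"D64.9"}), TABLE, seed=0)
        for section in ("History of Present Illness", "Hospital Course",
                        "Social History", "Family History",
                        "Discharge Diagnoses"):
            assert section in raw.text

    def test_unknown_generator_raises(self):
        with pytest.raises(GeneratorFailureError):
            generate_document(_record({"D64.9"}), TABLE, seed=0,
                              generator="hosted-model")


class TestExtraction:
    def test_single_bracketed_code(self):
        text = "Course.\n\nDischarge Diagnoses:\n1. Diabetes with nephropathy [E10.21]"
        codes, body = extract_assigned_codes(text)
        assert codes == {"E10.21"}
        assert "[E10.21]" not in body
        assert "Diabetes with nephropathy" in body

    def test_roundtrip_over_random_records(self):
        rng = np.random.default_rng(5)
        codes = sorted(TABLE.entries)
        for i in range(200):
            n = int(rng.integers(1, len(codes) + 1))
            picked = frozenset(
                codes[j] for j in rng.choice(len(codes), size=n, replace=False)
            )
            rec = _record(picked, temperature=0.1)
            raw = generate_document(rec, TABLE, seed=i)
            extracted, body = extract_assigned_codes(raw)
            assert extracted == picked
            assert not CODE_PATTERN.search(scrub_codes(body))

    def test_no_brackets_warns_and_returns_empty(self, caplog):
        codes, body = extract_assigned_codes("just prose, no codes")
        assert codes == set()
        assert body == "just prose, no codes"


class TestScrub:
    def test_basic(self):
        assert scrub_codes("fracture [S02.63XA] healed") == "fracture healed"

    def test_bare_code_removed(self):
        assert "E10.21" not in scrub_codes("diagnosed E10.21 today")

    def test_ordinary_words_untouched(self):
        text = "THE PATIENT was GIVEN 20 mg IV"
        assert scrub_codes(text) == text

    def test_idempotent(self):
        text = "a [E10.21] b G43.909 c"
        once = scrub_codes(text)
        assert scrub_codes(once) == once


class TestParseCodingResponse:
    def test_structured_path(self):
        resp = '[{"diagnosis": "anemia", "icd_code": "D64.9"}]'
        parsed = parse_coding_response(resp)
        assert parsed.parse_mode == "structured"
        assert parsed.pairs == [("anemia", "D64.9")]

    def test_structured_with_prose_wrapper(self):
        resp = ('Here are the codes:\n'
                '[{"diagnosis": "migraine", "icd_code": "G43.909"},'
                ' {"diagnosis": "anemia", "icd_code": "D64.9"}]\nThanks!')
        parsed = parse_coding_response(resp)
        assert parsed.parse_mode == "structured"
        assert len(parsed.pairs) == 2

    @pytest.mark.parametrize(
        "resp",
        [
            'diagnosis: anemia icd_code: D64.9, diagnosis: migraine '
            'icd_code: G43.909',
            '"diagnosis": "anemia", "icd_code": "D64.9"\n'
            '"diagnosis": "migraine", "icd_code": "G43.909"',
            '1. anemia [D64.9]\n2. migraine [G43.909]',
            'diagnosis - anemia, icd-code - D64.9; diagnosis - migraine, '
            'icd-code - G43.909',
        ],
    )
    def test_fallback_path_two_pairs(self, resp):
        parsed = parse_coding_response(resp)
        assert parsed.parse_mode == "fallback"
        assert {code for _, code in parsed.pairs} == {"D64.9", "G43.909"}

    def test_garbage_yields_empty_with_flag(self):
        parsed = parse_coding_response("I cannot code this.")
        assert parsed.parse_mode == "unparsed"
        assert parsed.pairs == []

    def test_duplicate_codes_keep_first_diagnosis(self):
        resp = ('[{"diagnosis": "anemia", "icd_code": "D64.9"},'
                ' {"diagnosis": "anaemia", "icd_code": "D64.9"}]')
        parsed = parse_coding_response(resp)
        assert parsed.pairs == [("anemia", "D64.9")]
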