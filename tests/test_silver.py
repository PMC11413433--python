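import numpy as np
import pytest

from icdaug.corpus import Document
from icdaug.errors import NoSiblingError, NoSourcesError
from icdaug.hierarchy import Hierarchy
from icdaug.silver import (
    SilverConfig,
    assign_temperatures,
    build_silver_set,
    clone_to_population,
    drop_nonrelevant,
    read_silver_set,
    substitute_zero_shot,
    write_silver_set,
)


def _doc(i, labels, split="train"):
    return Document(f"d{i}", "text", frozenset(labels), split)


class TestDropNonrelevant:
    def test_relevant_always_kept_and_cap_applied(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            out = drop_nonrelevant(
                frozenset({"R00", "A01", "A02", "A03"}), frozenset({"R00"}), 5, rng
            )
            assert "R00" in out

    def test_nothing_to_drop(self):
        rng = np.random.default_rng(0)
        assert drop_nonrelevant(frozenset({"R00"}), frozenset({"R00"}), 5, rng) == {
            "R00"
        }

    def test_uniform_k_contract(self):
        # 8 droppable labels, cap 5: every k in 0..5 observed, relevant never lost
        rng = np.random.default_rng(1)
        labels = frozenset({"R00"} | {f"A{i:02d}" for i in range(8)})
        seen_k = set()
        for _ in range(10_000):
            out = drop_nonrelevant(labels, frozenset({"R00"}), 5, rng)
            assert "R00" in out
            seen_k.add(len(labels) - len(out))
        assert seen_k == {0, 1, 2, 3, 4, 5}


class TestCloneToPopulation:
    def test_counts_4_sources(self):
        sources = [_doc(i, {"E10.3", f"A0{i}"}) for i in range(4)]
        rng = np.random.default_rng(0)
        records = clone_to_population(
            sources, "E10.3", frozenset({"E10.3"}), SilverConfig(), rng
        )
        assert len(records) == 100
        assert sum(r.clone_index == 0 for r in records) == 4

    def test_counts_98_sources(self):
        sources = [_doc(i, {"E10.3"}) for i in range(98)]
        rng = np.random.default_rng(0)
        records = clone_to_population(
            sources, "E10.3", frozenset({"E10.3"}), SilverConfig(), rng
        )
        assert len(records) == 100

    def test_population_already_met_returns_sources(self):
        sources = [_doc(i, {"E10.3"}) for i in range(120)]
        rng = np.random.default_rng(0)
        records = clone_to_population(
            sources, "E10.3", frozenset({"E10.3"}), SilverConfig(), rng
        )
        assert len(records) == 120
        assert all(r.clone_index == 0 for r in records)

    def test_no_sources_raises(self):
        with pytest.raises(NoSourcesError):
            clone_to_population(
                [], "E10.3", frozenset(), SilverConfig(), np.random.default_rng(0)
            )

    def test_originals_unmodified_clones_bounded_drops(self):
        sources = [_doc(0, {"E10.3", "A01", "A02", "A03", "B01", "B02", "B03",
                            "C01", "C02"})]
        rng = np.random.default_rng(2)
        records = clone_to_population(
            sources, "E10.3", frozenset({"E10.3"}), SilverConfig(), rng
        )
        assert records[0].label_set == sources[0].labels
        for rec in records[1:]:
            dropped = sources[0].labels - rec.label_set
            assert len(dropped) <= 5
            assert "E10.3" in rec.label_set


class TestSubstituteZeroShot:
    CODESET = {"S02.1", "S02.5", "S02.63XA", "K21.9", "G43.0", "G43.9"}
    HIER = Hierarchy.family_only(CODESET)

    def test_one_sibling_swapped(self):
        doc = _doc(0, {"S02.1", "S02.5", "K21.9"})
        rng = np.random.default_rng(0)
        rec = substitute_zero_shot(doc, "S02.63XA", self.CODESET, self.HIER, rng)
        assert rec.is_zero_shot
        assert "S02.63XA" in rec.label_set
        assert "K21.9" in rec.label_set
        removed = doc.labels - rec.label_set
        assert len(removed) == 1 and removed <= {"S02.1", "S02.5"}

    def test_single_sibling(self):
        doc = _doc(0, {"G43.0"})
        rng = np.random.default_rng(0)
        rec = substitute_zero_shot(doc, "G43.9", self.CODESET, self.HIER, rng)
        assert rec.label_set == {"G43.9"}

    def test_no_sibling_raises(self):
        doc = _doc(0, {"K21.9"})
        with pytest.raises(NoSiblingError):
            substitute_zero_shot(
                doc, "G43.9", self.CODESET, self.HIER, np.random.default_rng(0)
            )


class TestTemperatures:
    def test_all_unique_all_zero(self):
        from icdaug.silver import SilverRecord

        records = [
            SilverRecord("d0", "A01", frozenset({"A01", f"B{i:02d}"}), False)
            for i in range(5)
        ]
        silver = assign_temperatures(records)
        assert all(r.temperature == 0.0 for r in silver.records)
        assert not any(silver.duplicate_flags)

    def test_duplicates_get_point_one(self):
        from icdaug.silver import SilverRecord

        records = [
            SilverRecord("d0", "A01", frozenset({"A01"}), False),
            SilverRecord("d1", "A01", frozenset({"A01"}), False),
        ]
        silver = assign_temperatures(records)
        assert silver.records[0].temperature == 0.0
        assert silver.records[1].temperature == 0.1
        assert silver.duplicate_flags == [False, True]


class TestBuildSilverSet:
    def test_record_arithmetic_on_tiny_fixture(self):
        # 2 few-shot codes (pops 3 and 4) -> 100 each; 1 zero-shot code with
        # 5 sibling-bearing train docs -> 5 records; total 205
        from icdaug.selection import SelectionResult

        docs = []
        for i in range(3):
            docs.append(_doc(f"f1{i}", {"E10.1", "A01"}))
        for i in range(4):
            docs.append(_doc(f"f2{i}", {"E10.2", "A01"}))
        for i in range(5):
            docs.append(_doc(f"s{i}", {"G43.1", "B01"}))
        docs.append(Document("t0", "t", frozenset({"G43.9"}), "test"))
        from icdaug.corpus import Corpus

        corpus = Corpus(docs)
        sel = SelectionResult(
            few_shot_common=frozenset(),
            retained_families=frozenset({"E10", "G43"}),
            chosen_families=frozenset({"E10", "G43"}),
            few_shot_generation=frozenset({"E10.1", "E10.2"}),
            zero_shot_generation=frozenset({"G43.9"}),
        )
        hier = Hierarchy.family_only(corpus.codeset())
        silver = build_silver_set(
            corpus, sel, hier, SilverConfig(), np.random.default_rng(0)
        )
        assert len(silver) == 205
        zs = [r for r in silver.records if r.is_zero_shot]
        assert len(zs) == 5
        assert all("G43.9" in r.label_set and "G43.1" not in r.label_set
                   for r in zs)

    def test_contract_on_synthetic_corpus(self, small_corpus, small_selection):
        corpus, _ = small_corpus
        sel, pop = small_selection
        hier = Hierarchy.family_only(corpus.codeset())
        cfg = SilverConfig()
        silver = build_silver_set(corpus, sel, hier, cfg, np.random.default_rng(4))
        by_code: dict[str, int] = {}
        for rec in silver.records:
            assert rec.target_code in rec.label_set
            by_code[rec.target_code] = by_code.get(rec.target_code, 0) + 1
        for code in sel.few_shot_generation:
            if pop.count(code, "train") >= 1:
                assert by_code[code] == cfg.target_pop
        # duplicates and only duplicates carry temperature 0.1
        seen: set[frozenset] = set()
        for rec in silver.records:
            expected = 0.1 if rec.label_set in seen else 0.0
            assert rec.temperature == expected
            seen.add(rec.label_set)

    def test_seed_reproducible(self, small_corpus, small_selection):
        corpus, _ = small_corpus
        sel, _ = small_selection
        hier = Hierarchy.family_only(corpus.codeset())
        a = build_silver_set(corpus, sel, hier, SilverConfig(),
                             np.random.default_rng(9))
        b = build_silver_set(corpus, sel, hier, SilverConfig(),
                             np.random.default_rng(9))
        assert a.records == b.records

    def test_jsonl_roundtrip(self, tmp_path, small_corpus, small_selection):
        corpus, _ = small_corpus
        sel, _ = small_selection
        hier = Hierarchy.family_only(corpus.codeset())
        silver = build_silver_set(corpus, sel, hier, SilverConfig(),
                                  np.random.default_rng(4))
        path = tmp_path / "silver.jsonl"
        write_silver_set(silver, path)
        back = read_silver_set(path)
        assert back.records == silver.records
        assert back.duplicate_flags == silver.duplicate_flags
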