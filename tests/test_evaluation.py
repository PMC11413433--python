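"""Metric machinery tests, checked against independent brute-force oracles.

The oracles below recompute every metric by naive enumeration (loops over
documents and labels, ancestor multisets via collections.Counter) with no
shared code with the package's implementations.
"""

import numpy as np
import pytest

from oracles import (
    oracle_flat,
    oracle_hier,
    oracle_whcm,
    random_instance,
)

from icdaug.evaluation import (
    extend_with_ancestors,
    flat_metrics,
    hierarchical_metrics,
    whcm_rates,
)
from icdaug.hierarchy import Hierarchy

# ---------------------------------------------------------------------------
# Worked examples (hand-derived from the metric definitions)
# ---------------------------------------------------------------------------

HIER_A = Hierarchy.family_only(["A01.1", "A01.2", "A01.3"])


class TestWorkedExamples:
    def test_flat_single_doc(self):
        report = flat_metrics([{"A01.1"}], [{"A01.1", "A01.2"}],
                              ["A01.1", "A01.2"])
        assert report.micro_p == pytest.approx(0.5)
        assert report.micro_r == pytest.approx(1.0)
        assert report.micro_f1 == pytest.approx(2 / 3)

    def test_flat_macro_mixed_labels(self):
        # A01.1 perfect (F1=1), A01.2 pure false positive (F1=0) -> macro 0.5
        report = flat_metrics([{"A01.1"}], [{"A01.1", "A01.2"}],
                              ["A01.1", "A01.2"])
        assert report.macro_f1 == pytest.approx(0.5)

    def test_flat_perfect(self):
        report = flat_metrics([{"A01.1"}, {"A01.2"}], [{"A01.1"}, {"A01.2"}],
                              ["A01.1", "A01.2"])
        assert report.micro_f1 == 1.0 and report.macro_f1 == 1.0

    def test_extension_counts_and_set(self):
        got = extend_with_ancestors({"A01.1", "A01.2"}, HIER_A, mode="counts")
        assert got == {"A01.1": 1, "A01.2": 1, "A01": 2}
        got = extend_with_ancestors({"A01.1", "A01.2"}, HIER_A, mode="set")
        assert got == {"A01.1": 1, "A01.2": 1, "A01": 1}
        assert extend_with_ancestors(set(), HIER_A, mode="counts") == {}

    def test_sibling_confusion_partial_credit(self):
        # gold {A1,A2} vs pred {A1,A3}: leaf P=R=0.5;
        # set-based P=R=2/3; count-preserving P=R=3/4
        gold, pred = [{"A01.1", "A01.2"}], [{"A01.1", "A01.3"}]
        leaf = flat_metrics(gold, pred, ["A01.1", "A01.2", "A01.3"])
        assert leaf.micro_p == pytest.approx(0.5)
        assert leaf.micro_r == pytest.approx(0.5)
        sb = hierarchical_metrics(gold, pred, HIER_A, "set_based")
        assert sb.micro_p == pytest.approx(2 / 3)
        assert sb.micro_r == pytest.approx(2 / 3)
        cophe = hierarchical_metrics(gold, pred, HIER_A, "cophe")
        assert cophe.micro_p == pytest.approx(3 / 4)
        assert cophe.micro_r == pytest.approx(3 / 4)

    def test_overprediction_penalized_by_count_preservation(self):
        # gold {A1} vs pred {A1,A2}: set-based P=2/3,R=1;
        # count-preserving P=2/4,R=1 -> lower F1
        gold, pred = [{"A01.1"}], [{"A01.1", "A01.2"}]
        sb = hierarchical_metrics(gold, pred, HIER_A, "set_based")
        cophe = hierarchical_metrics(gold, pred, HIER_A, "cophe")
        assert sb.micro_p == pytest.approx(2 / 3)
        assert sb.micro_r == pytest.approx(1.0)
        assert cophe.micro_p == pytest.approx(0.5)
        assert cophe.micro_r == pytest.approx(1.0)
        assert cophe.micro_f1 < sb.micro_f1

    def test_perfect_prediction_all_variants(self):
        gold = [{"A01.1", "A01.2"}]
        for variant in ("set_based", "cophe"):
            report = hierarchical_metrics(gold, gold, HIER_A, variant)
            assert report.micro_f1 == 1.0

    def test_macro_over_nodes_option(self):
        # per-node scores, hand-derived: A1 (0,0,0), A2 (.5,1,2/3), A (1,1,1)
        gold, pred = [{"A01.1"}, {"A01.2"}], [{"A01.2"}, {"A01.2"}]
        report = hierarchical_metrics(gold, pred, HIER_A, "set_based",
                                      average="macro")
        assert report.micro_p == pytest.approx(3 / 4)
        assert report.macro_p == pytest.approx(0.5)
        assert report.macro_r == pytest.approx(2 / 3)
        assert report.macro_f1 == pytest.approx(5 / 9)

    def test_whcm_doc_example(self):
        # gold {A1,B1}, pred {A2}: A1 -> IF (A2 same-family FP); B1 -> OOF
        hier = Hierarchy.family_only(["A01.1", "A01.2", "B02.1"])
        report = whcm_rates([{"A01.1", "B02.1"}], [{"A01.2"}],
                            ["A01.1", "B02.1"], hier)
        assert report.oof_rate == pytest.approx(50.0)
        assert report.if_rate == pytest.approx(50.0)
        assert report.tp_rate == pytest.approx(0.0)

    def test_whcm_perfect_prediction(self):
        hier = Hierarchy.family_only(["A01.1", "B02.1"])
        report = whcm_rates([{"A01.1", "B02.1"}], [{"A01.1", "B02.1"}],
                            ["A01.1", "B02.1"], hier)
        assert report.oof_rate == 0.0 and report.if_rate == 0.0
        assert report.tp_rate == pytest.approx(100.0)

    def test_whcm_fp_alone_creates_no_error(self):
        hier = Hierarchy.family_only(["A01.1", "A01.2"])
        report = whcm_rates([{"A01.1"}], [{"A01.1", "A01.2"}], ["A01.1"], hier)
        assert report.tp_rate == pytest.approx(100.0)
        assert report.oof_rate == 0.0 and report.if_rate == 0.0


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        checked_whcm = 0
        for _ in range(500):
            leaves, families, gold, pred = random_instance(rng)
            hier = Hierarchy.family_only(leaves)
            report = flat_metrics(gold, pred, leaves)
            (mi_p, mi_r, mi_f), (ma_p, ma_r, ma_f) = oracle_flat(gold, pred, leaves)
            assert report.micro_p == pytest.approx(mi_p, abs=1e-12)
            assert report.micro_r == pytest.approx(mi_r, abs=1e-12)
            assert report.micro_f1 == pytest.approx(mi_f, abs=1e-12)
            assert report.macro_p == pytest.approx(ma_p, abs=1e-12)
            assert report.macro_r == pytest.approx(ma_r, abs=1e-12)
            assert report.macro_f1 == pytest.approx(ma_f, abs=1e-12)

            for variant, mode in (("set_based", "set"), ("cophe", "counts")):
                got = hierarchical_metrics(gold, pred, hier, variant)
                p, r, f = oracle_hier(gold, pred, families, mode)
                assert got.micro_p == pytest.approx(p, abs=1e-12)
                assert got.micro_r == pytest.approx(r, abs=1e-12)
                assert got.micro_f1 == pytest.approx(f, abs=1e-12)

            if any(g for g in gold):
                got = whcm_rates(gold, pred, leaves, hier)
                oof, if_, tp = oracle_whcm(gold, pred, set(leaves), families)
                assert got.oof_rate == pytest.approx(oof, abs=1e-9)
                assert got.if_rate == pytest.approx(if_, abs=1e-9)
                assert got.tp_rate == pytest.approx(tp, abs=1e-9)
                checked_whcm += 1
        assert checked_whcm > 400


class TestInvariants:
    def test_whcm_conservation_per_label(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            leaves, families, gold, pred = random_instance(rng)
            if not any(gold):
                continue
            hier = Hierarchy.family_only(leaves)
            report = whcm_rates(gold, pred, leaves, hier)
            assert report.tp_rate + report.if_rate + report.oof_rate == \
                pytest.approx(100.0)

    def test_document_and_label_order_invariance(self):
        rng = np.random.default_rng(11)
        leaves, families, gold, pred = random_instance(rng)
        while not any(gold):
            leaves, families, gold, pred = random_instance(rng)
        hier = Hierarchy.family_only(leaves)
        perm = list(reversed(range(len(gold))))
        gold2 = [gold[i] for i in perm]
        pred2 = [pred[i] for i in perm]
        assert flat_metrics(gold, pred, leaves) == \
            flat_metrics(gold2, pred2, list(reversed(leaves)))
        for variant in ("set_based", "cophe"):
            assert hierarchical_metrics(gold, pred, hier, variant) == \
                hierarchical_metrics(gold2, pred2, hier, variant)
        assert whcm_rates(gold, pred, leaves, hier) == \
            whcm_rates(gold2, pred2, list(reversed(leaves)), hier)

    def test_sibling_substitution_keeps_ancestor_credit(self):
        # replacing a predicted gold leaf with a sibling preserves the family
        # count, so count-preserving scores exceed set-based cannot drop below
        # ... they stay equal at ancestors while leaf TP drops
        gold = [{"A01.1", "A01.2"}]
        pred = [{"A01.1", "A01.3"}]  # A01.2 -> sibling A01.3
        cophe = hierarchical_metrics(gold, pred, HIER_A, "cophe")
        sb = hierarchical_metrics(gold, pred, HIER_A, "set_based")
        assert cophe.micro_f1 >= sb.micro_f1

    def test_extension_never_removes_leaves(self):
        labels = {"A01.1", "A01.3"}
        for mode in ("set", "counts"):
            vec = extend_with_ancestors(labels, HIER_A, mode)
            assert labels <= set(vec)
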