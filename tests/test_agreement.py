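"""Cohen's kappa, call vectors, decision-change analysis, status accuracy."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mrmcbe import (
    BinaryCallVector,
    call_vector,
    change_table,
    cohens_kappa,
    intra_reader_changes,
    mean_pairwise_kappa,
    readers_vs_ai_kappa,
    status_accuracy,
)
from mrmcbe.agreement import ChangeSummary, _summarize, ChangeRecord

from conftest import ai_ann, bb, build_study, gt_ann, reader_ann


def vec(calls, label="x", level="image"):
    return BinaryCallVector(
        level=level,
        source_label=label,
        unit_ids=tuple(f"u{i}" for i in range(len(calls))),
        calls=tuple(bool(c) for c in calls),
    )


def kappa_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Independent contingency-table formula: kappa = 2(ad-bc) /
    ((a+b)(b+d) + (a+c)(c+d))."""
    return 2 * (a * d - b * c) / ((a + b) * (b + d) + (a + c) * (c + d))


class TestCohensKappa:
    def test_identical_nonconstant_vectors_give_one(self):
        v = vec([1, 1, 0, 0, 1])
        assert cohens_kappa(v, v) == 1.0

    def test_contingency_closed_form(self):
        # agreement table: both-pos 20, a-only 5, b-only 10, both-neg 15
        a_calls = [1] * 20 + [1] * 5 + [0] * 10 + [0] * 15
        b_calls = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 15
        k = cohens_kappa(vec(a_calls), vec(b_calls))
        assert k == pytest.approx(kappa_closed_form(20, 5, 10, 15))

    def test_matches_sklearn_on_random_vectors(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.random(60) < rng.uniform(0.2, 0.8)
            b = rng.random(60) < rng.uniform(0.2, 0.8)
            if a.all() or (~a).all() or b.all() or (~b).all():
                continue
            assert cohens_kappa(vec(a), vec(b)) == pytest.approx(
                cohen_kappa_score(a, b)
            )

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(7)
        n = 10_000
        a, b = rng.random(n) < 0.5, rng.random(n) < 0.5
        assert abs(cohens_kappa(vec(a), vec(b))) < 0.05

    def test_symmetry_and_relabel_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.random(50) < 0.4, rng.random(50) < 0.6
        k = cohens_kappa(vec(a), vec(b))
        assert k == pytest.approx(cohens_kappa(vec(b), vec(a)))
        assert k == pytest.approx(cohens_kappa(vec(~a), vec(~b)))

    def test_constant_identical_raters_defined_as_one(self):
        assert cohens_kappa(vec([1, 1, 1]), vec([1, 1, 1])) == 1.0

    def test_mismatched_unit_sets_rejected(self):
        with pytest.raises(ValueError, match="unit sets"):
            cohens_kappa(vec([1, 0]), vec([1, 0, 1]))


class TestMeanPairwise:
    def test_identical_readers_give_one(self):
        vs = [vec([1, 0, 1, 0], label=f"r{i}") for i in range(7)]
        assert mean_pairwise_kappa(vs).kappa == 1.0

    def test_constructed_third_kappa(self):
        # pair kappas (1, 0, 0) by construction -> mean 1/3
        v1 = vec([1, 1, 0, 0], "a")
        v2 = vec([1, 1, 0, 0], "b")
        v3 = vec([1, 0, 1, 0], "c")
        res = mean_pairwise_kappa([v1, v2, v3])
        assert dict(((x, y), k) for x, y, k in res.pair_kappas) == pytest.approx(
            {("a", "b"): 1.0, ("a", "c"): 0.0, ("b", "c"): 0.0}
        )
        assert res.kappa == pytest.approx(1 / 3)

    def test_invariant_to_reader_ordering(self):
        rng = np.random.default_rng(11)
        vs = [vec(rng.random(40) < 0.5, label=f"r{i}") for i in range(4)]
        assert mean_pairwise_kappa(vs).kappa == pytest.approx(
            mean_pairwise_kappa(vs[::-1]).kappa
        )

    def test_single_reader_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mean_pairwise_kappa([vec([1, 0])])

    def test_readers_vs_ai_averages_each_reader(self):
        ai = vec([1, 0, 1, 0], "ai")
        r1 = vec([1, 0, 1, 0], "r1")  # kappa 1
        r2 = vec([1, 0, 0, 1], "r2")  # kappa 0
        assert readers_vs_ai_kappa([r1, r2], ai).kappa == pytest.approx(0.5)


class TestCallVector:
    def test_examination_positive_when_any_box_anywhere(self):
        anns = [reader_ann("i2", bb(0, 0, 5, 5), "R1", "r1")]
        ds = build_study({"e1": ["i1", "i2"], "e2": ["i3"]}, anns)
        v = call_vector(ds, "reader", "examination", "r1", "R1")
        assert v.as_mapping() == {"e1": True, "e2": False}

    def test_fracture_kappa_mode_fp_pseudo_unit_counts_once(self):
        # three stray boxes on one image -> single positive FP pseudo-unit
        anns = [
            gt_ann("i1", bb(0, 0, 10, 10)),
            reader_ann("i1", bb(100, 100, 110, 110), "R1", "r1"),
            reader_ann("i1", bb(200, 200, 210, 210), "R1", "r1"),
            reader_ann("i1", bb(300, 300, 310, 310), "R1", "r1"),
        ]
        ds = build_study({"e1": ["i1"]}, anns)
        v = call_vector(ds, "reader", "fracture", "r1", "R1", kappa_mode=True)
        assert v.as_mapping() == {"frac:i1:0": False, "fp:i1": True}
        gt_v = call_vector(ds, "ground_truth", "fracture", kappa_mode=True)
        assert gt_v.as_mapping() == {"frac:i1:0": True, "fp:i1": False}

    def test_fracture_level_requires_kappa_mode(self):
        ds = build_study({"e1": ["i1"]}, [])
        with pytest.raises(ValueError, match="kappa_mode"):
            call_vector(ds, "ai", "fracture")

    def test_ai_image_vector_consistent_with_confusion_counts(self, small_study):
        from mrmcbe import image_level_counts

        v = call_vector(small_study, "ai", "image")
        c = image_level_counts(small_study, small_study.ai)
        assert v.n_positive == c.tp + c.fp


class TestIntraReaderChanges:
    def _two_round_study(self):
        # i1: clean image, reader positive in r1 only; AI negative.
        # i2: fracture, reader misses r1, finds r2; AI positive on it.
        anns = [
            gt_ann("i2", bb(0, 0, 10, 10)),
            ai_ann("i2", bb(0, 0, 10, 10)),
            reader_ann("i1", bb(5, 5, 15, 15), "R1", "r1"),
            reader_ann("i2", bb(0, 0, 10, 10), "R1", "r2"),
        ]
        return build_study({"e1": ["i1", "i2"]}, anns)

    def test_image_level_directions_correctness_alignment(self):
        ds = self._two_round_study()
        records, summary = intra_reader_changes(ds, "R1", "image")
        by_unit = {r.unit_id: r for r in records}
        assert by_unit["i1"].direction == "pos_to_neg"
        assert by_unit["i1"].correct and by_unit["i1"].ai_aligned
        assert by_unit["i2"].direction == "neg_to_pos"
        assert by_unit["i2"].correct and by_unit["i2"].ai_aligned
        assert summary.overall == {"n": 2, "correct": 2, "wrong": 0}

    def test_fp_removal_counts_as_one_change_to_true_negative(self):
        # two stray boxes in round 1, one in round 2 on a clean image
        anns = [
            reader_ann("i1", bb(0, 0, 10, 10), "R1", "r1"),
            reader_ann("i1", bb(50, 50, 60, 60), "R1", "r1"),
            reader_ann("i1", bb(0, 0, 10, 10), "R1", "r2"),
            # second image so both rounds are non-empty at all times
            reader_ann("i2", bb(0, 0, 10, 10), "R1", "r1"),
            reader_ann("i2", bb(0, 0, 10, 10), "R1", "r2"),
        ]
        ds = build_study({"e1": ["i1", "i2"]}, anns)
        records, summary = intra_reader_changes(ds, "R1", "fracture")
        assert len(records) == 1
        rec = records[0]
        assert rec.unit_id == "fp:i1"
        assert rec.direction == "pos_to_neg"
        assert rec.correct  # removal lands on a true negative
        # the AI drew nothing on i1, so dropping the positive aligns with it
        assert rec.ai_aligned

    def test_missing_round_rejected(self):
        anns = [reader_ann("i1", bb(0, 0, 5, 5), "R1", "r1")]
        ds = build_study({"e1": ["i1"]}, anns)
        with pytest.raises(ValueError, match="r2"):
            intra_reader_changes(ds, "R1", "image")

    @pytest.mark.parametrize("level", ["image", "examination"])
    def test_change_counts_reconcile_round_totals(self, small_study, level):
        for rid in small_study.reader_ids:
            v1 = call_vector(small_study, "reader", level, "r1", rid)
            v2 = call_vector(small_study, "reader", level, "r2", rid)
            records, summary = intra_reader_changes(small_study, rid, level)
            p2n = summary.pos_to_neg["n"]
            n2p = summary.neg_to_pos["n"]
            assert v1.n_positive - p2n + n2p == v2.n_positive

    def test_nesting_sums(self, small_study):
        for level in ("image", "examination", "fracture"):
            _, s = intra_reader_changes(small_study, "R1", level)
            assert s.pos_to_neg["n"] + s.neg_to_pos["n"] == s.overall["n"]
            assert s.agree_ai["n"] + s.disagree_ai["n"] == s.overall["n"]
            for grp in (s.overall, s.pos_to_neg, s.neg_to_pos, s.agree_ai, s.disagree_ai):
                assert grp["correct"] + grp["wrong"] == grp["n"]
            for ali in (s.agree_ai, s.disagree_ai):
                assert ali["pos_to_neg"]["n"] + ali["neg_to_pos"]["n"] == ali["n"]

    def test_ai_alignment_consistent_with_ai_vector(self, small_study):
        ai_map = call_vector(small_study, "ai", "image").as_mapping()
        records, _ = intra_reader_changes(small_study, "R1", "image")
        for r in records:
            r2_call = r.direction == "neg_to_pos"
            assert r.ai_aligned == (r2_call == ai_map[r.unit_id])


def _fake_summary(n, correct, agree_n, agree_correct, total):
    """ChangeSummary with only the cells change_table needs populated."""
    wrong = n - correct
    mk = lambda nn, cc: {"n": nn, "correct": cc, "wrong": nn - cc}
    nested = lambda nn, cc: {**mk(nn, cc), "pos_to_neg": mk(0, 0), "neg_to_pos": mk(0, 0)}
    return ChangeSummary(
        reader_id="r",
        level="image",
        total_units=total,
        overall=mk(n, correct),
        pos_to_neg=mk(0, 0),
        neg_to_pos=mk(0, 0),
        agree_ai=nested(agree_n, agree_correct),
        disagree_ai=nested(n - agree_n, correct - agree_correct),
    )


class TestChangeTable:
    def test_reference_per_image_ratios(self):
        # per-reader integers summing to 350 changes, 261 AI-aligned of which
        # 216 correct -> averages 50.00, 37.29 (74.57%) and 30.86 (82.76%)
        n_per_reader = [50, 50, 50, 50, 50, 50, 50]
        agree = [37, 37, 37, 37, 38, 38, 37]  # sum 261
        agree_correct = [31, 31, 31, 31, 31, 31, 30]  # sum 216
        summaries = [
            _fake_summary(n, n, a, ac, 336)
            for n, a, ac in zip(n_per_reader, agree, agree_correct)
        ]
        t = change_table(summaries).set_index("row")
        assert t.loc["overall", "n"] == pytest.approx(50.0)
        assert t.loc["agree_ai", "n"] == pytest.approx(261 / 7)
        assert t.loc["agree_ai", "percent"] == pytest.approx(100 * 261 / 350)
        assert t.loc["agree_ai/correct", "percent"] == pytest.approx(100 * 216 / 261)

    def test_average_of_identical_summaries_is_identity(self, small_study):
        _, s = intra_reader_changes(small_study, "R1", "image")
        t = change_table([s, s]).set_index("row")
        assert t.loc["overall", "n"] == s.overall["n"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            change_table([])


class TestStatusAccuracy:
    def test_two_of_four_match(self):
        anns = []
        statuses_gt = ["acute", "acute", "healing", "healing"]
        statuses_rd = ["acute", "healing", "acute", "healing"]  # 2 match
        for k, (sg, sr) in enumerate(zip(statuses_gt, statuses_rd)):
            iid = f"i{k}"
            anns.append(gt_ann(iid, bb(0, 0, 10, 10), sg))
            anns.append(reader_ann(iid, bb(0, 0, 10, 10), "R1", "r1", sr))
        ds = build_study({"e1": [f"i{k}" for k in range(4)]}, anns)
        acc, n_correct, n_tp = status_accuracy(ds, "r1")
        assert (acc, n_correct, n_tp) == (0.5, 2, 4)

    def test_all_match_gives_one(self, small_study):
        # noiseless readers would score 1.0; here just check range and pooling
        acc, n_correct, n_tp = status_accuracy(small_study, "r1")
        assert 0.0 <= acc <= 1.0
        assert n_correct <= n_tp

    def test_ai_has_no_status_labels(self, small_study):
        with pytest.raises(ValueError, match="no acute/healing"):
            status_accuracy(small_study, "r1", source="ai")

    def test_recovers_configured_flip_probability(self):
        from mrmcbe import SimulationConfig, generate_study
        from mrmcbe.simulate import ReaderProfile
        from scipy.stats import beta

        q = 0.25
        cfg = SimulationConfig(n_examinations=80, n_patients=40)
        reader = ReaderProfile(reader_id="R1", p_detect=1.0, fp_rate_per_image=0.0,
                               localization_jitter=0.0, p_status_error=q)
        ds = generate_study(cfg, [reader], seed=3)
        acc, n_correct, n_tp = status_accuracy(ds, "r1", reader_id="R1")
        lo = beta.ppf(0.025, n_correct, n_tp - n_correct + 1)
        hi = beta.ppf(0.975, n_correct + 1, n_tp - n_correct)
        assert lo <= 1 - q <= hi
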