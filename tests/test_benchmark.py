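import random

import numpy as np
import pytest

from wgdbench.benchmark import (
    ConfusionTotals,
    classify_pillar,
    evaluate,
    match_groups,
    metrics,
    parameter_sweep,
    score_confusion,
    split_pillars,
    stratified_eval,
)
from wgdbench.model import GoldPillar

from conftest import make_group


def pillar(pid="P1", pre=("k1", "l1", "m1"), a=(), b=(), **kw):
    """Pre-WGD species k,l,m; post-WGD species s,t,u. Track entries are
    (species, gene) pairs or bare gene names ('s1a' -> species 's')."""
    def slot(entries):
        out = {}
        for e in entries:
            sp, gene = (e[0], e) if isinstance(e, str) else e
            out[sp] = gene
        return out

    p = GoldPillar(
        pid,
        pre_genes={g[0]: g for g in pre},
        track_a=slot(a),
        track_b=slot(b),
        **kw,
    )
    p.loss_class = classify_pillar(p)
    return p


class TestClassifyPillar:
    def test_no_losses_is_class_0(self):
        p = pillar(a=("s1a", "t1a", "u1a"), b=("s1b", "t1b", "u1b"))
        assert p.loss_class == "0"

    def test_one_and_two_losses(self):
        assert pillar(a=("s1a", "t1a", "u1a"), b=("s1b", "t1b")).loss_class == "I"
        assert pillar(a=("s1a", "t1a"), b=("s1b", "t1b")).loss_class == "II"

    def test_one_empty_track_is_class_IV(self):
        p = pillar(a=("s1a", "t1a", "u1a"), b=())
        assert p.loss_class == "IV"

    def test_cross_track_retention_is_class_III(self):
        # the trap: three retained post-WGD genes spanning both tracks
        p = pillar(a=("s1a",), b=("t1b", "u1b"))
        assert p.loss_class == "III"

    def test_four_or_more_losses_unclassified(self):
        assert pillar(a=("s1a",), b=("t1b",)).loss_class == "unclassified"
        assert pillar(a=("s1a",), b=()).loss_class == "unclassified"
        assert pillar(a=(), b=()).loss_class == "unclassified"


class TestSplitPillars:
    def test_minimal_pillar_splits_into_two_pairs(self):
        p = pillar(pre=("k1",), a=("s1a",), b=("s1b",))
        sga, sgb = split_pillars([p])
        assert sga.members == frozenset({"k1", "s1a"})
        assert sgb.members == frozenset({"k1", "s1b"})
        assert sga.members & sgb.members == {"k1"}

    def test_empty_track_subgroup_keeps_pre_genes(self):
        p = pillar(a=("s1a", "t1a", "u1a"), b=())
        sga, sgb = split_pillars([p])
        assert sgb.members == frozenset({"k1", "l1", "m1"})
        assert len(sga.members) == 6

    def test_full_pillar_gives_two_groups_of_six(self):
        p = pillar(a=("s1a", "t1a", "u1a"), b=("s1b", "t1b", "u1b"))
        sga, sgb = split_pillars([p])
        assert len(sga.members) == len(sgb.members) == 6

    def test_gene_on_both_tracks_is_error(self):
        p = pillar(a=("s1a",), b=())
        p.track_b = {"t": "s1a"}
        with pytest.raises(ValueError, match="both tracks"):
            split_pillars([p])

    def test_duplicate_pillar_id_is_error(self):
        with pytest.raises(ValueError, match="P1"):
            split_pillars([pillar(), pillar()])


class TestMatchGroups:
    def test_matches_best_subgroup(self):
        p = pillar(pre=("k1",), a=("s1a",), b=("s1b",))
        sgs = split_pillars([p])
        (m,) = match_groups([make_group("k1", "s1a", "x9")], sgs)
        assert m.subgroup_id == "P1:A"
        assert m.shared == 2
        assert m.status == "defined"

    def test_single_shared_gene_is_undefined(self):
        p = pillar(pre=("k1",), a=("s1a",), b=("s1b",))
        sgs = split_pillars([p])
        (m,) = match_groups([make_group("k1", "x1", "x2")], sgs)
        assert m.status == "undefined"
        assert m.subgroup_id is None

    def test_tie_between_pillars_is_deterministic(self):
        p1 = pillar("P1", pre=("k1",), a=("s1a",), b=())
        p2 = pillar("P2", pre=("k2",), a=("s2a",), b=())
        sgs = split_pillars([p1, p2])
        group = make_group("k1", "s1a", "k2", "s2a")
        first = match_groups([group], sgs)
        second = match_groups([group], sgs)
        assert first == second
        assert first[0].subgroup_id == "P1:A"  # ties fall to the smaller id


class TestScoreConfusion:
    def _small(self):
        p = pillar(pre=("k1", "l1"), a=("s1a", "t1a"), b=("s1b",))
        return p, split_pillars([p])

    def test_perfect_prediction(self):
        p, sgs = self._small()
        # both subgroups predicted exactly -> FP=0, FN=0
        test = [
            make_group("k1", "l1", "s1a", "t1a"),
            make_group("k1", "l1", "s1b", group_id="g2"),
        ]
        matches = match_groups(test, sgs)
        c = score_confusion(matches, test, sgs, n_total_genes=50)
        assert c.fp == 0 and c.fn == 0
        assert c.t_tp == c.tp

    def test_extrapolation_arithmetic(self):
        c = ConfusionTotals.from_counts(
            tp=80, fp=10, fn=5, n_defined_genes=100, n_undefined_genes=50,
            n_total_genes=1000,
        )
        assert c.tp_x == pytest.approx(40.0)
        assert c.fp_x == pytest.approx(5.0)
        assert c.t_tp == pytest.approx(120.0)
        assert c.t_tn == pytest.approx(1000 - 120 - 15 - 7.5)

    def test_all_defined_means_no_extrapolation(self):
        p, sgs = self._small()
        test = [make_group("k1", "l1", "s1a", "t1a")]
        matches = match_groups(test, sgs)
        c = score_confusion(matches, test, sgs, n_total_genes=20)
        assert c.n_undefined_genes == 0
        assert c.tp_x == c.fp_x == c.fn_x == 0

    def test_undefined_without_defined_is_error(self):
        with pytest.raises(ValueError, match="extrapolation"):
            ConfusionTotals.from_counts(0, 0, 0, 0, 10, 100)

    def test_gold_gene_in_another_group_is_not_fn(self):
        # s1b missing from its matched group but present elsewhere: FP there,
        # never FN
        p, sgs = self._small()
        test = [
            make_group("k1", "l1", "s1a", "t1a"),
            make_group("k9", "l9", "s1b", group_id="g9"),
        ]
        matches = match_groups(test, sgs)
        c = score_confusion(matches, test, sgs, n_total_genes=20)
        assert c.fn == 0


class TestMetrics:
    def test_worked_example(self):
        c = ConfusionTotals(8, 2, 2, 0, 0, 0, 8, 2, 2, 88, 10, 0, 100)
        m = metrics(c)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(88 / 90)
        assert m.accuracy == pytest.approx(0.96)
        assert m.fdr == pytest.approx(0.2)

    def test_zero_fp_gives_zero_fdr(self):
        c = ConfusionTotals(5, 0, 1, 0, 0, 0, 5, 0, 1, 94, 6, 0, 100)
        assert metrics(c).fdr == 0.0

    def test_zero_fn_gives_full_sensitivity(self):
        c = ConfusionTotals(5, 1, 0, 0, 0, 0, 5, 1, 0, 94, 6, 0, 100)
        assert metrics(c).sensitivity == 1.0

    def test_all_zero_totals_are_undefined(self):
        c = ConfusionTotals(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
        m = metrics(c)
        assert m.sensitivity is None and m.accuracy is None

    def test_random_totals_satisfy_identities(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            tp, fp, fn = rng.integers(0, 200, size=3)
            nd = int(rng.integers(1, 500))
            nu = int(rng.integers(0, 500))
            total = int(tp + fp + fn) * (nd + nu) // nd + int(rng.integers(1, 1000))
            c = ConfusionTotals.from_counts(int(tp), int(fp), int(fn), nd, nu, total)
            m = metrics(c)
            # the tTN identity holds exactly as written
            assert c.t_tn == total - c.t_tp - c.t_fp - c.t_fn
            assert m.fdr is None or 0 <= m.fdr <= 1
            if c.t_tp + c.t_fp > 0:
                precision = c.t_tp / (c.t_tp + c.t_fp)
                assert m.fdr == pytest.approx(1 - precision)


class TestStratifiedEval:
    def _trap_setup(self):
        # Fig-1B-style trap: one class-III pillar predicted as a single
        # mixed-track group
        p3 = pillar("P1", a=("s1a",), b=("t1b", "u1b"))
        p4 = pillar("P2", pre=("k2", "l2", "m2"), a=("s2a", "t2a", "u2a"), b=())
        test = [
            make_group("k1", "l1", "m1", "s1a", "t1b", "u1b"),
            make_group("k2", "l2", "m2", "s2a", "t2a", "u2a"),
        ]
        return [p3, p4], test

    def test_class_III_trap_counted_by_hand(self):
        pillars, test = self._trap_setup()
        strata = stratified_eval(test, pillars, n_total_genes=50)
        c3, m3 = strata["III"]
        # best subgroup is P1:B (5 shared); the stray track-A gene is an FP
        assert (c3.tp, c3.fp, c3.fn) == (5, 1, 0)
        assert m3.fdr == pytest.approx(1 / 6)
        c4, m4 = strata["IV"]
        assert (c4.fp, c4.fn) == (0, 0)
        assert m4.fdr == 0.0

    def test_single_class_restriction_is_identity(self):
        pillars, test = self._trap_setup()
        only_iv = [p for p in pillars if p.loss_class == "IV"]
        global_eval = evaluate(test, only_iv, 50)
        strata = stratified_eval(test, only_iv, 50)
        assert strata == {"IV": global_eval}

    def test_union_of_all_classes_reproduces_global(self):
        pillars, test = self._trap_setup()
        for p in pillars:
            p.loss_class = "IV"  # one pseudo-stratum holding every pillar
        with pytest.raises(ValueError):
            stratified_eval(test, pillars, 50)  # stored tag must match pattern
        for p in pillars:
            p.loss_class = classify_pillar(p)
        merged = evaluate(test, pillars, 50)
        assert merged[0].tp == sum(
            c.tp for c, _ in stratified_eval(test, pillars, 50).values()
        )

    def test_missing_class_absent(self):
        pillars, test = self._trap_setup()
        strata = stratified_eval(test, pillars, 50, classes=["0"])
        assert strata == {}

    def test_invariant_to_group_order(self):
        pillars, test = self._trap_setup()
        forward = evaluate(test, pillars, 50)
        backward = evaluate(list(reversed(test)), pillars, 50)
        assert forward == backward


class TestParameterSweep:
    def test_rows_and_roc(self):
        pillars = [pillar(pre=("k1",), a=("s1a",), b=("s1b",))]
        groups = [make_group("k1", "s1a")]

        frame = parameter_sweep([None, 0.5, 0.9], lambda v: groups, pillars, 10)
        assert len(frame) == 3
        assert list(frame["param"]) == ["unset", 0.5, 0.9]
        assert "one_minus_specificity" in frame.columns

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            parameter_sweep([], lambda v: [], [], 10)
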