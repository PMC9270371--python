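"""Experimentally validated FDR, FDR-score curves and post-score cutoffs."""

import logging
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from conftest import record
from oracles import brute_curve, brute_cutoff, brute_fdr
from xlfdr.results import group_to_unique_links
from xlfdr.validation import (
    apply_score_cutoff,
    fdr_score_curve,
    format_percent,
    validated_fdr,
)


def make_records(pairs, scores=None, lib=None):
    scores = scores if scores is not None else [100.0] * len(pairs)
    return [record(a, b, score=s, lib=lib) for (a, b), s in zip(pairs, scores)]


class TestValidatedFdr:
    def test_replicate_worked_example_425_links_2_cross_group(self, small_library):
        """425 unique links with 2 cross-group hits: FDR 0.47 %, shown 0.5 %."""
        pairs = [("MAKTIK", "LSYDTEASIAKAK")] * 423 \
            + [("LSYDTEASIAKAK", "VAVIKAVR")] * 2
        vr = validated_fdr(make_records(pairs), small_library)
        assert vr.n_total == 425
        assert vr.n_cross_group == 2
        assert vr.fdr == pytest.approx(2 / 425)
        assert round(100 * vr.fdr, 2) == 0.47
        assert vr.fdr_display == "0.5 %"

    def test_all_within_group_gives_zero(self, small_library):
        vr = validated_fdr(make_records([("GAKWR", "APKTLR")] * 100),
                           small_library)
        assert vr.fdr == 0.0

    def test_both_false_categories_counted_and_reported_separately(
            self, small_library):
        pairs = [("MAKTIK", "MAKTIK"), ("MAKTIK", "GAKWR"), ("MAKLTK", "MAKLTK")]
        vr = validated_fdr(make_records(pairs), small_library)
        assert (vr.n_within_group, vr.n_cross_group, vr.n_non_library) == (1, 1, 1)
        assert vr.fdr == pytest.approx(2 / 3)

    def test_empty_input_is_zero_with_warning(self, small_library, caplog):
        with caplog.at_level(logging.WARNING):
            vr = validated_fdr([], small_library)
        assert vr.n_total == 0 and vr.fdr == 0.0
        assert any("empty" in m for m in caplog.messages)

    def test_per_class_counts_sum_to_totals(self, small_library):
        pairs = [("MAKTIK", "MAKTIK"), ("VAVIKAVR", "GAKWR"),
                 ("MAKTIK", "GAKWR"), ("MAKLTK", "GAKWR")]
        vr = validated_fdr(make_records(pairs), small_library)
        total = sum(sum(d.values()) for d in vr.per_class.values())
        assert total == vr.n_total

    def test_adding_cross_group_raises_adding_true_lowers(self, small_library):
        base = make_records([("MAKTIK", "MAKTIK")] * 5 + [("MAKTIK", "GAKWR")])
        fdr0 = validated_fdr(base, small_library).fdr
        worse = validated_fdr(base + make_records([("MAKTIK", "GAKWR")]),
                              small_library).fdr
        better = validated_fdr(base + make_records([("MAKTIK", "MAKTIK")]),
                               small_library).fdr
        assert worse > fdr0 > better

    @settings(max_examples=200, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(st.lists(st.tuples(st.sampled_from(
        ["MAKTIK", "LSYDTEASIAKAK", "VAVIKAVR", "GAKWR", "APKTLR", "FAKE"]),
        st.sampled_from(
        ["MAKTIK", "LSYDTEASIAKAK", "VAVIKAVR", "GAKWR", "APKTLR", "FAKE"])),
        max_size=40))
    def test_matches_brute_force_recount(self, small_library, groups_of, pairs):
        vr = validated_fdr(make_records(pairs), small_library)
        assert vr.fdr == pytest.approx(brute_fdr(pairs, groups_of))
        assert 0.0 <= vr.fdr <= 1.0

    def test_csm_and_link_level_agree_at_one_csm_per_link(self, small_library):
        pairs = [("MAKTIK", "LSYDTEASIAKAK"), ("MAKTIK", "GAKWR"),
                 ("GAKWR", "APKTLR")]
        csms = make_records(pairs, scores=[1, 2, 3], lib=small_library)
        links = group_to_unique_links(csms)
        assert validated_fdr(csms, small_library, "csm").fdr \
            == validated_fdr(links, small_library, "unique_link").fdr


class TestFdrScoreCurve:
    def test_all_true_curve_is_flat_zero(self, small_library):
        recs = make_records([("MAKTIK", "MAKTIK")] * 3, scores=[3, 2, 1])
        curve = fdr_score_curve(recs, small_library)
        assert [p[0] for p in curve] == [3, 2, 1]
        assert all(p[2] == 0.0 for p in curve)

    def test_single_record_single_point(self, small_library):
        curve = fdr_score_curve(make_records([("GAKWR", "GAKWR")]), small_library)
        assert len(curve) == 1 and curve[0][1] == 1

    def test_retained_counts_non_decreasing(self, small_library):
        rng = np.random.default_rng(3)
        pairs = [("MAKTIK", "MAKTIK")] * 20 + [("MAKTIK", "GAKWR")] * 5
        recs = make_records(pairs, scores=rng.normal(size=25).tolist())
        curve = fdr_score_curve(recs, small_library)
        counts = [p[1] for p in curve]
        assert counts == sorted(counts)

    def test_matches_brute_force_sweep(self, small_library, groups_of):
        rng = np.random.default_rng(9)
        seqs = list(groups_of) + ["FAKE"]
        triples = [(float(rng.integers(0, 6)), str(rng.choice(seqs)),
                    str(rng.choice(seqs))) for _ in range(60)]
        recs = [record(a, b, score=s) for s, a, b in triples]
        got = fdr_score_curve(recs, small_library)
        assert got == brute_curve(triples, groups_of)


class TestApplyScoreCutoff:
    def test_worked_cutoff_example(self, small_library):
        recs = make_records(
            [("MAKTIK", "MAKTIK")] * 3 + [("MAKTIK", "GAKWR")],
            scores=[10, 9, 8, 7])
        cut = apply_score_cutoff(recs, small_library, target_fdr=0.01)
        assert cut.threshold == 8
        assert cut.n_retained == 3
        assert cut.achieved_fdr == 0.0

    def test_already_compliant_set_keeps_everything(self, small_library):
        recs = make_records([("MAKTIK", "MAKTIK")] * 4, scores=[4, 3, 2, 1])
        cut = apply_score_cutoff(recs, small_library, 0.05)
        assert cut.threshold == 1 and cut.n_retained == 4

    def test_all_false_returns_empty(self, small_library):
        recs = make_records([("MAKTIK", "GAKWR")] * 3, scores=[3, 2, 1])
        cut = apply_score_cutoff(recs, small_library, 0.01)
        assert not cut.feasible and cut.retained == []

    def test_invalid_target_rejected(self, small_library):
        with pytest.raises(ValueError):
            apply_score_cutoff([], small_library, 0.0)

    def test_ties_at_threshold_are_retained(self, small_library):
        recs = make_records([("MAKTIK", "MAKTIK")] * 3, scores=[5, 5, 5])
        cut = apply_score_cutoff(recs, small_library, 0.5)
        assert cut.n_retained == 3

    @pytest.mark.parametrize("seed", range(20))
    def test_optimality_against_exhaustive_sweep(self, small_library,
                                                 groups_of, seed):
        """No less strict threshold meets the target (brute-force sweep)."""
        rng = np.random.default_rng(seed)
        seqs = list(groups_of) + ["FAKE"]
        triples = [(float(rng.integers(0, 10)), str(rng.choice(seqs)),
                    str(rng.choice(seqs))) for _ in range(rng.integers(1, 80))]
        recs = [record(a, b, score=s) for s, a, b in triples]
        target = float(rng.choice([0.01, 0.05, 0.2, 0.5]))
        cut = apply_score_cutoff(recs, small_library, target)
        t_ref, n_ref, fdr_ref = brute_cutoff(triples, groups_of, target)
        if t_ref is None:
            assert not cut.feasible
        else:
            assert cut.threshold == t_ref
            assert cut.n_retained == n_ref
            assert cut.achieved_fdr == pytest.approx(fdr_ref)
            assert cut.achieved_fdr <= target

    def test_retained_monotone_in_target(self, small_library, groups_of):
        rng = np.random.default_rng(17)
        seqs = list(groups_of) + ["FAKE"]
        recs = [record(str(rng.choice(seqs)), str(rng.choice(seqs)),
                       score=float(rng.integers(0, 20))) for _ in range(120)]
        targets = [0.5, 0.2, 0.1, 0.05, 0.02, 0.01]
        counts = [apply_score_cutoff(recs, small_library, t).n_retained
                  for t in targets]
        assert counts == sorted(counts, reverse=True)


@pytest.mark.parametrize("fraction, display", [
    (2 / 425, "0.5 %"),     # 0.4706 rounds half-up to 0.5
    (0.0045, "0.5 %"),      # exact half rounds up, not to even
    (0.0, "0.0 %"),
    (1.0, "100.0 %"),
    (0.014, "1.4 %"),
])
def test_percent_display_rounds_half_up(fraction, display):
    assert format_percent(fraction) == display
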