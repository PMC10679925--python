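"""Filtering cascade: stage rules, boundaries, vote mapping, invariants."""

from __future__ import annotations

from dataclasses import replace

import pytest

import triovar as tv
from triovar.filters import (
    deleteriousness_vote,
    frequency_filter,
    region_filter,
    repeat_indel_filter,
    run_cascade,
    site_qc,
    synonymous_filter,
)
from conftest import make_variant
from oracles import straight_line_pass


class TestSiteQC:
    @pytest.mark.parametrize(
        "depth, mq, qual, expected, reason",
        [
            (4, 31, 21, False, "low_depth"),  # strict > boundary
            (5, 31, 21, True, "ok"),
            (30, 30, 50, False, "low_mq"),  # strict > boundary
            (30, 31, 20, False, "low_qual"),  # strict > boundary
            (30, 60, 60, True, "ok"),
        ],
    )
    def test_strict_thresholds(self, thresholds, depth, mq, qual, expected, reason):
        v = make_variant(qual=qual, mq=mq, genotypes={"KID": 1})
        v.genotypes["KID"].depth = depth
        d = site_qc(v, "KID", thresholds)
        assert (d.passed, d.reason) == (expected, reason)

    def test_missing_depth_fails_with_reason(self, thresholds):
        v = make_variant()
        v.genotypes["KID"].depth = None
        d = site_qc(v, "KID", thresholds)
        assert not d.passed and d.reason == "missing_dp"


class TestRegion:
    @pytest.mark.parametrize(
        "func_class, dist, expected",
        [
            ("exonic", None, True),
            ("splicing", 1, True),  # canonical +1 donor site
            ("splicing", 10, True),  # +10 duplication: inclusive boundary
            ("splicing", 11, False),
            ("splicing", 28, False),
            ("other", None, False),
        ],
    )
    def test_window(self, thresholds, func_class, dist, expected):
        v = make_variant(
            func_class=func_class,
            exonic_func="unknown" if func_class != "exonic" else "missense",
            splice_distance=dist,
        )
        assert region_filter(v, thresholds).passed is expected


class TestSynonymous:
    @pytest.mark.parametrize(
        "exonic_func, dbscsnv, expected",
        [
            ("synonymous", None, False),
            ("synonymous", (0.95, 0.2), True),  # splice-impacting rescue
            ("synonymous", (0.1, 0.2), False),
            ("missense", None, True),  # stage not applicable
        ],
    )
    def test_rescue_rule(self, thresholds, exonic_func, dbscsnv, expected):
        v = make_variant(exonic_func=exonic_func, dbscsnv_scores=dbscsnv)
        assert synonymous_filter(v, thresholds).passed is expected


class TestRepeatIndel:
    @pytest.mark.parametrize(
        "ref, in_repeat, expected",
        [
            ("ATTT", True, False),  # 3-bp in-frame deletion in repeat
            ("ATTT", False, True),
            ("ATTTT", True, True),  # 4-bp frameshift: rule not scoped
            ("A" + "T" * 12, True, True),  # >= 10 bp: kept even in repeat
        ],
    )
    def test_scoped_to_small_inframe(self, thresholds, ref, in_repeat, expected):
        v = make_variant(ref=ref, alt="A", exonic_func="nonframeshift",
                         in_repeat=in_repeat)
        assert repeat_indel_filter(v, thresholds).passed is expected


class TestFrequency:
    @pytest.mark.parametrize(
        "afs, expected",
        [
            ({"1000g_all": None, "gnomAD_all": None}, True),  # ABSENT = rare
            ({"1000g_all": 0.0071885, "gnomAD_all": 0.00199517}, True),
            ({"1000g_all": 0.01}, False),  # strict < boundary
            ({"1000g_all": 0.0, "gnomAD_all": None}, True),
            ({"1000g_all": 0.2}, False),
        ],
    )
    def test_every_database_must_be_rare(self, thresholds, afs, expected):
        v = make_variant(af_fields=afs)
        assert frequency_filter(v, thresholds).passed is expected


class TestDeleteriousnessVote:
    @pytest.mark.parametrize(
        "sift, hvar, hdiv, mt, cadd, n_expected, passed",
        [
            ("D", "D", "D", "D", 31.0, 4, True),
            ("T", "B", "B", "N", 5.0, 0, False),
            # SIFT yes, PolyPhen yes (P), MutationTaster no (N), CADD yes
            ("D", "P", "P", "N", 23.0, 3, True),
            # either PolyPhen sub-score supports the merged vote
            ("T", "B", "P", "D", 5.0, 2, False),
            ("T", "B", "B", "A", 25.0, 2, False),  # MT "A" supports
            ("D", "B", "B", "D", 12.19, 2, False),
            (None, "D", "D", "D", None, 2, False),  # absent = non-supporting
        ],
    )
    def test_vote_mapping(self, thresholds, sift, hvar, hdiv, mt, cadd,
                          n_expected, passed):
        pv = tv.PredictorVerdict(
            sift=sift, polyphen_hvar=hvar, polyphen_hdiv=hdiv, mutation_taster=mt
        )
        d = deleteriousness_vote(pv, cadd, thresholds)
        assert d.observed["supporting"] == n_expected
        assert d.passed is passed

    def test_all_absent_without_lof_is_no_predictions(self, thresholds):
        d = deleteriousness_vote(tv.PredictorVerdict(), None, thresholds)
        assert not d.passed and d.reason == "no_predictions"

    def test_lof_bypass_for_unscored_null_variants(self, thresholds):
        d = deleteriousness_vote(
            tv.PredictorVerdict(), None, thresholds, lof_bypass=True
        )
        assert d.passed and d.reason == "lof_bypass"


class TestCascade:
    def test_common_synonymous_short_circuits(self, thresholds):
        v = make_variant(
            exonic_func="synonymous",
            af_fields={"1000g_all": 0.3},
            predictor_verdicts=tv.PredictorVerdict(),
            cadd=None,
        )
        trace = run_cascade(v, "KID", thresholds)
        assert not trace.passed
        assert trace.failing_stage == "synonymous"
        # later stages were never evaluated
        assert [d.stage for d in trace.decisions] == [
            "site_qc", "region", "synonymous",
        ]

    def test_final_status_is_conjunction_of_stages(self, study_cohort, thresholds):
        """Short-circuiting changes traces, never outcomes."""
        from triovar.filters import _deleteriousness_stage

        proband = study_cohort.pedigree.affected[0].sample_id
        for v in study_cohort.records[:400]:
            independent = all(
                d.passed
                for d in (
                    site_qc(v, proband, thresholds),
                    region_filter(v, thresholds),
                    synonymous_filter(v, thresholds),
                    repeat_indel_filter(v, thresholds),
                    frequency_filter(v, thresholds),
                    _deleteriousness_stage(v, thresholds),
                )
            )
            assert run_cascade(v, proband, thresholds).passed == independent

    def test_oracle_equivalence_on_synthetic_variants(self, thresholds):
        """Cascade output equals an independent straight-line re-evaluation
        of the rules on 1,000 synthetic variants."""
        sim = tv.simulate_cohort(tv.CohortConfig(n_sites=1000), seed=42)
        samples = [s.sample_id for s in sim.pedigree.affected]
        checked = disagreements = 0
        for v in sim.records:
            sample = samples[checked % len(samples)]
            expected = straight_line_pass(v, sample, thresholds)
            got = run_cascade(v, sample, thresholds).passed
            disagreements += expected != got
            checked += 1
        assert checked >= 1000
        assert disagreements == 0

    def test_monotonicity_under_threshold_tightening(self, thresholds):
        """Lowering max_af or raising the CADD cutoff never adds passers."""
        sim = tv.simulate_cohort(tv.CohortConfig(n_sites=800), seed=9)
        proband = sim.pedigree.affected[0].sample_id
        base = {
            v.key for v in sim.records if run_cascade(v, proband, thresholds).passed
        }
        tighter_af = replace(thresholds, max_af=0.001)
        tighter_cadd = replace(thresholds, cadd_deleterious_cutoff=30.0)
        for tight in (tighter_af, tighter_cadd):
            passing = {
                v.key for v in sim.records if run_cascade(v, proband, tight).passed
            }
            assert passing <= base


class TestPublishedLociSurvive:
    def test_all_published_candidate_loci_pass_under_defaults(
        self, fixture_candidates
    ):
        """Every locus of the published candidate table survives the
        shipped cascade (retention mode; see methods note)."""
        failures = []
        for cand, v in tv.fixture_variant_records(fixture_candidates):
            trace = run_cascade(v, cand.patient)
            if not trace.passed:
                failures.append((cand.gene, cand.change, trace.failing_stage))
        assert failures == []

    def test_majority_vote_is_still_recorded_for_minority_rows(
        self, fixture_candidates, thresholds
    ):
        """Retention is weaker than the majority vote: rows kept with
        minority support must carry majority=False in the trace."""
        by_change = {c.change: c for c in fixture_candidates}
        weak = by_change["p.F388L"]  # T|B|B|D with CADD 11.9: one vote
        (_, v), = tv.fixture_variant_records([weak])
        trace = run_cascade(v, weak.patient, thresholds)
        d = trace.decision("deleteriousness")
        assert trace.passed
        assert d.reason == "retained_minority_support"
        assert d.observed["majority"] is False
        assert d.observed["supporting"] == 1
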