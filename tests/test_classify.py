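"""ACMG-lite engine, panel intersection, enrichment, cohort summary."""

from __future__ import annotations

from itertools import product

import pytest

import triovar as tv
from triovar.classify import EVIDENCE_CODES, EvidenceProfile, combine_acmg
from oracles import exact_hypergeom_sf


def make_candidate(**kw):
    defaults = dict(
        patient="P1",
        family="F1",
        normal_name="-",
        inheritance=tv.InheritanceCall(
            model="inherited_het", proband="P1",
            variant_key=("1", 100, "A", "G"), gene="GENE1",
            carrier_parent="father",
        ),
        gene="GENE1",
        chrom="1",
        func_class="exonic",
        exonic_func="missense",
        zygosity="het",
        change="p.A1B",
        af_fields={"1000g_all": None, "gnomAD_all": None},
        predictor_verdicts=tv.PredictorVerdict(
            sift="D", polyphen_hvar="D", polyphen_hdiv="D", mutation_taster="D"
        ),
        cadd=30.0,
    )
    defaults.update(kw)
    return tv.CandidateRecord(**defaults)


class TestAssignEvidence:
    def test_de_novo_stopgain_absent_everywhere(self):
        c = make_candidate(
            exonic_func="stopgain",
            inheritance=tv.InheritanceCall(
                model="de_novo", proband="P1",
                variant_key=("3", 1, "C", "T"), gene="GATA2",
                carrier_parent="none",
            ),
            gene="GATA2",
            panel_tag="PID",
            predictor_verdicts=tv.PredictorVerdict(),
            cadd=None,
        )
        profile = tv.assign_evidence(c)
        assert profile.codes == ("PVS1", "PS2", "PM2")
        assert combine_acmg(profile) == ("Pathogenic", False)

    def test_canonical_splice_de_novo(self):
        c = make_candidate(
            func_class="splicing",
            exonic_func="unknown",
            splice_distance=1,
            inheritance=tv.InheritanceCall(
                model="de_novo", proband="P1",
                variant_key=("5", 1, "G", "A"), gene="PIK3R1",
                carrier_parent="none",
            ),
            gene="PIK3R1",
            panel_tag="PID",
            predictor_verdicts=tv.PredictorVerdict(),
            cadd=None,
        )
        profile = tv.assign_evidence(c)
        assert profile.codes == ("PVS1", "PS2", "PM2")

    def test_rare_missense_with_vote_is_pp3_only(self):
        c = make_candidate(
            af_fields={"1000g_all": 0.0002, "gnomAD_all": 0.0001},
            predictor_verdicts=tv.PredictorVerdict(
                sift="D", polyphen_hvar="P", polyphen_hdiv="P",
                mutation_taster="N",
            ),
            cadd=23.0,
        )
        profile = tv.assign_evidence(c)
        assert profile.codes == ("PP3",)
        assert combine_acmg(profile) == ("VUS", False)

    def test_de_novo_off_panel_gets_no_ps2(self):
        """Phenotype consistency gate: a de novo hit in a gene unrelated to
        the phenotype is not strong evidence."""
        c = make_candidate(
            inheritance=tv.InheritanceCall(
                model="de_novo", proband="P1",
                variant_key=("6", 1, "G", "A"), gene="MYB",
                carrier_parent="none",
            ),
            gene="MYB",
            panel_tag=None,
        )
        assert not tv.assign_evidence(c).PS2

    def test_x_linked_with_carrier_mother_fires_pp1(self):
        c = make_candidate(
            chrom="X",
            zygosity="hom",
            inheritance=tv.InheritanceCall(
                model="x_linked_recessive", proband="P1",
                variant_key=("X", 1, "A", "C"), gene="CD40LG",
                carrier_parent="mother",
            ),
            gene="CD40LG",
            phenotype_match=True,
        )
        profile = tv.assign_evidence(c)
        assert profile.PP1 and profile.PP2 and profile.PP3 and profile.PP4
        assert profile.PM2
        assert combine_acmg(profile) == ("Likely Pathogenic", False)

    def test_common_benign_missense(self):
        c = make_candidate(
            af_fields={"1000g_all": 0.12, "gnomAD_all": 0.2},
            predictor_verdicts=tv.PredictorVerdict(
                sift="T", polyphen_hvar="B", polyphen_hdiv="B",
                mutation_taster="N",
            ),
            cadd=3.0,
        )
        profile = tv.assign_evidence(c)
        assert profile.BA1 and profile.BS1 and profile.BP4
        assert combine_acmg(profile) == ("Benign", False)


class TestCombineAcmg:
    def test_full_evidence_space_executes(self):
        """All 2^11 profiles combine without error into a valid tier."""
        seen = set()
        for bits in product((False, True), repeat=len(EVIDENCE_CODES)):
            profile = EvidenceProfile(**dict(zip(EVIDENCE_CODES, bits)))
            cls, conflict = combine_acmg(profile)
            assert cls in tv.classify.ACMG_CLASSES
            assert isinstance(conflict, bool)
            seen.add(cls)
        assert seen == set(tv.classify.ACMG_CLASSES)

    @pytest.mark.parametrize(
        "codes, expected",
        [
            ((), "VUS"),
            (("PP3",), "VUS"),
            (("PVS1", "PS2", "PM2"), "Pathogenic"),
            (("PVS1", "PM2"), "Likely Pathogenic"),
            (("PS2", "PM2"), "Likely Pathogenic"),
            (("PM2", "PM3"), "VUS"),
            (("PM2", "PM3", "PP1", "PP3"), "Likely Pathogenic"),
            (("PM2", "PP1", "PP2", "PP3", "PP4"), "Likely Pathogenic"),
            (("PM2", "PP1", "PP2", "PP3"), "VUS"),  # 1 PM + 3 PP is not enough
            (("BA1",), "Benign"),
            (("BS1", "BP4"), "Likely Benign"),
        ],
    )
    def test_combination_table(self, codes, expected):
        profile = EvidenceProfile(**{c: True for c in codes})
        assert combine_acmg(profile)[0] == expected

    def test_conflicting_evidence_is_vus_with_flag(self):
        profile = EvidenceProfile(PVS1=True, PS2=True, BA1=True)
        assert combine_acmg(profile) == ("VUS", True)

    def test_pure_function(self):
        p = EvidenceProfile(PM2=True, PP3=True)
        assert combine_acmg(p) == combine_acmg(EvidenceProfile(PM2=True, PP3=True))


class TestPanelIntersection:
    def test_tags_and_off_panel_flag(self):
        panel = tv.load_default_panel()
        lrba = make_candidate(gene="LRBA")
        myb = make_candidate(gene="MYB")
        tv.intersect_panel([lrba, myb], panel)
        assert lrba.panel_tag == "CVID_OMIM"
        assert myb.panel_tag is None  # retained but flagged off-panel

    def test_empty_candidate_list(self):
        assert tv.intersect_panel([], tv.load_default_panel()) == []


class TestEnrichment:
    def test_matches_exact_combinatorial_oracle(self):
        """Hypergeometric tail equals exact rational combinatorics to 1e-12
        on small universes."""
        sets = {
            "all_in": frozenset(f"G{i}" for i in range(6)),
            "partial": frozenset(f"G{i}" for i in range(4, 12)),
            "disjoint": frozenset(f"H{i}" for i in range(5)),
        }
        query = [f"G{i}" for i in range(6)]
        for background in (20, 35, 50):
            results = tv.enrich(query, sets, background=background)
            for r in results:
                exact = float(
                    exact_hypergeom_sf(r.overlap, background, r.set_size,
                                       r.query_size)
                )
                assert r.p_value == pytest.approx(exact, abs=1e-12)

    def test_disjoint_set_reports_p_one(self):
        results = tv.enrich(["A", "B"], {"s": frozenset({"X", "Y"})}, 50)
        assert results[0].overlap == 0 and results[0].p_value == 1.0

    def test_query_equal_to_universe_is_degenerate(self):
        query = [f"G{i}" for i in range(10)]
        results = tv.enrich(query, {"s": frozenset(query[:4])}, background=10)
        assert results[0].p_value == pytest.approx(1.0)

    def test_bh_adjustment_matches_manual_oracle(self):
        sets = {
            f"s{i}": frozenset({f"G{j}" for j in range(i + 1)}) for i in range(5)
        }
        results = tv.enrich(["G0", "G1", "G2"], sets, background=40)
        ps = sorted(r.p_value for r in results)
        m = len(ps)
        manual = [p * m / (k + 1) for k, p in enumerate(ps)]
        for k in range(m - 2, -1, -1):
            manual[k] = min(manual[k], manual[k + 1])
        manual = [min(x, 1.0) for x in manual]
        assert [r.adjusted_p for r in sorted(results, key=lambda r: r.p_value)] == (
            pytest.approx(manual)
        )


class TestSummarize:
    def test_dedup_counts_on_toy_table(self, fixture_phenotypes):
        c1 = make_candidate(patient="S1", gene="LRBA", change="p.G359D")
        c2 = make_candidate(patient="S2", gene="LRBA", change="p.G359D")
        c3 = make_candidate(patient="S1", gene="CTLA4", change="p.P169A")
        summary = tv.summarize_cohort([c1, c2, c3], fixture_phenotypes)
        assert summary["n_rows"] == 3
        assert summary["n_loci"] == 2  # duplicate + loci = rows
        assert summary["n_genes"] == 2
        assert summary["recurrent_loci"]["LRBA p.G359D"]["n_patients"] == 2

    def test_empty_candidate_set_is_all_zero(self, fixture_phenotypes):
        summary = tv.summarize_cohort([], fixture_phenotypes)
        assert summary["n_loci"] == 0 and summary["n_genes"] == 0
        assert summary["patients_with_multiple_loci"] == 0
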