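from __future__ import annotations

import pytest

import triovar as tv


@pytest.fixture(scope="session")
def thresholds():
    return tv.FilterThresholds()


@pytest.fixture(scope="session")
def fixture_candidates():
    """Packaged published candidate table, classified under shipped defaults."""
    cands = tv.load_fixture_candidates()
    tv.classify_candidates(cands, panel=tv.load_default_panel())
    return cands


@pytest.fixture(scope="session")
def fixture_phenotypes():
    return tv.load_fixture_phenotypes()


@pytest.fixture(scope="session")
def study_cohort():
    """Seeded synthetic cohort at the study scale: 12 trios + 4 sporadic
    cases, 5,000 background sites, genotyping-error rate 0."""
    return tv.simulate_cohort(tv.CohortConfig(), seed=20_240_001)


@pytest.fixture(scope="session")
def study_screen(study_cohort):
    return tv.screen_cohort(study_cohort.records, study_cohort.pedigree)


@pytest.fixture()
def trio_pedigree():
    """One trio plus one unrelated sporadic case."""
    return tv.Pedigree(
        [
            tv.SampleInfo("DAD", "FAM1", None, None, "male", False),
            tv.SampleInfo("MOM", "FAM1", None, None, "female", False),
            tv.SampleInfo("KID", "FAM1", "DAD", "MOM", "male", True),
            tv.SampleInfo("CASE", "SP1", None, None, "female", True),
        ]
    )


def make_variant(
    chrom="1",
    pos=100,
    ref="A",
    alt="G",
    qual=60.0,
    mq=60.0,
    genotypes=None,
    **ann,
):
    """Terse VariantRecord builder for unit tests."""
    counts = genotypes or {"KID": 1}
    gt = {
        sid: tv.GenotypeCall(c, 30) if c is not None
        else tv.GenotypeCall(None, 30, missing=True)
        for sid, c in counts.items()
    }
    defaults = dict(
        gene="GENEX",
        func_class="exonic",
        exonic_func="missense",
        af_fields={"1000g_all": None, "gnomAD_all": None},
        predictor_verdicts=tv.PredictorVerdict(
            sift="D", polyphen_hvar="D", polyphen_hdiv="D", mutation_taster="D"
        ),
        cadd=30.0,
    )
    defaults.update(ann)
    return tv.VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        site_qual=qual,
        site_mq=mq,
        genotypes=gt,
        annotation=tv.AnnotationBundle(**defaults),
    )
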