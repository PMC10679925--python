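"""Synthetic trio/sporadic cohort generator with spiked causal variants.

Emulates the statistical structure the screening pipeline assumes: parental
genotypes at Hardy-Weinberg proportions from each site's true allele
frequency, offspring genotypes by Mendelian transmission (with an optional
genotyping-error rate), ANNOVAR-style annotations drawn from a latent
deleterious/benign predictor-concordance model, and database AFs that are
noisy copies of the true AF or ABSENT. Causal variants are spiked under
each inheritance model with annotations forced to survive the filter
cascade, and the ground truth is written alongside the VCF so recall can be
measured end to end.

Defaults mirror the study cohort: 12 trio families plus 4 sporadic
cases (16 patients, 26 healthy relatives... 24 parents here since only
parents are simulated), mean sequencing depth 34x, rarity-dominated AF
spectrum. Genes are synthetic labels (GENE0001...) mapped to coordinate
windows; background sites are autosomal, the X chromosome carries only
X-linked spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import (
    AnnotationBundle,
    GenotypeCall,
    IntervalEvent,
    Pedigree,
    PredictorVerdict,
    SampleInfo,
    VariantRecord,
    write_events,
    write_vcf,
)

SPIKE_MODELS = (
    "de_novo",
    "hom_recessive",
    "compound_het",
    "x_linked_recessive",
    "sporadic_only",
)

_SUPPORT_CODE = {
    "sift": ("D", "T"),
    "polyphen_hvar": ("D", "B"),
    "polyphen_hdiv": ("P", "B"),
    "mutation_taster": ("D", "N"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; the defaults are the study conditions."""

    n_trio_families: int = 12
    n_sporadic_cases: int = 4
    n_sites: int = 5000
    n_genes: int = 500
    af_log10_min: float = -6.0
    af_log10_max: float = np.log10(0.5)
    af_absent_fraction: float = 0.15
    p_deleterious: float = 0.10
    p_support_given_deleterious: float = 0.85
    p_support_given_benign: float = 0.05
    p_predictor_absent: float = 0.05
    genotyping_error_rate: float = 0.0
    mean_depth: float = 34.0
    fraction_synonymous: float = 0.25
    fraction_splicing: float = 0.08
    fraction_indel: float = 0.08
    fraction_repeat_given_indel: float = 0.40
    spikes: dict = field(
        default_factory=lambda: {
            "de_novo": 3,
            "hom_recessive": 2,
            "compound_het": 2,  # trans pairs (two sites each)
            "x_linked_recessive": 1,
            "sporadic_only": 2,
        }
    )

    def __post_init__(self) -> None:
        if self.n_trio_families < 0 or self.n_sporadic_cases < 0:
            raise ValueError("cohort sizes must be >= 0")
        for name in (
            "af_absent_fraction",
            "p_deleterious",
            "p_support_given_deleterious",
            "p_support_given_benign",
            "p_predictor_absent",
            "genotyping_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for model in self.spikes:
            if model not in SPIKE_MODELS:
                raise ValueError(f"unknown spike model {model!r}")


@dataclass(frozen=True)
class TruthRow:
    chrom: str
    pos: int
    ref: str
    alt: str
    model: str
    proband: str
    carrier_parent: str
    gene: str
    expected_pass: bool = True

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimulatedCohort:
    config: CohortConfig
    pedigree: Pedigree
    records: list[VariantRecord]
    truth: list[TruthRow]
    sample_order: list[str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "ped": outdir / "cohort.ped",
            "truth": outdir / "truth.tsv",
        }
        write_vcf(self.records, paths["vcf"], self.sample_order)
        write_ped(self.pedigree, paths["ped"])
        write_truth(self.truth, paths["truth"])
        return paths


def write_ped(pedigree: Pedigree, path: str | Path) -> None:
    lines = []
    for s in pedigree.samples:
        lines.append(
            "\t".join(
                [
                    s.family_id,
                    s.sample_id,
                    s.father_id or "0",
                    s.mother_id or "0",
                    "1" if s.sex == "male" else "2",
                    "2" if s.affected else "1",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth: list[TruthRow], path: str | Path) -> None:
    lines = ["chrom\tpos\tref\talt\tmodel\tproband\tcarrier_parent\tgene\texpected_pass"]
    for r in truth:
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.model}\t{r.proband}"
            f"\t{r.carrier_parent}\t{r.gene}\t{int(r.expected_pass)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# pedigree construction


def build_pedigree(cfg: CohortConfig, rng: np.random.Generator) -> Pedigree:
    """12 trios (one male + one female parent each; child sex Bernoulli(0.5),
    with the first trio forced male when an X-linked spike is requested)
    plus singleton sporadic cases."""
    samples: list[SampleInfo] = []
    force_male_child = cfg.spikes.get("x_linked_recessive", 0) > 0
    for i in range(1, cfg.n_trio_families + 1):
        fam = f"FAM{i:02d}"
        father, mother, child = f"{fam}_F", f"{fam}_M", f"{fam}_C"
        child_sex = (
            "male"
            if (i == 1 and force_male_child) or rng.random() < 0.5
            else "female"
        )
        samples.append(SampleInfo(father, fam, None, None, "male", False))
        samples.append(SampleInfo(mother, fam, None, None, "female", False))
        samples.append(SampleInfo(child, fam, father, mother, child_sex, True))
    for i in range(1, cfg.n_sporadic_cases + 1):
        sid = f"SP{i:02d}"
        sex = "male" if rng.random() < 0.5 else "female"
        samples.append(SampleInfo(sid, sid, None, None, sex, True))
    return Pedigree(samples)


# --------------------------------------------------------------------------
# background sites


def _draw_verdicts(
    rng: np.random.Generator, cfg: CohortConfig, deleterious: bool, missense: bool
) -> tuple[PredictorVerdict, Optional[float]]:
    if not missense:
        return PredictorVerdict(), None
    p = (
        cfg.p_support_given_deleterious
        if deleterious
        else cfg.p_support_given_benign
    )
    codes = {}
    for tool, (support, benign) in _SUPPORT_CODE.items():
        if rng.random() < cfg.p_predictor_absent:
            codes[tool] = None
        else:
            codes[tool] = support if rng.random() < p else benign
    cadd = round(
        max(float(rng.normal(28.0, 4.0) if deleterious else rng.normal(8.0, 4.0)), 0.0),
        2,
    )
    if rng.random() < cfg.p_predictor_absent:
        cadd = None
    return PredictorVerdict(**codes), cadd


def _draw_af_fields(
    rng: np.random.Generator, cfg: CohortConfig, true_af: float
) -> dict[str, Optional[float]]:
    out: dict[str, Optional[float]] = {}
    for db in ("1000g_all", "esp6500siv2_all", "gnomAD_all", "gnomAD_EAS"):
        if rng.random() < cfg.af_absent_fraction:
            out[db] = None
        else:
            noisy = min(max(true_af * float(rng.lognormal(0.0, 0.3)), 0.0), 1.0)
            out[db] = float(f"{noisy:.6g}")  # text-stable precision
    return out


def simulate_background(
    cfg: CohortConfig,
    pedigree: Pedigree,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Autosomal background sites with HWE parents and Mendelian children."""
    trios = [s for s in pedigree.samples if s.father_id and s.mother_id]
    singletons = [
        s for s in pedigree.samples if pedigree.is_singleton(s.sample_id)
    ]
    n_fam = len(trios)
    records: list[VariantRecord] = []
    sites_per_gene = max(1, -(-cfg.n_sites // cfg.n_genes))
    for i in range(cfg.n_sites):
        chrom = str(1 + (i % 22))
        pos = 1_000_000 + 150 * i
        gene = f"GENE{1 + i // sites_per_gene:04d}"
        af = 10.0 ** rng.uniform(cfg.af_log10_min, cfg.af_log10_max)

        fathers = rng.binomial(2, af, size=n_fam)
        mothers = rng.binomial(2, af, size=n_fam)
        paternal = rng.random(n_fam) < fathers / 2.0
        maternal = rng.random(n_fam) < mothers / 2.0
        children = paternal.astype(int) + maternal.astype(int)
        sporadic = rng.binomial(2, af, size=len(singletons))

        counts: dict[str, int] = {}
        for j, trio in enumerate(trios):
            fam_samples = pedigree.families[trio.family_id]
            father = next(s for s in fam_samples if s.sex == "male" and not s.affected)
            mother = next(
                s for s in fam_samples if s.sex == "female" and not s.affected
            )
            counts[father.sample_id] = int(fathers[j])
            counts[mother.sample_id] = int(mothers[j])
            counts[trio.sample_id] = int(children[j])
        for j, s in enumerate(singletons):
            counts[s.sample_id] = int(sporadic[j])

        if cfg.genotyping_error_rate > 0:
            for sid in counts:
                if rng.random() < cfg.genotyping_error_rate:
                    counts[sid] = int(rng.integers(0, 3))

        depths = rng.poisson(cfg.mean_depth, size=len(counts))
        genotypes = {
            sid: GenotypeCall(c, int(max(d, 1)))
            for (sid, c), d in zip(counts.items(), depths)
        }

        is_indel = rng.random() < cfg.fraction_indel
        u = rng.random()
        if u < cfg.fraction_splicing:
            func_class, exonic_func = "splicing", "unknown"
            splice_distance = int(rng.integers(1, 25))
        else:
            func_class, splice_distance = "exonic", None
            if is_indel:
                exonic_func = "nonframeshift" if rng.random() < 0.5 else "frameshift"
            elif u < cfg.fraction_splicing + cfg.fraction_synonymous:
                exonic_func = "synonymous"
            else:
                exonic_func = "missense"
        if is_indel:
            length = int(rng.integers(1, 13))
            if exonic_func == "nonframeshift":
                length = max(3, 3 * (length // 3))
            ref, alt = "A" + "T" * length, "A"
            in_repeat = rng.random() < cfg.fraction_repeat_given_indel
        else:
            ref, alt = "A", "G"
            in_repeat = False

        deleterious = rng.random() < cfg.p_deleterious
        verdicts, cadd = _draw_verdicts(
            rng, cfg, deleterious, exonic_func == "missense" and not is_indel
        )
        dbscsnv = None
        if exonic_func == "synonymous" and rng.random() < 0.05:
            dbscsnv = (round(float(rng.random()), 3), round(float(rng.random()), 3))

        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                # integer-valued: VCF QUAL and Float INFO are 32-bit in
                # htslib, so fractional values would not round-trip exactly
                site_qual=float(int(rng.normal(60.0, 15.0))),
                site_mq=float(int(rng.normal(55.0, 8.0))),
                genotypes=genotypes,
                annotation=AnnotationBundle(
                    gene=gene,
                    func_class=func_class,
                    exonic_func=exonic_func,
                    splice_distance=splice_distance,
                    dbscsnv_scores=dbscsnv,
                    in_repeat=in_repeat,
                    af_fields=_draw_af_fields(rng, cfg, af),
                    predictor_verdicts=verdicts,
                    cadd=cadd,
                    gerp=round(float(rng.normal(2.0, 2.0)), 2),
                ),
            )
        )
    return records


# --------------------------------------------------------------------------
# causal spikes


def _causal_annotation(gene: str) -> AnnotationBundle:
    """Annotations guaranteed to pass the cascade: exonic missense, absent
    from every database, unanimous deleterious vote, CADD 35."""
    return AnnotationBundle(
        gene=gene,
        func_class="exonic",
        exonic_func="missense",
        af_fields={
            "1000g_all": None,
            "esp6500siv2_all": None,
            "gnomAD_all": None,
            "gnomAD_EAS": None,
        },
        predictor_verdicts=PredictorVerdict(
            sift="D", polyphen_hvar="D", polyphen_hdiv="D", mutation_taster="D"
        ),
        cadd=35.0,
        gerp=5.5,
    )


def spike_causal(
    cfg: CohortConfig,
    pedigree: Pedigree,
    records: list[VariantRecord],
    rng: np.random.Generator,
) -> list[TruthRow]:
    """Append spiked causal variants per inheritance model; returns truth.

    Spiked sites live in dedicated genes (SPIKE...) on chromosome 21 (X for
    the X-linked model) at positions beyond the background windows; every
    non-carrier sample is hom-ref with full depth, so the spikes are also
    clean test material for the sporadic exclusivity rule.
    """
    trios = [
        s
        for s in pedigree.samples
        if s.father_id and s.mother_id and s.affected
    ]
    male_trios = [s for s in trios if s.sex == "male"]
    singletons = [s for s in pedigree.samples if pedigree.is_singleton(s.sample_id)]
    all_ids = [s.sample_id for s in pedigree.samples]

    needed = {m: int(cfg.spikes.get(m, 0)) for m in SPIKE_MODELS}
    if needed["x_linked_recessive"] > 0 and not male_trios:
        raise ValueError("X-linked spike requested but no male trio child")
    if (needed["de_novo"] or needed["hom_recessive"] or needed["compound_het"]) and not trios:
        raise ValueError("trio spikes requested but cohort has no trios")
    if needed["sporadic_only"] > 0 and not singletons:
        raise ValueError("sporadic spike requested but cohort has no singletons")

    truth: list[TruthRow] = []
    pos = 1_000_000 + 150 * cfg.n_sites + 10_000
    spike_idx = 0

    def base_genotypes() -> dict[str, GenotypeCall]:
        return {sid: GenotypeCall(0, 30) for sid in all_ids}

    def add_site(
        chrom: str, gene: str, carriers: dict[str, int], model: str,
        proband: str, carrier_parent: str,
    ) -> None:
        nonlocal pos, spike_idx
        spike_idx += 1
        genotypes = base_genotypes()
        for sid, count in carriers.items():
            genotypes[sid] = GenotypeCall(count, 30)
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref="C",
                alt="T",
                site_qual=80.0,
                site_mq=60.0,
                genotypes=genotypes,
                annotation=_causal_annotation(gene),
            )
        )
        truth.append(
            TruthRow("X" if chrom == "X" else chrom, pos, "C", "T", model,
                     proband, carrier_parent, gene)
        )
        pos += 500

    for k in range(needed["de_novo"]):
        child = trios[k % len(trios)]
        add_site(
            "21", f"SPIKEDN{k + 1:02d}", {child.sample_id: 1},
            "de_novo", child.sample_id, "none",
        )
    for k in range(needed["hom_recessive"]):
        child = trios[k % len(trios)]
        add_site(
            "21",
            f"SPIKEHR{k + 1:02d}",
            {child.sample_id: 2, child.father_id: 1, child.mother_id: 1},
            "hom_recessive",
            child.sample_id,
            "both",
        )
    for k in range(needed["compound_het"]):
        child = trios[k % len(trios)]
        gene = f"SPIKECH{k + 1:02d}"
        add_site(
            "21", gene, {child.sample_id: 1, child.father_id: 1},
            "compound_het", child.sample_id, "father",
        )
        add_site(
            "21", gene, {child.sample_id: 1, child.mother_id: 1},
            "compound_het", child.sample_id, "mother",
        )
    for k in range(needed["x_linked_recessive"]):
        child = male_trios[k % len(male_trios)]
        add_site(
            "X", f"SPIKEXL{k + 1:02d}",
            {child.sample_id: 1, child.mother_id: 1},
            "x_linked_recessive", child.sample_id, "mother",
        )
    for k in range(needed["sporadic_only"]):
        case = singletons[k % len(singletons)]
        add_site(
            "21", f"SPIKESP{k + 1:02d}", {case.sample_id: 1},
            "sporadic_only", case.sample_id, "none",
        )
    return truth


def simulate_cohort(cfg: CohortConfig, seed: int) -> SimulatedCohort:
    """Full deterministic cohort: background + spikes + pedigree."""
    rng = np.random.default_rng(seed)
    pedigree = build_pedigree(cfg, rng)
    records = simulate_background(cfg, pedigree, rng)
    truth = spike_causal(cfg, pedigree, records, rng)
    return SimulatedCohort(
        config=cfg,
        pedigree=pedigree,
        records=records,
        truth=truth,
        sample_order=[s.sample_id for s in pedigree.samples],
    )


# --------------------------------------------------------------------------
# CNV/SV event simulation


@dataclass(frozen=True)
class EventTruth:
    cluster_label: str
    chrom: str
    start: int
    end: int
    expected_kept: bool


def simulate_events(
    pedigree: Pedigree,
    rng: np.random.Generator,
    n_recurrent: int = 3,
    n_control_tainted: int = 2,
    n_private: int = 10,
    jitter_fraction: float = 0.08,
) -> tuple[list[IntervalEvent], list[EventTruth]]:
    """Planted CNV clusters plus decoys, with truth labels.

    ``n_recurrent`` clusters appear in >= 2 patients with jitter well below
    the 50% reciprocal-overlap bound (these must survive the screen);
    ``n_control_tainted`` clusters add an unaffected carrier (screened
    out); ``n_private`` events are single-patient decoys.
    """
    patients = [s.sample_id for s in pedigree.affected]
    controls = [s.sample_id for s in pedigree.unaffected]
    events: list[IntervalEvent] = []
    truth: list[EventTruth] = []

    def jittered(start: int, end: int) -> tuple[int, int]:
        length = end - start
        shift = int(rng.integers(-int(length * jitter_fraction),
                                 int(length * jitter_fraction) + 1))
        return start + shift, end + shift

    base = 5_000_000
    for k in range(n_recurrent):
        chrom = str(2 + k)
        start, end = base, base + 60_000
        carriers = [patients[(2 * k) % len(patients)],
                    patients[(2 * k + 1) % len(patients)]]
        for sid in carriers:
            s, e = jittered(start, end)
            events.append(IntervalEvent(sid, chrom, s, e, "DEL", "CNV"))
        truth.append(EventTruth(f"recurrent{k + 1}", chrom, start, end, True))
    for k in range(n_control_tainted):
        chrom = str(10 + k)
        start, end = base, base + 40_000
        carriers = [
            patients[k % len(patients)],
            patients[(k + 1) % len(patients)],
            controls[k % len(controls)],
        ]
        for sid in carriers:
            s, e = jittered(start, end)
            events.append(IntervalEvent(sid, chrom, s, e, "DUP", "CNV"))
        truth.append(EventTruth(f"tainted{k + 1}", chrom, start, end, False))
    for k in range(n_private):
        chrom = str(1 + (k % 22))
        start = 20_000_000 + 200_000 * k
        sid = patients[k % len(patients)]
        events.append(
            IntervalEvent(sid, chrom, start, start + 30_000, "DEL", "CNV")
        )
        truth.append(
            EventTruth(f"private{k + 1}", chrom, start, start + 30_000, False)
        )
    events.sort(key=lambda e: (e.chrom, e.start, e.end, e.sample_id))
    return events, truth
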