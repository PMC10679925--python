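"""Panel intersection, ACMG-lite classification, enrichment, cohort reports.

The ACMG engine implements a deliberately small evidence subset — PVS1,
PS2, PM2, PM3, PP1, PP2, PP3, PP4, BA1, BS1, BP4 — everything derivable
from the pipeline's own annotations and segregation calls. Codes needing
literature curation (PS1, PM5, PP5, ...) are out of scope. The combination
table is the standard five-tier one (Pathogenic / Likely Pathogenic / VUS /
Likely Benign / Benign); contradictory pathogenic + benign evidence yields
VUS with a conflict flag.

Evidence triggers:

* PVS1 — null variant: stopgain, frameshift, or canonical (+/-2) splice.
* PS2  — confirmed de novo in a gene consistent with the phenotype (on the
         PID/CVID panel, or the case carries a clinician-set
         phenotype-match flag).
* PM2  — absent from every configured population database.
* PM3  — in trans with another candidate in a recessive gene (phased
         compound het).
* PP1  — segregation consistent with a recessive/X-linked model through
         genotyped unaffected carrier parents.
* PP2  — missense in a configured missense-constrained gene.
* PP3  — computational support: deleteriousness majority vote (>= 3 of 4).
* PP4  — phenotype highly specific for the gene (metadata flag).
* BA1 / BS1 — allele frequency above 5% / above the disorder bound.
* BP4  — unanimous computational benign signal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from scipy import stats

from .config import (
    ACMGConfig,
    CONNECTIVE_TISSUE_CATEGORIES,
    FilterThresholds,
)
from .filters import count_supporting_votes
from .io import (
    AnnotationBundle,
    GenePanel,
    GenotypeCall,
    PredictorVerdict,
    VariantRecord,
    read_panel,
)
from .segregation import InheritanceCall

ACMG_CLASSES = (
    "Pathogenic",
    "Likely Pathogenic",
    "VUS",
    "Likely Benign",
    "Benign",
)

EVIDENCE_CODES = (
    "PVS1",
    "PS2",
    "PM2",
    "PM3",
    "PP1",
    "PP2",
    "PP3",
    "PP4",
    "BA1",
    "BS1",
    "BP4",
)


@dataclass(frozen=True)
class EvidenceProfile:
    PVS1: bool = False
    PS2: bool = False
    PM2: bool = False
    PM3: bool = False
    PP1: bool = False
    PP2: bool = False
    PP3: bool = False
    PP4: bool = False
    BA1: bool = False
    BS1: bool = False
    BP4: bool = False

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c for c in EVIDENCE_CODES if getattr(self, c))

    @property
    def counts(self) -> dict[str, int]:
        return {
            "pvs": int(self.PVS1),
            "ps": int(self.PS2),
            "pm": int(self.PM2) + int(self.PM3),
            "pp": int(self.PP1) + int(self.PP2) + int(self.PP3) + int(self.PP4),
            "ba": int(self.BA1),
            "bs": int(self.BS1),
            "bp": int(self.BP4),
        }


@dataclass
class CandidateRecord:
    """One surviving variant with its inheritance context — a report row."""

    patient: str
    family: str
    normal_name: str  # carrier label as printed in clinical tables
    inheritance: InheritanceCall
    gene: str
    chrom: str
    func_class: str
    exonic_func: str
    zygosity: str  # het | hom (hemizygous males display "hom")
    change: str
    af_fields: dict[str, Optional[float]]
    predictor_verdicts: PredictorVerdict = field(default_factory=PredictorVerdict)
    cadd: Optional[float] = None
    gerp: Optional[float] = None
    dbscsnv_scores: Optional[tuple[float, float]] = None
    splice_distance: Optional[int] = None
    phenotype_match: bool = False
    panel_tag: Optional[str] = None
    evidence: Optional[EvidenceProfile] = None
    acmg_class: Optional[str] = None
    published_acmg: Optional[str] = None

    @property
    def locus_key(self) -> tuple[str, str]:
        """Dedup key: gene + amino-acid/nucleotide change."""
        return (self.gene, self.change)

    @property
    def is_null_variant(self) -> bool:
        return self.exonic_func in ("stopgain", "frameshift") or (
            self.func_class == "splicing"
            and self.splice_distance is not None
            and self.splice_distance <= 2
        )


# --------------------------------------------------------------------------
# panel intersection


def intersect_panel(
    candidates: Iterable[CandidateRecord], panel: GenePanel
) -> list[CandidateRecord]:
    """Tag candidates CVID_OMIM / PID / off-panel (off-panel rows are kept,
    only flagged)."""
    out = []
    for c in candidates:
        c.panel_tag = panel.tag_of(c.gene)  # None = off-panel
        out.append(c)
    return out


# --------------------------------------------------------------------------
# evidence assignment and combination


def assign_evidence(
    c: CandidateRecord,
    acmg: ACMGConfig | None = None,
    thresholds: FilterThresholds | None = None,
) -> EvidenceProfile:
    acmg = acmg or ACMGConfig()
    t = thresholds or FilterThresholds()
    votes = count_supporting_votes(c.predictor_verdicts, c.cadd, t)
    n_support = sum(votes.values())
    afs = [v for v in c.af_fields.values() if v is not None]
    model = c.inheritance.model

    pvs1 = c.is_null_variant
    ps2 = (
        model == "de_novo"
        and (c.panel_tag is not None or c.phenotype_match)
    )
    pm2 = not afs  # unobserved in every configured database
    pm3 = model == "compound_het" and "possible_cis" not in c.inheritance.flags
    pp1 = (
        model in ("hom_recessive", "x_linked_recessive")
        and c.inheritance.carrier_parent in ("father", "mother", "both")
    )
    pp2 = c.exonic_func == "missense" and c.gene.upper() in acmg.pp2_genes
    pp3 = (
        c.exonic_func == "missense" and n_support >= t.predictor_min_votes
    )
    pp4 = c.phenotype_match
    ba1 = any(v >= acmg.ba1_af for v in afs)
    bs1 = any(v >= acmg.bs1_af for v in afs)
    pv = c.predictor_verdicts
    benign_signals = sum(
        (
            pv.sift == "T",
            pv.polyphen_hvar == "B" or pv.polyphen_hdiv == "B",
            pv.mutation_taster in ("N", "P"),
            c.cadd is not None and c.cadd < t.cadd_deleterious_cutoff,
        )
    )
    bp4 = c.exonic_func == "missense" and n_support == 0 and benign_signals >= 3
    return EvidenceProfile(
        PVS1=pvs1, PS2=ps2, PM2=pm2, PM3=pm3, PP1=pp1, PP2=pp2,
        PP3=pp3, PP4=pp4, BA1=ba1, BS1=bs1, BP4=bp4,
    )


def combine_acmg(profile: EvidenceProfile) -> tuple[str, bool]:
    """Five-tier combination of evidence codes.

    Returns ``(class, conflict)``; conflicting pathogenic and benign
    evidence yields ("VUS", True). Pure function over the profile.
    """
    n = profile.counts
    pvs, ps, pm, pp = n["pvs"], n["ps"], n["pm"], n["pp"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = n["ba"] >= 1 or n["bs"] >= 2
    likely_benign = (n["bs"] == 1 and n["bp"] >= 1) or n["bp"] >= 2

    path_tier = pathogenic or likely_pathogenic
    benign_tier = benign or likely_benign
    if path_tier and benign_tier:
        return ("VUS", True)
    if pathogenic:
        return ("Pathogenic", False)
    if likely_pathogenic:
        return ("Likely Pathogenic", False)
    if benign:
        return ("Benign", False)
    if likely_benign:
        return ("Likely Benign", False)
    return ("VUS", False)


def classify_candidates(
    candidates: Iterable[CandidateRecord],
    panel: GenePanel | None = None,
    acmg: ACMGConfig | None = None,
    thresholds: FilterThresholds | None = None,
) -> list[CandidateRecord]:
    """Tag against the panel, assign evidence, and combine, in place."""
    out = list(candidates)
    if panel is not None:
        intersect_panel(out, panel)
    for c in out:
        c.evidence = assign_evidence(c, acmg, thresholds)
        c.acmg_class, _ = combine_acmg(c.evidence)
    return out


# --------------------------------------------------------------------------
# gene-set over-representation


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    overlap: int
    set_size: int
    query_size: int
    background: int
    p_value: float
    adjusted_p: float


def enrich(
    query_genes: Iterable[str],
    gene_sets: dict[str, frozenset[str]],
    background: int = 20_000,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a gene list in each set.

    Upper-tail p = P(X >= overlap) for X ~ Hypergeom(background, set size,
    query size), Benjamini-Hochberg adjusted across sets, sorted by
    ascending p. Zero overlap reports p = 1 rather than dropping the set.
    """
    query = {g.upper() for g in query_genes}
    if not gene_sets:
        return []
    if len(query) > background:
        raise ValueError("query larger than the background universe")
    names = sorted(gene_sets)
    raw = []
    for name in names:
        genes = gene_sets[name]
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, background, len(genes), len(query)))
        raw.append((name, k, len(genes), min(p, 1.0)))
    adjusted = stats.false_discovery_control([p for *_, p in raw], method="bh")
    results = [
        EnrichmentResult(
            name=name,
            overlap=k,
            set_size=size,
            query_size=len(query),
            background=background,
            p_value=p,
            adjusted_p=float(min(adj, 1.0)),
        )
        for (name, k, size, p), adj in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.name))
    return results


# --------------------------------------------------------------------------
# phenotypes and cohort summary


@dataclass(frozen=True)
class PatientPhenotype:
    patient_id: str
    sex: str
    phenotype: str
    phenotype_match_gene: Optional[str] = None


def read_phenotypes(path: str | Path) -> list[PatientPhenotype]:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("patient\t"):
            continue
        patient, sex, phenotype, match = (line.split("\t") + ["."])[:4]
        rows.append(
            PatientPhenotype(
                patient_id=patient,
                sex=sex,
                phenotype=phenotype,
                phenotype_match_gene=None if match in (".", "") else match,
            )
        )
    if not rows:
        raise ValueError(f"{path}: empty phenotype table")
    return rows


def summarize_cohort(
    candidates: Sequence[CandidateRecord],
    phenotypes: Sequence[PatientPhenotype],
    ctd_categories: frozenset[str] = CONNECTIVE_TISSUE_CATEGORIES,
) -> dict:
    """Cohort-level counts: distinct genes/loci, per-gene recurrence,
    per-patient locus counts, ACMG tier counts, phenotype percentages.

    Loci deduplicate on (gene, change); percentages are over the phenotype
    table's patients and printed to one decimal.
    """
    n_patients = len(phenotypes)
    loci: dict[tuple[str, str], list[str]] = {}
    per_patient: dict[str, int] = {p.patient_id: 0 for p in phenotypes}
    tier_by_locus: dict[tuple[str, str], str] = {}
    cvid_loci: set[tuple[str, str]] = set()
    for c in candidates:
        loci.setdefault(c.locus_key, []).append(c.patient)
        per_patient[c.patient] = per_patient.get(c.patient, 0) + 1
        if c.acmg_class:
            tier_by_locus[c.locus_key] = c.acmg_class
        if c.panel_tag == "CVID_OMIM":
            cvid_loci.add(c.locus_key)
    recurrence = {
        f"{gene} {change}": {
            "patients": sorted(set(carriers)),
            "n_patients": len(set(carriers)),
            "pct": round(100.0 * len(set(carriers)) / n_patients, 1)
            if n_patients
            else 0.0,
        }
        for (gene, change), carriers in sorted(loci.items())
        if len(set(carriers)) > 1
    }
    pheno_counts: dict[str, int] = {}
    for p in phenotypes:
        pheno_counts[p.phenotype] = pheno_counts.get(p.phenotype, 0) + 1
    n_ctd = sum(n for cat, n in pheno_counts.items() if cat in ctd_categories)
    tiers = {cls: 0 for cls in ACMG_CLASSES}
    for cls in tier_by_locus.values():
        tiers[cls] += 1
    return {
        "n_patients": n_patients,
        "n_rows": len(candidates),
        "n_loci": len(loci),
        "n_genes": len({gene for gene, _ in loci}),
        "n_cvid_panel_loci": len(cvid_loci),
        "per_patient_loci": dict(sorted(per_patient.items())),
        "patients_with_multiple_loci": sum(
            1 for n in per_patient.values() if n >= 2
        ),
        "recurrent_loci": recurrence,
        "acmg_tiers_by_locus": tiers,
        "phenotype_pct": {
            cat: round(100.0 * n / n_patients, 1)
            for cat, n in sorted(pheno_counts.items())
        },
        "connective_tissue_disease_pct": round(100.0 * n_ctd / n_patients, 1)
        if n_patients
        else 0.0,
    }


# --------------------------------------------------------------------------
# packaged cohort fixture (published candidate table + phenotypes + panel)

_SPLICE_DIST_RE = re.compile(r"c\.\d+\+(\d+)")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("triovar").joinpath("data", name)))


def _opt_float(s: str) -> Optional[float]:
    return None if s in (".", "", "<2") else float(s)


def _opt_code(s: str) -> Optional[str]:
    return None if s in (".", "") else s


def load_fixture_phenotypes() -> list[PatientPhenotype]:
    return read_phenotypes(_data_path("phenotypes.tsv"))


def load_default_panel() -> GenePanel:
    return read_panel(_data_path("panel_pid_cvid.txt"), name="PID/CVID")


def load_fixture_candidates() -> list[CandidateRecord]:
    """The packaged published candidate table as CandidateRecord rows.

    Coordinates and per-site QC values are synthetic (not printed in the
    source table); annotation content — gene, consequence, zygosity,
    inheritance label, database AFs, predictor verdicts, CADD, GERP++ —
    is transcribed.
    """
    pheno = {p.patient_id: p for p in load_fixture_phenotypes()}
    rows: list[CandidateRecord] = []
    text = _data_path("table1_candidates.tsv").read_text()
    for i, line in enumerate(text.splitlines()):
        line = line.strip("\n")
        if not line or line.startswith("#") or line.startswith("patient\t"):
            continue
        (
            patient, normal_name, heredity, gene, chrom, function, het_hom,
            change, published, af_1000g, af_gnomad, sift, hvar, hdiv, mt,
            cadd, ada, rf, gerp,
        ) = line.split("\t")
        func_class = "splicing" if function == "splicing" else "exonic"
        exonic_func = {
            "missense": "missense",
            "stopgain": "stopgain",
            "splicing": "unknown",
        }[function]
        m = _SPLICE_DIST_RE.search(change)
        splice_distance = int(m.group(1)) if m and func_class == "splicing" else None
        patient_pheno = pheno[patient]
        sex = patient_pheno.sex
        model, carrier = _fixture_inheritance(heredity, normal_name, chrom, sex)
        ada_f, rf_f = _opt_float(ada), _opt_float(rf)
        rows.append(
            CandidateRecord(
                patient=patient,
                family=patient,
                normal_name=normal_name,
                inheritance=InheritanceCall(
                    model=model,
                    proband=patient,
                    variant_key=(chrom, 1_000_000 + 1_000 * i, "N", "N"),
                    gene=gene,
                    carrier_parent=carrier,
                ),
                gene=gene,
                chrom=chrom,
                func_class=func_class,
                exonic_func=exonic_func,
                zygosity=het_hom,
                change=change,
                af_fields={
                    "1000g_all": _opt_float(af_1000g),
                    "gnomAD_all": _opt_float(af_gnomad),
                },
                predictor_verdicts=PredictorVerdict(
                    sift=_opt_code(sift),
                    polyphen_hvar=_opt_code(hvar),
                    polyphen_hdiv=_opt_code(hdiv),
                    mutation_taster=_opt_code(mt),
                ),
                cadd=_opt_float(cadd),
                gerp=_opt_float(gerp),
                dbscsnv_scores=(ada_f, rf_f)
                if ada_f is not None and rf_f is not None
                else None,
                splice_distance=splice_distance,
                phenotype_match=patient_pheno.phenotype_match_gene == gene,
                published_acmg=published,
            )
        )
    return rows


def _fixture_inheritance(
    heredity: str, normal_name: str, chrom: str, sex: str
) -> tuple[str, str]:
    if heredity == "sporadic":
        return ("sporadic_only", "none")
    if heredity == "de_novo":
        return ("de_novo", "none")
    if heredity == "recessive":
        carrier = _carrier_from_name(normal_name)
        if chrom in ("X", "chrX") and sex == "male":
            return ("x_linked_recessive", carrier)
        return ("hom_recessive", carrier if carrier != "none" else "both")
    if heredity == "oligogene":
        return ("inherited_het", _carrier_from_name(normal_name))
    raise ValueError(f"unknown heredity label {heredity!r}")


def _carrier_from_name(normal_name: str) -> str:
    if normal_name.endswith("Dad"):
        return "father"
    if normal_name.endswith("Mom"):
        return "mother"
    return "unknown" if normal_name not in ("-", "") else "none"


def fixture_variant_records(
    candidates: Iterable[CandidateRecord],
) -> list[tuple[CandidateRecord, VariantRecord]]:
    """Reconstruct minimal VariantRecords from fixture rows so the filter
    cascade can run on them; QC values are synthetic passing defaults
    (depth 30, MQ 60, QUAL 60) since the published table omits raw-call QC.
    """
    out = []
    for c in candidates:
        chrom, pos, _, _ = c.inheritance.variant_key
        if "dup" in c.change:
            ref, alt = "A", "A" + "GT" * 9 + "C"  # 19-bp insertion
        else:
            ref, alt = "A", "G"
        zyg_count = 2 if c.zygosity == "hom" else 1
        v = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            site_qual=60.0,
            site_mq=60.0,
            genotypes={c.patient: GenotypeCall(zyg_count, 30)},
            annotation=AnnotationBundle(
                gene=c.gene,
                func_class=c.func_class,
                exonic_func=c.exonic_func,
                splice_distance=c.splice_distance,
                dbscsnv_scores=c.dbscsnv_scores,
                af_fields=dict(c.af_fields),
                predictor_verdicts=c.predictor_verdicts,
                cadd=c.cadd,
                gerp=c.gerp,
            ),
        )
        out.append((c, v))
    return out


# --------------------------------------------------------------------------
# report writing


def write_candidate_table(
    candidates: Iterable[CandidateRecord], path: str | Path
) -> None:
    """Candidate report in the clinical table layout."""
    header = (
        "Patient\tNormal_name\tHeredity\tGene\tFunction\tHet_hom\tChange"
        "\tACMG\tFrequency\tDeleterious\tgerp\tPanel\tEvidence"
    )
    lines = [header]
    for c in candidates:
        pv = c.predictor_verdicts
        freq = "|".join(
            "." if v is None else f"{v:.10g}"
            for v in c.af_fields.values()
        )
        dele = "|".join(
            [
                pv.sift or ".",
                pv.polyphen_hvar or ".",
                pv.polyphen_hdiv or ".",
                pv.mutation_taster or ".",
                "." if c.cadd is None else f"{c.cadd:.10g}",
            ]
        )
        lines.append(
            "\t".join(
                [
                    c.patient,
                    c.normal_name,
                    c.inheritance.model,
                    c.gene,
                    c.exonic_func if c.func_class != "splicing" else "splicing",
                    c.zygosity,
                    c.change,
                    c.acmg_class or ".",
                    freq,
                    dele,
                    "." if c.gerp is None else f"{c.gerp:.10g}",
                    c.panel_tag or "off-panel",
                    ",".join(c.evidence.codes) if c.evidence else ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
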