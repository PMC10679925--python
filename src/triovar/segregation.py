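"""Inheritance-model screening over filtered variants.

For each affected proband the engine evaluates, per variant:

* de novo           — proband carries the allele, both parents observed
                      hom-ref with adequate depth;
* hom. recessive    — proband hom-alt, each observed parent carries >= 1
                      copy (the transmitting parents);
* X-linked recessive — hemizygous alt in an affected male with a carrier
                      mother (displayed "hom" in clinical tables);
* inherited het     — transmitted from one unaffected parent; such calls
                      feed compound-het pairing and oligogenic profiles;
* sporadic-only     — for singleton cases, the allele is present in the
                      case and in no other cohort sample.

Soundness: no variant is ever both de novo and inherited for the same
proband, and an autosomal hom-alt proband with a hom-ref observed parent is
reported as ``possible_denovo_or_error`` — a Mendelian inconsistency —
never as recessive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional

from .config import FilterThresholds
from .io import Pedigree, SampleInfo, VariantRecord

MODELS = (
    "de_novo",
    "hom_recessive",
    "compound_het",
    "x_linked_recessive",
    "sporadic_only",
    "inherited_het",
    "possible_denovo_or_error",
)


@dataclass
class InheritanceCall:
    model: str
    proband: str
    variant_key: tuple
    gene: Optional[str]
    carrier_parent: str = "none"  # father | mother | both | none | unknown
    partner_variant: Optional[tuple] = None  # compound-het only
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.carrier_parent not in ("father", "mother", "both", "none", "unknown"):
            raise ValueError(f"carrier_parent {self.carrier_parent!r}")

    @property
    def is_denovo(self) -> bool:
        return self.model == "de_novo"

    @property
    def is_mendelian_violation(self) -> bool:
        return self.model == "possible_denovo_or_error"


@dataclass
class OligogenicProfile:
    """>= 2 heterozygous candidate loci across >= 2 genes in one proband,
    each inherited from an unaffected parent or arisen de novo."""

    proband: str
    loci: list[InheritanceCall]

    def __post_init__(self) -> None:
        if len({c.gene for c in self.loci}) < 2:
            raise ValueError("oligogenic profile needs >= 2 distinct genes")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(c.gene for c in self.loci if c.gene)


def _alt_count(v: VariantRecord, sample: Optional[SampleInfo]) -> Optional[int]:
    if sample is None:
        return None
    g = v.genotypes.get(sample.sample_id)
    if g is None or g.missing:
        return None
    return g.allele_count


def _depth_ok(v: VariantRecord, sample: SampleInfo, t: FilterThresholds) -> bool:
    g = v.genotypes.get(sample.sample_id)
    return g is not None and not g.missing and g.depth is not None and g.depth > t.min_depth


def call_trio_model(
    v: VariantRecord,
    proband: SampleInfo,
    pedigree: Pedigree,
    thresholds: FilterThresholds | None = None,
) -> Optional[InheritanceCall]:
    """Classify one variant in one proband against the parental genotypes.

    De novo additionally requires parental depth above the site-QC bound at
    the site, so parental dropout is not mistaken for a new mutation.
    Returns ``None`` when the proband does not carry the allele or no model
    applies.
    """
    t = thresholds or FilterThresholds()
    pb = _alt_count(v, proband)
    if not pb:
        return None
    father, mother = pedigree.parents_of(proband.sample_id)
    fa, mo = _alt_count(v, father), _alt_count(v, mother)
    gene = v.annotation.gene
    base = dict(proband=proband.sample_id, variant_key=v.key, gene=gene)
    male_x = v.on_x and proband.sex == "male"

    if male_x:
        # hemizygous male: only the maternal X is informative
        if mo is not None and mo >= 1:
            return InheritanceCall(
                model="x_linked_recessive", carrier_parent="mother", **base
            )
        if mo == 0:
            if mother is not None and _depth_ok(v, mother, t):
                return InheritanceCall(model="de_novo", carrier_parent="none", **base)
            return None
        return InheritanceCall(
            model="x_linked_recessive",
            carrier_parent="unknown",
            flags=["incomplete_trio"],
            **base,
        )

    if fa == 0 and mo == 0:
        if (
            father is not None
            and mother is not None
            and _depth_ok(v, father, t)
            and _depth_ok(v, mother, t)
        ):
            if pb == 2:
                # hom-alt child from two hom-ref parents: a double de novo
                # is vanishingly unlikely; call it an error candidate
                return InheritanceCall(
                    model="possible_denovo_or_error", carrier_parent="none", **base
                )
            return InheritanceCall(model="de_novo", carrier_parent="none", **base)
        return None  # parental dropout: not callable either way

    if pb == 2:
        if fa is None or mo is None:
            return InheritanceCall(
                model="hom_recessive",
                carrier_parent="unknown",
                flags=["incomplete_trio"],
                **base,
            )
        if fa >= 1 and mo >= 1:
            return InheritanceCall(
                model="hom_recessive", carrier_parent="both", **base
            )
        # one observed parent hom-ref: Mendelian violation
        return InheritanceCall(
            model="possible_denovo_or_error",
            carrier_parent="father" if fa else "mother",
            **base,
        )

    # heterozygous proband: inherited only when a carrier parent is observed;
    # an allele that could equally come from an ungenotyped parent or arise
    # de novo is not callable
    if fa and mo:
        carrier = "both"
    elif fa:
        carrier = "father"
    elif mo:
        carrier = "mother"
    else:
        return None
    flags = []
    if fa is None or mo is None:
        flags.append("incomplete_trio")
    return InheritanceCall(
        model="inherited_het", carrier_parent=carrier, flags=flags, **base
    )


def call_compound_het(
    variants: list[VariantRecord],
    proband: SampleInfo,
    pedigree: Pedigree,
    thresholds: FilterThresholds | None = None,
) -> list[tuple[InheritanceCall, InheritanceCall]]:
    """Trans compound-heterozygote pairs among one gene's proband-het calls.

    A pair is trans when one variant is transmitted by the father only and
    the other by the mother only. Pairs that cannot be phased by parental
    origin (a parent carries both, or parental genotypes are missing) are
    flagged ``possible_cis`` rather than silently dropped.
    """
    t = thresholds or FilterThresholds()
    hets: list[tuple[VariantRecord, InheritanceCall]] = []
    for v in variants:
        if _alt_count(v, proband) != 1:
            continue
        call = call_trio_model(v, proband, pedigree, t)
        if call is not None and call.model == "inherited_het":
            hets.append((v, call))
    pairs: list[tuple[InheritanceCall, InheritanceCall]] = []
    for (va, ca), (vb, cb) in combinations(hets, 2):
        if va.annotation.gene != vb.annotation.gene:
            continue
        carriers = {ca.carrier_parent, cb.carrier_parent}
        if carriers == {"father", "mother"}:
            flags: list[str] = []
        elif "both" in carriers or "unknown" in carriers:
            flags = ["possible_cis"]
        else:
            continue  # same single carrier parent: cis configuration
        a = InheritanceCall(
            model="compound_het",
            proband=proband.sample_id,
            variant_key=va.key,
            gene=va.annotation.gene,
            carrier_parent=ca.carrier_parent,
            partner_variant=vb.key,
            flags=list(flags),
        )
        b = InheritanceCall(
            model="compound_het",
            proband=proband.sample_id,
            variant_key=vb.key,
            gene=vb.annotation.gene,
            carrier_parent=cb.carrier_parent,
            partner_variant=va.key,
            flags=list(flags),
        )
        pairs.append((a, b))
    return pairs


def call_sporadic(
    v: VariantRecord,
    case: SampleInfo,
    control_ids: Iterable[str],
) -> Optional[InheritanceCall]:
    """Case-exclusive presence screen for singleton (sporadic) cases.

    The allele must be present in the case and absent from every other
    cohort sample. A missing control genotype counts as "not detected" —
    absence of data is not presence — but the call is flagged.
    """
    g = v.genotypes.get(case.sample_id)
    if g is None or g.missing or not g.carries_alt:
        return None
    flags: list[str] = []
    for cid in control_ids:
        if cid == case.sample_id:
            continue
        cg = v.genotypes.get(cid)
        if cg is None or cg.missing:
            flags.append("control_missing")
            continue
        if cg.carries_alt:
            return None
    return InheritanceCall(
        model="sporadic_only",
        proband=case.sample_id,
        variant_key=v.key,
        gene=v.annotation.gene,
        carrier_parent="none",
        flags=sorted(set(flags)),
    )


def build_oligogenic_profile(
    proband: str, calls: Iterable[InheritanceCall]
) -> Optional[OligogenicProfile]:
    """Aggregate a proband's candidate calls into an oligogenic profile.

    Emitted iff >= 2 heterozygous candidate loci across >= 2 genes, each
    either de novo or inherited from an unaffected parent (carrier parents
    are healthy first-degree relatives by cohort design). Homozygous and
    hemizygous models are monogenic explanations and are excluded.
    """
    eligible = [
        c
        for c in calls
        if c.proband == proband
        and c.model in ("inherited_het", "de_novo", "compound_het")
        and c.gene is not None
    ]
    genes = {c.gene for c in eligible}
    if len(eligible) < 2 or len(genes) < 2:
        return None
    return OligogenicProfile(proband=proband, loci=eligible)
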