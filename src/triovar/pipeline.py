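"""End-to-end screening: cascade -> segregation -> classification.

Thin orchestration over the library modules; every step is individually
importable and tested, this module just wires them in the order the method
runs and evaluates results against a simulator truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .classify import CandidateRecord, classify_candidates
from .config import ACMGConfig, FilterThresholds
from .filters import FilterTrace, run_cascade
from .io import GenePanel, Pedigree, VariantRecord
from .segregation import (
    InheritanceCall,
    OligogenicProfile,
    build_oligogenic_profile,
    call_compound_het,
    call_sporadic,
    call_trio_model,
)

CANDIDATE_MODELS = frozenset(
    {"de_novo", "hom_recessive", "x_linked_recessive", "sporadic_only",
     "compound_het"}
)


@dataclass
class ScreenResult:
    calls: list[InheritanceCall]
    candidates: list[CandidateRecord]
    profiles: list[OligogenicProfile]
    traces: list[FilterTrace]

    def calls_for(self, proband: str) -> list[InheritanceCall]:
        return [c for c in self.calls if c.proband == proband]


def screen_cohort(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    thresholds: FilterThresholds | None = None,
    panel: GenePanel | None = None,
    acmg: ACMGConfig | None = None,
    keep_traces: bool = False,
) -> ScreenResult:
    """Run the filter cascade and segregation screen for every affected
    sample, then classify the resulting candidates."""
    t = thresholds or FilterThresholds()
    all_ids = [s.sample_id for s in pedigree.samples]
    calls: list[InheritanceCall] = []
    traces: list[FilterTrace] = []
    profiles: list[OligogenicProfile] = []

    for proband in pedigree.affected:
        pid = proband.sample_id
        passing: list[VariantRecord] = []
        for v in records:
            g = v.genotypes.get(pid)
            if g is None or g.missing or not g.carries_alt:
                continue
            trace = run_cascade(v, pid, t)
            if keep_traces:
                traces.append(trace)
            if trace.passed:
                passing.append(v)

        proband_calls: list[InheritanceCall] = []
        if pedigree.is_singleton(pid):
            for v in passing:
                call = call_sporadic(v, proband, all_ids)
                if call is not None:
                    proband_calls.append(call)
        else:
            het_by_gene: dict[str, list[VariantRecord]] = {}
            for v in passing:
                call = call_trio_model(v, proband, pedigree, t)
                if call is None:
                    continue
                proband_calls.append(call)
                if call.model == "inherited_het" and v.annotation.gene:
                    het_by_gene.setdefault(v.annotation.gene, []).append(v)
            for gene in sorted(het_by_gene):
                for a, b in call_compound_het(
                    het_by_gene[gene], proband, pedigree, t
                ):
                    proband_calls.extend((a, b))
        calls.extend(proband_calls)
        profile = build_oligogenic_profile(pid, proband_calls)
        if profile is not None:
            profiles.append(profile)

    candidates = _to_candidates(records, pedigree, calls, profiles)
    classify_candidates(candidates, panel=panel, acmg=acmg, thresholds=t)
    return ScreenResult(
        calls=calls, candidates=candidates, profiles=profiles, traces=traces
    )


def _to_candidates(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    calls: Sequence[InheritanceCall],
    profiles: Sequence[OligogenicProfile],
) -> list[CandidateRecord]:
    by_key = {v.key: v for v in records}
    oligo_keys = {
        (p.proband, c.variant_key) for p in profiles for c in p.loci
    }
    out: list[CandidateRecord] = []
    seen: set[tuple] = set()
    for call in calls:
        if call.model not in CANDIDATE_MODELS and (
            call.proband, call.variant_key
        ) not in oligo_keys:
            continue
        dedup = (call.proband, call.variant_key, call.model)
        if dedup in seen:
            continue
        seen.add(dedup)
        v = by_key[call.variant_key]
        sample = pedigree[call.proband]
        g = v.genotypes[call.proband]
        hemizygous = v.on_x and sample.sex == "male" and g.carries_alt
        a = v.annotation
        out.append(
            CandidateRecord(
                patient=call.proband,
                family=sample.family_id,
                normal_name=_normal_name(call, sample),
                inheritance=call,
                gene=a.gene or ".",
                chrom=v.chrom,
                func_class=a.func_class,
                exonic_func=a.exonic_func,
                zygosity="hom" if g.allele_count == 2 or hemizygous else "het",
                change=f"{v.chrom}:{v.pos}{v.ref}>{v.alt}",
                af_fields=dict(a.af_fields),
                predictor_verdicts=a.predictor_verdicts,
                cadd=a.cadd,
                gerp=a.gerp,
                dbscsnv_scores=a.dbscsnv_scores,
                splice_distance=a.splice_distance,
            )
        )
    return out


def _normal_name(call: InheritanceCall, sample) -> str:
    if call.model == "de_novo":
        return "De novo"
    if call.carrier_parent == "father":
        return f"{sample.family_id}_Dad"
    if call.carrier_parent == "mother":
        return f"{sample.family_id}_Mom"
    return "-"


# --------------------------------------------------------------------------
# truth evaluation (simulator spike-ins)


@dataclass
class RecallReport:
    per_model: dict[str, tuple[int, int]]  # model -> (recovered, spiked)
    mendelian_violation_calls: int
    false_de_novo_keys: list[tuple] = field(default_factory=list)

    @property
    def overall_recall(self) -> float:
        found = sum(f for f, _ in self.per_model.values())
        total = sum(n for _, n in self.per_model.values())
        return found / total if total else 1.0

    def recall(self, model: str) -> float:
        found, total = self.per_model.get(model, (0, 0))
        return found / total if total else 1.0


def evaluate_truth(
    calls: Iterable[InheritanceCall],
    truth_rows,
    *,
    truth_keys: Optional[set[tuple]] = None,
) -> RecallReport:
    """Spike-in recovery: per-model recall plus Mendelian-violation and
    false de novo counts over the full call set."""
    calls = list(calls)
    indexed = {(c.proband, c.variant_key, c.model) for c in calls}
    per_model: dict[str, list[int]] = {}
    spiked_keys = set()
    for row in truth_rows:
        spiked_keys.add(row.variant_key)
        hit = (row.proband, row.variant_key, row.model) in indexed
        per_model.setdefault(row.model, [0, 0])
        per_model[row.model][1] += 1
        per_model[row.model][0] += int(hit)
    if truth_keys is not None:
        spiked_keys |= truth_keys
    violations = sum(1 for c in calls if c.is_mendelian_violation)
    false_dn = [
        c.variant_key
        for c in calls
        if c.model == "de_novo" and c.variant_key not in spiked_keys
    ]
    return RecallReport(
        per_model={m: (f, n) for m, (f, n) in per_model.items()},
        mendelian_violation_calls=violations,
        false_de_novo_keys=false_dn,
    )
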