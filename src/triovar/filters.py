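"""Site-QC and rare/deleterious filtering cascade.

Stages run in a fixed order — site_qc, region, synonymous, repeat_indel,
frequency, deleteriousness — and every variant gets a :class:`FilterTrace`
recording each stage's decision and the observed values it used. The first
failing stage short-circuits evaluation (later stages are not run), but
because each stage is a pure predicate of the variant alone, the final
outcome is identical to the conjunction of independently evaluated stages.

Stage semantics (all inequalities strict as stated by the protocol):

* site_qc       — per-sample read depth > 4, site RMS mapping quality > 30,
                  variant quality > 20.
* region        — exonic, or splicing within 10 bp of the junction
                  (inclusive window; an annotated splicing call without a
                  recorded distance is trusted to be in-window).
* synonymous    — synonymous SNVs are discarded unless dbscSNV predicts a
                  splice impact (either score >= 0.6 by default).
* repeat_indel  — non-frameshift indels shorter than 10 bp inside
                  RepeatMasker repeats are discarded.
* frequency     — every configured database AF must be ABSENT or < 0.01.
* deleteriousness — four voters (SIFT; PolyPhen, HVAR/HDIV merged;
                  MutationTaster; CADD). The majority verdict (>= 3 of 4)
                  is always computed and recorded and is what "predicted
                  deleterious" means downstream (PP3). Retention by the
                  cascade is governed by ``retain_min_votes`` and applies
                  to missense variants; non-missense consequences
                  (stopgain, frameshift, splicing, ...) are retained on
                  consequence since these tools only score missense sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .config import FilterThresholds
from .io import PredictorVerdict, VariantRecord

STAGES = (
    "site_qc",
    "region",
    "synonymous",
    "repeat_indel",
    "frequency",
    "deleteriousness",
)

# verdict codes that count as a supporting (deleterious) vote per tool
SIFT_SUPPORTING = frozenset({"D"})
POLYPHEN_SUPPORTING = frozenset({"D", "P"})
MT_SUPPORTING = frozenset({"D", "A"})


@dataclass(frozen=True)
class FilterDecision:
    stage: str
    passed: bool
    reason: str
    observed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class FilterTrace:
    variant_key: tuple
    decisions: list[FilterDecision]

    @property
    def passed(self) -> bool:
        return all(d.passed for d in self.decisions)

    @property
    def failing_stage(self) -> Optional[str]:
        for d in self.decisions:
            if not d.passed:
                return d.stage
        return None

    def decision(self, stage: str) -> Optional[FilterDecision]:
        for d in self.decisions:
            if d.stage == stage:
                return d
        return None


# --------------------------------------------------------------------------
# stages


def site_qc(
    v: VariantRecord, sample: str, t: FilterThresholds
) -> FilterDecision:
    """Raw-call QC for one sample: depth, mapping quality, variant quality."""
    g = v.genotypes.get(sample)
    observed = {
        "depth": None if g is None else g.depth,
        "mq": v.site_mq,
        "qual": v.site_qual,
    }
    if g is None or g.missing:
        return FilterDecision("site_qc", False, "missing_genotype", observed)
    if g.depth is None:
        return FilterDecision("site_qc", False, "missing_dp", observed)
    if g.depth <= t.min_depth:
        return FilterDecision("site_qc", False, "low_depth", observed)
    if v.site_mq is None or v.site_mq <= t.min_mq:
        return FilterDecision("site_qc", False, "low_mq", observed)
    if v.site_qual is None or v.site_qual <= t.min_qual:
        return FilterDecision("site_qc", False, "low_qual", observed)
    return FilterDecision("site_qc", True, "ok", observed)


def region_filter(v: VariantRecord, t: FilterThresholds) -> FilterDecision:
    """Keep exonic variants and splice-region variants within the window."""
    a = v.annotation
    observed = {"func_class": a.func_class, "splice_distance": a.splice_distance}
    if a.func_class == "exonic":
        return FilterDecision("region", True, "exonic", observed)
    if a.func_class == "splicing":
        if a.splice_distance is None or a.splice_distance <= t.splice_window_bp:
            return FilterDecision("region", True, "splicing_in_window", observed)
        return FilterDecision("region", False, "splicing_out_of_window", observed)
    if a.func_class == "other":
        return FilterDecision("region", False, "outside_target_region", observed)
    return FilterDecision("region", False, "unannotated", observed)


def synonymous_filter(v: VariantRecord, t: FilterThresholds) -> FilterDecision:
    """Discard synonymous SNVs unless dbscSNV flags a splice impact."""
    a = v.annotation
    observed = {"exonic_func": a.exonic_func, "dbscsnv": a.dbscsnv_scores}
    if a.exonic_func != "synonymous":
        return FilterDecision("synonymous", True, "not_applicable", observed)
    if a.dbscsnv_scores is not None and (
        max(a.dbscsnv_scores) >= t.dbscsnv_splice_cutoff
    ):
        return FilterDecision("synonymous", True, "splice_impacting", observed)
    return FilterDecision("synonymous", False, "synonymous", observed)


def repeat_indel_filter(v: VariantRecord, t: FilterThresholds) -> FilterDecision:
    """Discard small non-frameshift indels inside repetitive regions."""
    observed = {
        "indel_length": v.indel_length,
        "in_repeat": v.annotation.in_repeat,
    }
    if not v.is_indel:
        return FilterDecision("repeat_indel", True, "not_applicable", observed)
    nonframeshift = v.indel_length % 3 == 0
    if (
        nonframeshift
        and v.indel_length < t.indel_repeat_max_len
        and v.annotation.in_repeat
    ):
        return FilterDecision(
            "repeat_indel", False, "small_nonframeshift_in_repeat", observed
        )
    return FilterDecision("repeat_indel", True, "ok", observed)


def frequency_filter(v: VariantRecord, t: FilterThresholds) -> FilterDecision:
    """Rarity screen: every database AF must be ABSENT or below the bound.

    ABSENT (``None``) means unobserved in that database — extremely rare —
    and always passes; it is never treated as 0.0.
    """
    observed = dict(v.annotation.af_fields)
    for db, af in v.annotation.af_fields.items():
        if af is not None and af >= t.max_af:
            return FilterDecision(
                "frequency", False, f"common_in_{db}", observed
            )
    return FilterDecision("frequency", True, "rare_or_absent", observed)


def count_supporting_votes(
    pv: PredictorVerdict, cadd: Optional[float], t: FilterThresholds
) -> dict[str, bool]:
    """Per-voter support for deleteriousness. Absent voter = no support.

    PolyPhen's two sub-scores (HVAR, HDIV) are merged into a single vote,
    supporting if either is damaging or possibly damaging, keeping exactly
    four voters.
    """
    return {
        "sift": pv.sift in SIFT_SUPPORTING,
        "polyphen": (
            pv.polyphen_hvar in POLYPHEN_SUPPORTING
            or pv.polyphen_hdiv in POLYPHEN_SUPPORTING
        ),
        "mutation_taster": pv.mutation_taster in MT_SUPPORTING,
        "cadd": cadd is not None and cadd >= t.cadd_deleterious_cutoff,
    }


def deleteriousness_vote(
    pv: PredictorVerdict,
    cadd: Optional[float],
    t: FilterThresholds,
    *,
    lof_bypass: bool = False,
) -> FilterDecision:
    """Majority vote over the four predictors (pass iff >= 3 of 4 support).

    ``lof_bypass`` marks a loss-of-function consequence (stopgain or
    canonical +/-2 splice) with no predictor output at all: such variants
    bypass the vote rather than being penalized for unscored tools.
    """
    votes = count_supporting_votes(pv, cadd, t)
    n = sum(votes.values())
    observed = {"votes": votes, "supporting": n, "cadd": cadd}
    if pv.all_absent and cadd is None:
        if lof_bypass:
            return FilterDecision("deleteriousness", True, "lof_bypass", observed)
        return FilterDecision("deleteriousness", False, "no_predictions", observed)
    if n >= t.predictor_min_votes:
        return FilterDecision("deleteriousness", True, "majority_deleterious", observed)
    return FilterDecision("deleteriousness", False, "majority_not_reached", observed)


def is_canonical_splice(v: VariantRecord) -> bool:
    a = v.annotation
    return (
        a.func_class == "splicing"
        and a.splice_distance is not None
        and a.splice_distance <= 2
    )


def is_lof(v: VariantRecord) -> bool:
    """Null-variant consequence: stopgain, frameshift, canonical splice."""
    return v.annotation.exonic_func in ("stopgain", "frameshift") or (
        is_canonical_splice(v)
    )


def _deleteriousness_stage(v: VariantRecord, t: FilterThresholds) -> FilterDecision:
    """Cascade retention at the deleteriousness stage.

    Missense variants are retained with at least ``retain_min_votes``
    supporting votes (the >= 3/4 majority verdict is recorded in the
    observation either way). Non-missense consequences are retained on
    consequence class — the four tools only score missense changes.
    """
    a = v.annotation
    if a.func_class == "splicing" or a.exonic_func != "missense":
        votes = count_supporting_votes(a.predictor_verdicts, a.cadd, t)
        observed = {
            "votes": votes,
            "supporting": sum(votes.values()),
            "majority": sum(votes.values()) >= t.predictor_min_votes,
            "consequence": a.exonic_func if a.func_class != "splicing" else "splicing",
        }
        return FilterDecision(
            "deleteriousness", True, "non_missense_consequence", observed
        )
    decision = deleteriousness_vote(
        a.predictor_verdicts, a.cadd, t, lof_bypass=is_lof(v)
    )
    observed = dict(decision.observed)
    observed["majority"] = decision.passed
    if decision.passed or observed["supporting"] >= t.retain_min_votes:
        reason = decision.reason if decision.passed else "retained_minority_support"
        return FilterDecision("deleteriousness", True, reason, observed)
    return FilterDecision("deleteriousness", False, decision.reason, observed)


# --------------------------------------------------------------------------
# cascade


def run_cascade(
    v: VariantRecord, sample: str, t: FilterThresholds | None = None
) -> FilterTrace:
    """Apply all stages in order for one sample; short-circuit on failure."""
    t = t or FilterThresholds()
    decisions: list[FilterDecision] = []
    for stage_fn in (
        lambda: site_qc(v, sample, t),
        lambda: region_filter(v, t),
        lambda: synonymous_filter(v, t),
        lambda: repeat_indel_filter(v, t),
        lambda: frequency_filter(v, t),
        lambda: _deleteriousness_stage(v, t),
    ):
        d = stage_fn()
        decisions.append(d)
        if not d.passed:
            break
    return FilterTrace(variant_key=(*v.key, sample), decisions=decisions)


def write_trace_tsv(traces: Iterable[FilterTrace], path: str | Path) -> None:
    """One row per variant x stage, with pass/fail and reason codes."""
    lines = ["chrom\tpos\tref\talt\tsample\tstage\tpassed\treason"]
    for tr in traces:
        chrom, pos, ref, alt, sample = tr.variant_key
        for d in tr.decisions:
            lines.append(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t{sample}\t{d.stage}"
                f"\t{int(d.passed)}\t{d.reason}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
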