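"""Shared configuration: annotation dialect, filter thresholds, ACMG knobs.

The annotation dialect maps the semantic fields the pipeline needs (gene
symbol, functional class, four population allele-frequency databases, four
deleteriousness predictors, CADD, GERP++, dbscSNV, repeat overlap) onto VCF
INFO keys. Defaults follow ANNOVAR column names, sanitized where the literal
ANNOVAR spelling is not a legal VCF identifier (``1000g2015aug_all`` starts
with a digit, ``GERP++_RS`` contains ``+``); any spelling can be restored
through a YAML config file because ANNOVAR key names drift across versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

# Population AF databases screened for rarity (AF < max_af in every one).
DEFAULT_AF_KEYS: dict[str, str] = {
    "1000g_all": "g1000_2015aug_all",
    "esp6500siv2_all": "esp6500siv2_all",
    "gnomAD_all": "gnomAD_genome_ALL",
    "gnomAD_EAS": "gnomAD_genome_EAS",
}

DEFAULT_PREDICTOR_KEYS: dict[str, str] = {
    "sift": "SIFT_pred",
    "polyphen_hvar": "Polyphen2_HVAR_pred",
    "polyphen_hdiv": "Polyphen2_HDIV_pred",
    "mutation_taster": "MutationTaster_pred",
}


@dataclass(frozen=True)
class AnnotationDialect:
    """INFO key names for ANNOVAR-style annotations."""

    gene: str = "Gene_refGene"
    func: str = "Func_refGene"
    exonic_func: str = "ExonicFunc_refGene"
    splice_distance: str = "SpliceDist"
    dbscsnv_ada: str = "dbscSNV_ADA_SCORE"
    dbscsnv_rf: str = "dbscSNV_RF_SCORE"
    in_repeat: str = "InRepeat"
    cadd: str = "CADD_phred"
    gerp: str = "GERP_RS"
    mq: str = "MQ"
    af_keys: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_AF_KEYS))
    predictor_keys: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTOR_KEYS)
    )


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the site-QC and rarity/deleteriousness cascade.

    All inequalities are strict as printed in the source protocol: read
    depth > 4, RMS mapping quality > 30, variant quality > 20, every
    database AF < 0.01, non-frameshift indel length < 10 bp. The splice
    window is inclusive (<= 10 bp from the junction).

    ``predictor_min_votes`` is the majority rule for the four-tool
    deleteriousness vote (more than half of SIFT / PolyPhen / MutationTaster
    / CADD, i.e. >= 3 of 4); ``retain_min_votes`` is the weaker retention
    bound the cascade applies to missense variants (see docs/methods.md for
    why retention and majority are separate knobs).
    """

    min_depth: int = 4
    min_mq: float = 30.0
    min_qual: float = 20.0
    max_af: float = 0.01
    splice_window_bp: int = 10
    indel_repeat_max_len: int = 10
    predictor_min_votes: int = 3
    retain_min_votes: int = 1
    cadd_deleterious_cutoff: float = 20.0
    dbscsnv_splice_cutoff: float = 0.6

    def __post_init__(self) -> None:
        for name in (
            "min_depth",
            "min_mq",
            "min_qual",
            "max_af",
            "splice_window_bp",
            "indel_repeat_max_len",
            "cadd_deleterious_cutoff",
            "dbscsnv_splice_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if not 1 <= self.predictor_min_votes <= 4:
            raise ValueError("predictor_min_votes must be in 1..4")
        if not 1 <= self.retain_min_votes <= 4:
            raise ValueError("retain_min_votes must be in 1..4")
        if self.retain_min_votes > self.predictor_min_votes:
            raise ValueError("retain_min_votes cannot exceed predictor_min_votes")


@dataclass(frozen=True)
class ACMGConfig:
    """Knobs of the ACMG-lite evidence mapping.

    pp2_genes: genes treated as missense-constrained (PP2 applies).
    bs1_af / ba1_af: allele-frequency bounds for the benign branches.
    """

    pp2_genes: frozenset[str] = frozenset({"CD40LG"})
    bs1_af: float = 0.01
    ba1_af: float = 0.05
    background_genes: int = 20_000

    def __post_init__(self) -> None:
        if not 0 < self.bs1_af <= self.ba1_af <= 1:
            raise ValueError("need 0 < bs1_af <= ba1_af <= 1")


# Autoimmune phenotype vocabulary; the connective-tissue-disease grouping
# used for cohort summaries ships as the default.
CONNECTIVE_TISSUE_CATEGORIES: frozenset[str] = frozenset(
    {
        "SLE",
        "Sjogren",
        "UCTD",
        "EGPA",
    }
)


def load_config(path: str | Path) -> tuple[AnnotationDialect, FilterThresholds]:
    """Read dialect and threshold overrides from a YAML file.

    Two optional top-level mappings are recognized: ``dialect`` and
    ``thresholds``; unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"dialect", "thresholds"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    dialect = replace(AnnotationDialect(), **(raw.get("dialect") or {}))
    thresholds = replace(FilterThresholds(), **(raw.get("thresholds") or {}))
    return dialect, thresholds
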