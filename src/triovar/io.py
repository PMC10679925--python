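"""Cohort I/O: VCF, PED, gene panels, repeat BED, CNV/SV event tables, GMT.

Conventions
-----------
* VCF coordinates are 1-based inclusive; BED and event tables are 0-based
  half-open. All conversions happen here.
* Multi-allelic VCF rows are split into one :class:`VariantRecord` per
  alternate allele, with genotypes re-coded as copy number of that allele.
* A population allele frequency of ``None`` means ABSENT — the variant is
  unobserved in that database. ABSENT is deliberately distinct from ``0.0``
  and is never compared numerically downstream.
* Deterministic ordering everywhere: (karyotype chromosome order, position,
  ref, alt).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import cyvcf2
from intervaltree import IntervalTree

from .config import AnnotationDialect

# --------------------------------------------------------------------------
# vocabularies and ordering

FUNC_CLASSES = ("exonic", "splicing", "other")
EXONIC_FUNCS = (
    "missense",
    "synonymous",
    "stopgain",
    "stoploss",
    "frameshift",
    "nonframeshift",
    "unknown",
)
SIFT_CODES = frozenset({"D", "T"})
POLYPHEN_CODES = frozenset({"D", "P", "B"})
MT_CODES = frozenset({"D", "A", "N", "P"})
EVENT_TYPES = ("DEL", "DUP", "INV", "SV")

_KARYOTYPE = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix; keep the label otherwise untouched."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = normalize_chrom(chrom)
    return (_KARYOTYPE.get(c, 99), c)


class VcfParseError(ValueError):
    pass


class PedigreeError(ValueError):
    pass


# --------------------------------------------------------------------------
# domain types


@dataclass
class GenotypeCall:
    """Copies of one alternate allele carried by one sample at one site."""

    allele_count: Optional[int]  # 0/1/2; None when missing
    depth: Optional[int]
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            self.allele_count = None
        elif self.allele_count not in (0, 1, 2):
            raise ValueError(f"allele_count must be 0/1/2, got {self.allele_count}")

    @property
    def carries_alt(self) -> bool:
        return bool(self.allele_count)


@dataclass
class PredictorVerdict:
    """Categorical verdicts of the four deleteriousness predictors.

    ``None`` means the tool produced no call for this variant.
    """

    sift: Optional[str] = None
    polyphen_hvar: Optional[str] = None
    polyphen_hdiv: Optional[str] = None
    mutation_taster: Optional[str] = None

    def __post_init__(self) -> None:
        for attr, codes in (
            ("sift", SIFT_CODES),
            ("polyphen_hvar", POLYPHEN_CODES),
            ("polyphen_hdiv", POLYPHEN_CODES),
            ("mutation_taster", MT_CODES),
        ):
            v = getattr(self, attr)
            if v is not None and v not in codes:
                raise ValueError(f"{attr} code {v!r} not in {sorted(codes)}")

    @property
    def all_absent(self) -> bool:
        return (
            self.sift is None
            and self.polyphen_hvar is None
            and self.polyphen_hdiv is None
            and self.mutation_taster is None
        )


@dataclass
class AnnotationBundle:
    gene: Optional[str] = None
    func_class: str = "other"
    exonic_func: str = "unknown"
    splice_distance: Optional[int] = None
    dbscsnv_scores: Optional[tuple[float, float]] = None
    in_repeat: bool = False
    af_fields: dict[str, Optional[float]] = field(default_factory=dict)
    predictor_verdicts: PredictorVerdict = field(default_factory=PredictorVerdict)
    cadd: Optional[float] = None
    gerp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(f"func_class {self.func_class!r}")
        if self.exonic_func not in EXONIC_FUNCS:
            raise ValueError(f"exonic_func {self.exonic_func!r}")
        for db, af in self.af_fields.items():
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValueError(f"AF out of [0,1] for {db}: {af}")


@dataclass
class VariantRecord:
    """One normalized alternate allele at one site, across all samples."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_qual: Optional[float]
    site_mq: Optional[float]
    genotypes: dict[str, GenotypeCall]
    annotation: AnnotationBundle

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError("ref and alt must be non-empty and different")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def sort_key(self) -> tuple[int, str, int, str, str]:
        return (*chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def on_x(self) -> bool:
        return normalize_chrom(self.chrom) == "X"


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str  # "male" | "female"
    affected: bool

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex {self.sex!r}")


class Pedigree:
    """Family structure with affected status; drives segregation logic."""

    def __init__(self, samples: list[SampleInfo]):
        self.samples = list(samples)
        self._by_id = {s.sample_id: s for s in self.samples}
        if len(self._by_id) != len(self.samples):
            raise PedigreeError("duplicate sample ids")
        self.families: dict[str, list[SampleInfo]] = {}
        for s in self.samples:
            self.families.setdefault(s.family_id, []).append(s)
        self._validate()

    def _validate(self) -> None:
        for s in self.samples:
            for pid in (s.father_id, s.mother_id):
                if pid is None:
                    continue
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeError(f"unknown parent {pid!r} of {s.sample_id}")
                if parent.family_id != s.family_id:
                    raise PedigreeError(
                        f"parent {pid} of {s.sample_id} is in another family"
                    )
        # no sample may be its own ancestor
        for s in self.samples:
            seen: set[str] = set()
            stack = [s.sample_id]
            while stack:
                cur = self._by_id[stack.pop()]
                for pid in (cur.father_id, cur.mother_id):
                    if pid is None:
                        continue
                    if pid == s.sample_id:
                        raise PedigreeError(f"cyclic parentage at {s.sample_id}")
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)
        for fam, members in self.families.items():
            if not any(m.affected for m in members):
                raise PedigreeError(f"family {fam} has no affected member")

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> SampleInfo:
        return self._by_id[sample_id]

    @property
    def affected(self) -> list[SampleInfo]:
        return [s for s in self.samples if s.affected]

    @property
    def unaffected(self) -> list[SampleInfo]:
        return [s for s in self.samples if not s.affected]

    def parents_of(
        self, sample_id: str
    ) -> tuple[Optional[SampleInfo], Optional[SampleInfo]]:
        s = self._by_id[sample_id]
        father = self._by_id.get(s.father_id) if s.father_id else None
        mother = self._by_id.get(s.mother_id) if s.mother_id else None
        return father, mother

    def is_trio(self, sample_id: str) -> bool:
        father, mother = self.parents_of(sample_id)
        return father is not None and mother is not None

    def is_singleton(self, sample_id: str) -> bool:
        """Affected sample with no sequenced relatives (sporadic case)."""
        s = self._by_id[sample_id]
        return s.affected and len(self.families[s.family_id]) == 1


@dataclass
class GenePanel:
    """Disease gene panel; per-gene sub-panel tag (CVID_OMIM or PID)."""

    name: str
    tags: dict[str, str]  # gene symbol (upper-case) -> tag

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.tags)

    def tag_of(self, gene: str) -> Optional[str]:
        return self.tags.get(gene.upper())

    def subset(self, tag: str) -> frozenset[str]:
        return frozenset(g for g, t in self.tags.items() if t == tag)


@dataclass(frozen=True)
class IntervalEvent:
    """A CNV or SV call in one sample; 0-based half-open coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    event_type: str
    source: str  # "CNV" | "SV"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start >= end: {self.start} >= {self.end}")
        if self.source not in ("CNV", "SV"):
            raise ValueError(f"source {self.source!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def group_key(self) -> tuple[str, str, str]:
        # events are only ever compared within the same chrom/type/source
        return (normalize_chrom(self.chrom), self.event_type, self.source)


# --------------------------------------------------------------------------
# VCF reading


def _parse_float(value) -> Optional[float]:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", ".", "NA", "nan"):
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _per_alt(value, alt_index: int, n_alts: int):
    """Per-allele INFO heuristic: split a comma list iff it has one entry
    per alternate allele, otherwise the value applies to every allele."""
    if value is None:
        return None
    s = str(value)
    if n_alts > 1 and s.count(",") == n_alts - 1:
        return s.split(",")[alt_index]
    return s


_FUNC_MAP = [("exonic", "exonic"), ("splicing", "splicing")]

_EXONIC_FUNC_MAP = {
    "nonsynonymous": "missense",
    "missense": "missense",
    "synonymous": "synonymous",
    "stopgain": "stopgain",
    "stoploss": "stoploss",
    "frameshift": "frameshift",
    "nonframeshift": "nonframeshift",
}


def _map_func(raw: Optional[str]) -> str:
    if raw is None:
        return "other"
    s = raw.lower()
    for needle, cls in _FUNC_MAP:
        if needle in s:
            return cls
    return "other"


def _map_exonic_func(raw: Optional[str]) -> str:
    if raw is None:
        return "unknown"
    s = raw.lower().replace(" ", "_")
    if s.startswith("nonframeshift"):
        return "nonframeshift"
    for needle, cls in _EXONIC_FUNC_MAP.items():
        if needle in s:
            return cls
    return "unknown"


def _code_or_none(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    s = str(value).strip()
    return s if s and s != "." else None


def read_vcf(
    path: str | Path,
    dialect: AnnotationDialect | None = None,
) -> Iterator[VariantRecord]:
    """Stream :class:`VariantRecord` from a multi-sample VCF.

    Multi-allelic rows are split into one record per alternate allele, each
    sample genotype re-coded as the number of copies of that allele.
    Unparseable AF fields become ABSENT (``None``). Records are yielded in
    file order.
    """
    dialect = dialect or AnnotationDialect()
    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    for idx, rec in enumerate(vcf, start=1):
        try:
            yield from _split_record(rec, samples, dialect)
        except Exception as exc:  # noqa: BLE001 - re-raise with location
            raise VcfParseError(
                f"{path}: malformed record #{idx} at "
                f"{rec.CHROM}:{rec.POS}: {exc}"
            ) from exc


def _split_record(
    rec, samples: list[str], dialect: AnnotationDialect
) -> Iterator[VariantRecord]:
    alts = list(rec.ALT)
    n_alts = len(alts)
    try:
        depths = rec.format("DP")
    except KeyError:
        depths = None
    genotype_rows = rec.genotypes  # [[a0, a1, phased], ...] per sample
    info = rec.INFO
    mq = _parse_float(info.get(dialect.mq))
    for k, alt in enumerate(alts):
        if alt in ("*", "<NON_REF>"):
            continue
        annotation = _build_annotation(info, dialect, k, n_alts)
        genotypes: dict[str, GenotypeCall] = {}
        for si, sample in enumerate(samples):
            row = genotype_rows[si]
            alleles = [a for a in row[:-1] if isinstance(a, int)]
            depth = None
            if depths is not None:
                d = int(depths[si][0]) if depths.ndim > 1 else int(depths[si])
                depth = d if d >= 0 else None
            if not alleles or any(a < 0 for a in alleles):
                genotypes[sample] = GenotypeCall(None, depth, missing=True)
            else:
                count = sum(1 for a in alleles if a == k + 1)
                # haploid calls (male X) are stored by raw copy number
                genotypes[sample] = GenotypeCall(min(count, 2), depth)
        yield VariantRecord(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF,
            alt=alt,
            site_qual=rec.QUAL,
            site_mq=mq,
            genotypes=genotypes,
            annotation=annotation,
        )


def _build_annotation(
    info, dialect: AnnotationDialect, k: int, n_alts: int
) -> AnnotationBundle:
    def get(key: str):
        return _per_alt(info.get(key), k, n_alts)

    af_fields = {db: _parse_float(get(key)) for db, key in dialect.af_keys.items()}
    verdict = PredictorVerdict(
        **{
            name: _code_or_none(get(key))
            for name, key in dialect.predictor_keys.items()
        }
    )
    ada = _parse_float(get(dialect.dbscsnv_ada))
    rf = _parse_float(get(dialect.dbscsnv_rf))
    dbscsnv = (ada, rf) if ada is not None and rf is not None else None
    splice_distance = _parse_float(get(dialect.splice_distance))
    gene = _code_or_none(get(dialect.gene))
    return AnnotationBundle(
        gene=gene.upper() if gene else None,
        func_class=_map_func(_code_or_none(get(dialect.func))),
        exonic_func=_map_exonic_func(_code_or_none(get(dialect.exonic_func))),
        splice_distance=int(splice_distance) if splice_distance is not None else None,
        dbscsnv_scores=dbscsnv,
        in_repeat=bool(info.get(dialect.in_repeat)),
        af_fields=af_fields,
        predictor_verdicts=verdict,
        cadd=_parse_float(get(dialect.cadd)),
        gerp=_parse_float(get(dialect.gerp)),
    )


# --------------------------------------------------------------------------
# VCF writing (deterministic plain-text emission; round-trips through the
# reader above)


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return "."
    return f"{x:.10g}"


_GT_BY_COUNT = {None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    samples: list[str],
    dialect: AnnotationDialect | None = None,
) -> None:
    """Write split biallelic records to a VCF v4.2 text file."""
    dialect = dialect or AnnotationDialect()
    records = sorted(records, key=lambda r: r.sort_key)
    contigs: list[str] = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    info_keys = (
        [dialect.gene, dialect.func, dialect.exonic_func, dialect.splice_distance]
        + list(dialect.af_keys.values())
        + list(dialect.predictor_keys.values())
        + [dialect.cadd, dialect.gerp, dialect.dbscsnv_ada, dialect.dbscsnv_rf]
    )
    for key in info_keys:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=String,Description="annotation">'
        )
    lines.append(
        f'##INFO=<ID={dialect.in_repeat},Number=0,Type=Flag,'
        'Description="RepeatMasker overlap">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for r in records:
        a = r.annotation
        info_parts = []
        if r.site_mq is not None:
            info_parts.append(f"MQ={_fmt(r.site_mq)}")
        info_parts.append(f"{dialect.gene}={a.gene or '.'}")
        info_parts.append(f"{dialect.func}={a.func_class}")
        info_parts.append(f"{dialect.exonic_func}={a.exonic_func}")
        if a.splice_distance is not None:
            info_parts.append(f"{dialect.splice_distance}={a.splice_distance}")
        for db, key in dialect.af_keys.items():
            info_parts.append(f"{key}={_fmt(a.af_fields.get(db))}")
        pv = a.predictor_verdicts
        for name, key in dialect.predictor_keys.items():
            info_parts.append(f"{key}={getattr(pv, name) or '.'}")
        info_parts.append(f"{dialect.cadd}={_fmt(a.cadd)}")
        info_parts.append(f"{dialect.gerp}={_fmt(a.gerp)}")
        if a.dbscsnv_scores is not None:
            info_parts.append(f"{dialect.dbscsnv_ada}={_fmt(a.dbscsnv_scores[0])}")
            info_parts.append(f"{dialect.dbscsnv_rf}={_fmt(a.dbscsnv_scores[1])}")
        if a.in_repeat:
            info_parts.append(dialect.in_repeat)
        cols = [
            r.chrom,
            str(r.pos),
            ".",
            r.ref,
            r.alt,
            _fmt(r.site_qual),
            "PASS",
            ";".join(info_parts),
            "GT:DP",
        ]
        for s in samples:
            g = r.genotypes.get(s, GenotypeCall(None, None, missing=True))
            dp = str(g.depth) if g.depth is not None else "."
            cols.append(f"{_GT_BY_COUNT[g.allele_count]}:{dp}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# PED / panel / GMT / BED / event tables

_SEX_MAP = {"1": "male", "2": "female", "M": "male", "F": "female"}


def read_ped(path: str | Path) -> Pedigree:
    """Parse a 6-column PED file (family, sample, father, mother, sex,
    phenotype; phenotype 2 = affected)."""
    samples: list[SampleInfo] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise PedigreeError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
        fam, sid, father, mother, sex, pheno = parts[:6]
        sex_label = _SEX_MAP.get(sex.upper())
        if sex_label is None:
            raise PedigreeError(f"{path}:{ln}: bad sex code {sex!r}")
        samples.append(
            SampleInfo(
                sample_id=sid,
                family_id=fam,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=sex_label,
                affected=pheno == "2",
            )
        )
    if not samples:
        raise PedigreeError(f"{path}: empty PED file")
    return Pedigree(samples)


def read_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """One gene symbol per line, optional tab-separated sub-panel tag
    (defaults to ``PID``). Symbols are upper-cased and deduplicated; a
    CVID_OMIM tag wins over PID on duplicates."""
    tags: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        gene = parts[0].strip().upper()
        tag = parts[1].strip() if len(parts) > 1 and parts[1].strip() else "PID"
        if tags.get(gene) != "CVID_OMIM":
            tags[gene] = tag
    if not tags:
        raise ValueError(f"{path}: empty gene panel")
    return GenePanel(name=name or Path(path).stem, tags=tags)


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Standard GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, frozenset[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs >= 3 columns")
        name = parts[0]
        sets[name] = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """BED3+ intervals (0-based half-open) into per-chromosome trees."""
    trees: dict[str, IntervalTree] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        trees.setdefault(normalize_chrom(chrom), IntervalTree()).addi(
            int(start), int(end)
        )
    return trees


def annotate_repeats(
    records: Iterable[VariantRecord], repeat_trees: dict[str, IntervalTree]
) -> None:
    """Set ``in_repeat`` from RepeatMasker-style BED intervals (in place)."""
    for r in records:
        tree = repeat_trees.get(normalize_chrom(r.chrom))
        if tree is None:
            continue
        start0 = r.pos - 1
        r.annotation.in_repeat = bool(tree.overlap(start0, start0 + len(r.ref)))


_EVENT_COLUMNS = ["sample", "chrom", "start", "end", "type", "source"]


def read_events(
    path: str | Path,
) -> tuple[list[IntervalEvent], list[tuple[int, str]]]:
    """Read a CNV/SV event table (TSV, 0-based half-open coordinates).

    Returns the validated events sorted by (chrom, start, end) and a list of
    ``(line_number, reason)`` for rejected rows. Duplicate identical rows are
    kept; same-sample duplicates collapse later during clustering.
    """
    events: list[IntervalEvent] = []
    rejected: list[tuple[int, str]] = []
    header_seen = False
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            m = re.search(r"coords\s*[:=]\s*(\S.*)", stripped)
            if m and "0-based" not in m.group(1):
                raise ValueError(
                    f"{path}:{ln}: event tables must declare 0-based half-open "
                    f"coordinates, got {m.group(1)!r}"
                )
            continue
        parts = stripped.split("\t")
        if not header_seen:
            if [p.lower() for p in parts[:6]] != _EVENT_COLUMNS:
                raise ValueError(
                    f"{path}:{ln}: expected header {_EVENT_COLUMNS}, got {parts[:6]}"
                )
            header_seen = True
            continue
        if len(parts) < 6:
            rejected.append((ln, "too_few_columns"))
            continue
        sample, chrom, start, end, etype, source = parts[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            rejected.append((ln, "non_integer_coordinates"))
            continue
        if start_i >= end_i:
            rejected.append((ln, "start_not_before_end"))
            continue
        try:
            events.append(
                IntervalEvent(sample, chrom, start_i, end_i, etype, source)
            )
        except ValueError as exc:
            rejected.append((ln, str(exc)))
    events.sort(key=lambda e: (*chrom_sort_key(e.chrom), e.start, e.end))
    return events, rejected


def write_events(events: Iterable[IntervalEvent], path: str | Path) -> None:
    lines = ["# coords: 0-based half-open", "\t".join(_EVENT_COLUMNS)]
    for e in events:
        lines.append(
            f"{e.sample_id}\t{e.chrom}\t{e.start}\t{e.end}\t{e.event_type}\t{e.source}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
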