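"""CNV/SV co-occurrence analysis.

Two events of the same chromosome, type and source are "the same" when
their reciprocal overlap exceeds 50%: min(overlap/len(a), overlap/len(b))
> 0.5, strictly. Cross-sample clusters are the connected components of
this pairwise relation (single linkage, so a cluster may contain pairs
below the bound via chaining; a strict clique mode is available). The
recurrence screen keeps clusters seen in at least two patients and in no
unaffected individual. CNVs and SVs are clustered separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import median_low
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .io import IntervalEvent, Pedigree, chrom_sort_key


def reciprocal_overlap(a: IntervalEvent, b: IntervalEvent) -> tuple[float, float]:
    """Overlap fractions (overlap/len(a), overlap/len(b)) on half-open
    intervals; events on different chrom/type/source never overlap."""
    if a.group_key != b.group_key:
        return (0.0, 0.0)
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return (0.0, 0.0)
    return (overlap / a.length, overlap / b.length)


def same_event(a: IntervalEvent, b: IntervalEvent, min_fraction: float = 0.5) -> bool:
    """Strict reciprocal-overlap predicate: min fraction must exceed 50%."""
    fa, fb = reciprocal_overlap(a, b)
    return min(fa, fb) > min_fraction


@dataclass
class EventCluster:
    members: list[IntervalEvent]
    region_label: str = "unknown"  # exonic | intronic/intergenic | unknown

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty cluster")
        if len({m.group_key for m in self.members}) != 1:
            raise ValueError("cluster mixes chrom/type/source")
        self.members.sort(key=lambda e: (e.start, e.end, e.sample_id))

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def event_type(self) -> str:
        return self.members[0].event_type

    @property
    def source(self) -> str:
        return self.members[0].source

    @property
    def representative(self) -> tuple[int, int]:
        """Median start / median end over members (robust to chaining)."""
        return (
            median_low([m.start for m in self.members]),
            median_low([m.end for m in self.members]),
        )

    @property
    def sample_ids(self) -> frozenset[str]:
        return frozenset(m.sample_id for m in self.members)

    def patient_count(self, pedigree: Pedigree) -> int:
        """Distinct affected carriers (samples, not events)."""
        return sum(1 for s in self.sample_ids if s in pedigree and pedigree[s].affected)

    def control_count(self, pedigree: Pedigree) -> int:
        return sum(
            1 for s in self.sample_ids if s in pedigree and not pedigree[s].affected
        )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_events(
    events: Iterable[IntervalEvent], *, mode: str = "single_linkage"
) -> list[EventCluster]:
    """Group events into clusters under the same-event predicate.

    ``single_linkage`` (default): connected components. ``clique``: greedy
    refinement in which every member pair must satisfy the predicate
    (deterministic, seeded by sorted order).
    """
    if mode not in ("single_linkage", "clique"):
        raise ValueError(f"unknown mode {mode!r}")
    # identical rows from the same sample collapse here (one carrier, one
    # event); identical coordinates in different samples stay distinct
    events = sorted(
        set(events),
        key=lambda e: (*chrom_sort_key(e.chrom), e.start, e.end, e.sample_id),
    )
    # groups never compared across chrom/type/source
    groups: dict[tuple, list[IntervalEvent]] = {}
    for e in events:
        groups.setdefault(e.group_key, []).append(e)
    clusters: list[EventCluster] = []
    for key in sorted(groups):
        members = groups[key]
        uf = _UnionFind(len(members))
        # sorted sweep: b.start is non-decreasing; stop once no overlap
        for i, a in enumerate(members):
            for j in range(i + 1, len(members)):
                b = members[j]
                if b.start >= a.end:
                    break
                if same_event(a, b):
                    uf.union(i, j)
        comp: dict[int, list[IntervalEvent]] = {}
        for i, e in enumerate(members):
            comp.setdefault(uf.find(i), []).append(e)
        for root in sorted(comp):
            if mode == "clique":
                clusters.extend(_split_cliques(comp[root]))
            else:
                clusters.append(EventCluster(members=comp[root]))
    clusters.sort(
        key=lambda c: (*chrom_sort_key(c.chrom), c.representative, c.event_type)
    )
    return clusters


def _split_cliques(members: list[IntervalEvent]) -> list[EventCluster]:
    """Greedy clique partition of one connected component."""
    remaining = sorted(members, key=lambda e: (e.start, e.end, e.sample_id))
    out: list[EventCluster] = []
    while remaining:
        seed = remaining.pop(0)
        clique = [seed]
        rest: list[IntervalEvent] = []
        for e in remaining:
            if all(same_event(e, m) for m in clique):
                clique.append(e)
            else:
                rest.append(e)
        remaining = rest
        out.append(EventCluster(members=clique))
    return out


def recurrence_screen(
    clusters: Iterable[EventCluster], pedigree: Pedigree
) -> tuple[list[EventCluster], list[EventCluster]]:
    """Keep clusters shared by >= 2 patients and absent from all controls.

    Returns (kept, dropped); kept + dropped partitions the input.
    """
    kept, dropped = [], []
    for c in clusters:
        if c.patient_count(pedigree) >= 2 and c.control_count(pedigree) == 0:
            kept.append(c)
        else:
            dropped.append(c)
    return kept, dropped


def annotate_exon_overlap(
    clusters: Iterable[EventCluster],
    exon_trees: Optional[dict[str, IntervalTree]],
) -> list[EventCluster]:
    """Label clusters exonic iff the representative interval intersects any
    exon by >= 1 bp; without an exon BED everything stays "unknown"."""
    out = []
    for c in clusters:
        if exon_trees is None:
            c.region_label = "unknown"
        else:
            from .io import normalize_chrom

            tree = exon_trees.get(normalize_chrom(c.chrom))
            start, end = c.representative
            hit = bool(tree is not None and tree.overlap(start, end))
            c.region_label = "exonic" if hit else "intronic/intergenic"
        out.append(c)
    return out


def write_cluster_report(
    clusters: Iterable[EventCluster], pedigree: Pedigree, path: str | Path
) -> None:
    lines = [
        "chrom\tstart\tend\ttype\tsource\tn_members\tpatients\tcontrols"
        "\tregion\tsamples"
    ]
    for c in clusters:
        start, end = c.representative
        lines.append(
            f"{c.chrom}\t{start}\t{end}\t{c.event_type}\t{c.source}"
            f"\t{len(c.members)}\t{c.patient_count(pedigree)}"
            f"\t{c.control_count(pedigree)}\t{c.region_label}"
            f"\t{','.join(sorted(c.sample_ids))}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
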