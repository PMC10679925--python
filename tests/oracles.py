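"""Independent straight-line oracles used by the test suite.

These deliberately re-derive the rules in one pass of plain conditionals,
without calling the package's staged implementation, so the cascade and the
clustering can be checked against a second, independent route.
"""

from __future__ import annotations

from itertools import combinations


def straight_line_pass(v, sample, t) -> bool:
    """One-expression re-evaluation of the whole filtering cascade."""
    g = v.genotypes.get(sample)
    if g is None or g.missing or g.depth is None:
        return False
    if not (g.depth > t.min_depth):
        return False
    if v.site_mq is None or not (v.site_mq > t.min_mq):
        return False
    if v.site_qual is None or not (v.site_qual > t.min_qual):
        return False
    a = v.annotation
    if a.func_class == "exonic":
        pass
    elif a.func_class == "splicing":
        if a.splice_distance is not None and a.splice_distance > t.splice_window_bp:
            return False
    else:
        return False
    if a.exonic_func == "synonymous":
        if a.dbscsnv_scores is None or max(a.dbscsnv_scores) < t.dbscsnv_splice_cutoff:
            return False
    length = abs(len(v.ref) - len(v.alt))
    if length and length % 3 == 0 and length < t.indel_repeat_max_len and a.in_repeat:
        return False
    if any(af is not None and af >= t.max_af for af in a.af_fields.values()):
        return False
    if a.func_class != "splicing" and a.exonic_func == "missense":
        pv = a.predictor_verdicts
        votes = (
            int(pv.sift == "D")
            + int(pv.polyphen_hvar in ("D", "P") or pv.polyphen_hdiv in ("D", "P"))
            + int(pv.mutation_taster in ("D", "A"))
            + int(v.annotation.cadd is not None
                  and v.annotation.cadd >= t.cadd_deleterious_cutoff)
        )
        if votes < t.retain_min_votes:
            return False
    return True


def brute_force_components(events) -> list[frozenset]:
    """Connected components over the pairwise same-event predicate by
    explicit O(n^2) adjacency and breadth-first search."""
    from triovar.svoverlap import same_event

    events = list(dict.fromkeys(events))
    n = len(events)
    adj = {i: set() for i in range(n)}
    for i, j in combinations(range(n), 2):
        if same_event(events[i], events[j]):
            adj[i].add(j)
            adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        queue, comp = [i], set()
        while queue:
            k = queue.pop()
            if k in comp:
                continue
            comp.add(k)
            queue.extend(adj[k] - comp)
        seen |= comp
        comps.append(frozenset(events[k] for k in comp))
    return comps


def brute_force_trans_pairs(variants, proband_id, father_id, mother_id):
    """All trans het pairs by exhaustive enumeration over genotype columns."""

    def count(v, sid):
        g = v.genotypes.get(sid)
        return None if g is None or g.missing else g.allele_count

    pairs = set()
    for a, b in combinations(variants, 2):
        if a.annotation.gene != b.annotation.gene:
            continue
        if count(a, proband_id) != 1 or count(b, proband_id) != 1:
            continue
        def origin(v):
            fa, mo = count(v, father_id), count(v, mother_id)
            if fa and not mo:
                return "father"
            if mo and not fa:
                return "mother"
            return None
        oa, ob = origin(a), origin(b)
        if oa and ob and oa != ob:
            pairs.add(frozenset((a.key, b.key)))
    return pairs


def exact_hypergeom_sf(k: int, background: int, set_size: int, query: int):
    """P(X >= k) for X ~ Hypergeom, via exact rational combinatorics."""
    from fractions import Fraction
    from math import comb

    hi = min(set_size, query)
    total = comb(background, query)
    acc = Fraction(0)
    for x in range(k, hi + 1):
        acc += Fraction(comb(set_size, x) * comb(background - set_size, query - x), total)
    return acc
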