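"""Ancestral-karyotype projection (chromosome painting) and rearrangement
classification.

Each extant chromosome is partitioned into segments assigned to the
proto-chromosome of an ancestral karyotype that contributes the majority of
synteny anchors in that region.  The ordered segment signature of a
chromosome then reveals its fusion history:

* ``X-Y-X`` with a complete nested donor Y  ->  nested chromosome fusion
  (NCF) of Y into X;
* ``X-Y`` where both protos reach their own termini at the junction  ->
  end-to-end joining (EEJ);
* a proto split over two chromosomes that reciprocally exchange arms  ->
  one reciprocal arm translocation (RTA), count-neutral;
* a proto split without reciprocity  ->  fission.

The chromosome-count arithmetic n_extant = n_proto - #EEJ - #NCF + #FISSION
is emitted with every classification as an internal consistency check.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .genome_model import GenomeTable, KaryotypeMap, ValidationError
from .ploidy import self_depth_mode
from .synteny import SyntenyBlock

__all__ = [
    "PaintedSegment",
    "KaryotypePainting",
    "RearrangementEvent",
    "paint_chromosomes",
    "classify_events",
    "reconstruct_ancestor",
    "trajectory_report",
    "proto_lengths_from_proxy",
]


@dataclass
class PaintedSegment:
    chromosome: str
    rank_start: int
    rank_end: int
    proto: str
    orientation: str  # "parallel" | "antiparallel"
    support: int  # anchor count
    proto_lo: int  # half-open interval covered on the proto's own rank axis
    proto_hi: int


@dataclass
class KaryotypePainting:
    genome_id: str
    ancestor_id: str
    segments: dict[str, list[PaintedSegment]]
    proto_lengths: dict[str, int]

    def proto_of(self, chromosome: str, rank: int) -> str | None:
        for seg in self.segments.get(chromosome, []):
            if seg.rank_start <= rank < seg.rank_end:
                return seg.proto
        return None


@dataclass
class RearrangementEvent:
    kind: str  # EEJ | NCF | RTA | FISSION | UNRESOLVED
    protos: tuple[str, ...]
    chromosome: str  # extant chromosome (or "a+b" for paired RTA)
    evidence: str


def proto_lengths_from_proxy(
    proxy: GenomeTable, kmap: KaryotypeMap | None = None
) -> dict[str, int]:
    """Gene count per proto-chromosome of an ancestor proxy genome.  Without
    a map, proxy chromosome names are taken as the proto ids."""
    out: dict[str, int] = defaultdict(int)
    if kmap is None:
        for chrom in proxy.chromosomes:
            out[chrom] = len(proxy.chromosome_genes(chrom))
    else:
        for gid, chrom, lo, hi, proto in kmap.segment_assignments:
            out[proto] += hi - lo
    return dict(out)


def paint_chromosomes(
    blocks: Sequence[SyntenyBlock],
    extant: GenomeTable,
    ancestor_proxy: GenomeTable,
    kmap: KaryotypeMap | None = None,
    min_paint: int = 3,
    min_segment_genes: int = 10,
) -> KaryotypePainting:
    """Partition each extant chromosome into proto-chromosome segments.

    ``blocks`` must have the extant genome on the A axis and the ancestor
    proxy on the B axis.  Anchor runs below ``min_segment_genes`` ranks or
    ``min_paint`` anchors are merged into the flanking segment with more
    anchors (ties toward the preceding segment); segment bounds are then
    stretched to cover every rank.
    """

    def proto_and_rank(chrom_b: str, rank_b: int) -> tuple[str, int] | None:
        if kmap is None:
            return chrom_b, rank_b
        for gid, chrom, lo, hi, proto in kmap.segment_assignments:
            if chrom == chrom_b and lo <= rank_b < hi:
                return proto, rank_b - lo
        return None

    per_chrom: dict[str, list[tuple[int, str, int]]] = defaultdict(list)
    for b in blocks:
        for a in b.anchors:
            pr = proto_and_rank(a.chrom_b, a.rank_b)
            if pr is None:
                raise ValidationError(
                    f"ancestor position {a.chrom_b}:{a.rank_b} lacks a proto assignment"
                )
            per_chrom[a.chrom_a].append((a.rank_a, pr[0], pr[1]))
    proto_lengths = proto_lengths_from_proxy(ancestor_proxy, kmap)
    segments: dict[str, list[PaintedSegment]] = {}
    for chrom in extant.chromosomes:
        anchors = sorted(per_chrom.get(chrom, []))
        n_genes = len(extant.chromosome_genes(chrom))
        if not anchors:
            segments[chrom] = []
            continue
        # collapse colliding ranks: keep one proto vote per extant rank
        dedup: list[tuple[int, str, int]] = []
        for rank_a, proto, rank_p in anchors:
            if dedup and dedup[-1][0] == rank_a:
                continue
            dedup.append((rank_a, proto, rank_p))
        runs = _compress_runs(chrom, dedup)
        runs = _merge_small_runs(runs, min_paint, min_segment_genes)
        runs = _stretch(runs, n_genes)
        segments[chrom] = runs
    return KaryotypePainting(
        genome_id=extant.genome_id,
        ancestor_id=ancestor_proxy.genome_id,
        segments=segments,
        proto_lengths=proto_lengths,
    )


def _compress_runs(
    chrom: str, anchors: list[tuple[int, str, int]]
) -> list[PaintedSegment]:
    runs: list[PaintedSegment] = []
    start = 0
    for i in range(1, len(anchors) + 1):
        if i == len(anchors) or anchors[i][1] != anchors[start][1]:
            chunk = anchors[start:i]
            p_ranks = [r for _, _, r in chunk]
            orientation = (
                "antiparallel" if len(chunk) > 1 and p_ranks[-1] < p_ranks[0] else "parallel"
            )
            runs.append(
                PaintedSegment(
                    chromosome=chrom,
                    rank_start=chunk[0][0],
                    rank_end=chunk[-1][0] + 1,
                    proto=chunk[0][1],
                    orientation=orientation,
                    support=len(chunk),
                    proto_lo=min(p_ranks),
                    proto_hi=max(p_ranks) + 1,
                )
            )
            start = i
    return runs


def _merge_small_runs(
    runs: list[PaintedSegment], min_paint: int, min_segment_genes: int
) -> list[PaintedSegment]:
    def weak(seg: PaintedSegment) -> bool:
        return seg.support < min_paint or (seg.rank_end - seg.rank_start) < min_segment_genes

    runs = list(runs)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, seg in enumerate(runs):
            if not weak(seg):
                continue
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i + 1 < len(runs) else None
            target = None
            if left is not None and right is not None:
                target = left if left.support >= right.support else right
            else:
                target = left or right
            if target is None:
                break
            # absorb the weak run's extant span into the stronger neighbour
            if target is left:
                left_new = replace(left, rank_end=seg.rank_end, support=left.support)
                runs[i - 1] = left_new
            else:
                runs[i + 1] = replace(right, rank_start=seg.rank_start)
            del runs[i]
            changed = True
            break
        # coalesce neighbours that now share a proto
        j = 0
        while j + 1 < len(runs):
            a, b = runs[j], runs[j + 1]
            if a.proto == b.proto:
                runs[j] = PaintedSegment(
                    chromosome=a.chromosome,
                    rank_start=a.rank_start,
                    rank_end=b.rank_end,
                    proto=a.proto,
                    orientation=a.orientation if a.support >= b.support else b.orientation,
                    support=a.support + b.support,
                    proto_lo=min(a.proto_lo, b.proto_lo),
                    proto_hi=max(a.proto_hi, b.proto_hi),
                )
                del runs[j + 1]
                changed = True
            else:
                j += 1
    return runs


def _stretch(runs: list[PaintedSegment], n_genes: int) -> list[PaintedSegment]:
    if not runs:
        return runs
    out = []
    for i, seg in enumerate(runs):
        lo = 0 if i == 0 else runs[i - 1].rank_end
        hi = n_genes if i == len(runs) - 1 else seg.rank_end
        out.append(replace(seg, rank_start=min(seg.rank_start, lo) if i == 0 else lo, rank_end=hi))
    return out


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------

@dataclass
class _Elem:
    protos: list[str]
    left_proto: str
    left_term: bool
    right_proto: str
    right_term: bool
    complete: bool  # covers (nearly) the whole proto: both ends terminal
    signature: str


def _segment_elem(seg: PaintedSegment, proto_len: int, w: int) -> _Elem:
    lo_term = seg.proto_lo < w
    hi_term = seg.proto_hi > proto_len - w
    if seg.orientation == "parallel":
        left_term, right_term = lo_term, hi_term
    else:
        left_term, right_term = hi_term, lo_term
    return _Elem(
        protos=[seg.proto],
        left_proto=seg.proto,
        left_term=left_term,
        right_proto=seg.proto,
        right_term=right_term,
        complete=lo_term and hi_term,
        signature=seg.proto,
    )


def classify_events(
    painting: KaryotypePainting,
    telomere_window: int = 5,
    min_support: int = 3,
) -> tuple[list[RearrangementEvent], dict]:
    """Classify the fusion/translocation history recorded in a painting.

    Returns the event list and the chromosome-count arithmetic check
    ``n_extant = n_proto - #EEJ - #NCF + #FISSION``; chromosomes whose
    signature cannot be reduced are reported UNRESOLVED and the check is
    flagged unbalanced.
    """
    events: list[RearrangementEvent] = []
    leftovers: dict[str, list[_Elem]] = {}
    for chrom in sorted(painting.segments):
        segs = [s for s in painting.segments[chrom] if s.support >= min_support]
        if not segs:
            continue
        elems = [
            _segment_elem(s, painting.proto_lengths.get(s.proto, 0), telomere_window)
            for s in segs
        ]
        changed = True
        while len(elems) > 1 and changed:
            changed = False
            # nested fusion: complete donor with one host proto on both sides
            for i in range(1, len(elems) - 1):
                d, l, r = elems[i], elems[i - 1], elems[i + 1]
                if (
                    len(d.protos) == 1
                    and d.complete
                    and l.right_proto == r.left_proto
                    and d.protos[0] != l.right_proto
                ):
                    events.append(
                        RearrangementEvent(
                            "NCF", (d.protos[0], l.right_proto), chrom,
                            f"{l.right_proto}-{d.protos[0]}-{r.left_proto}",
                        )
                    )
                    merged = _Elem(
                        protos=l.protos + r.protos,
                        left_proto=l.left_proto,
                        left_term=l.left_term,
                        right_proto=r.right_proto,
                        right_term=r.right_term,
                        complete=l.left_term and r.right_term,
                        signature=l.signature + "/" + r.signature,
                    )
                    elems[i - 1 : i + 2] = [merged]
                    changed = True
                    break
            if changed:
                continue
            # end-to-end joining: terminal-terminal junction of two protos
            for i in range(len(elems) - 1):
                l, r = elems[i], elems[i + 1]
                if l.right_proto != r.left_proto and l.right_term and r.left_term:
                    events.append(
                        RearrangementEvent(
                            "EEJ", (l.right_proto, r.left_proto), chrom,
                            f"{l.signature}+{r.signature}",
                        )
                    )
                    merged = _Elem(
                        protos=l.protos + r.protos,
                        left_proto=l.left_proto,
                        left_term=l.left_term,
                        right_proto=r.right_proto,
                        right_term=r.right_term,
                        complete=l.left_term and r.right_term,
                        signature=l.signature + "+" + r.signature,
                    )
                    elems[i : i + 2] = [merged]
                    changed = True
                    break
        if len(elems) > 1:
            leftovers[chrom] = elems

    # reciprocity analysis over chromosomes that did not reduce to one unit
    proto_sites: dict[str, list[str]] = defaultdict(list)
    for chrom, elems in leftovers.items():
        for e in elems:
            for p in e.protos:
                proto_sites[p].append(chrom)
    handled: set[str] = set()
    chroms = sorted(leftovers)
    for i, c1 in enumerate(chroms):
        if c1 in handled:
            continue
        for c2 in chroms[i + 1 :]:
            if c2 in handled:
                continue
            p1 = {p for e in leftovers[c1] for p in e.protos}
            p2 = {p for e in leftovers[c2] for p in e.protos}
            common = p1 & p2
            if (
                len(common) == 2
                and len(leftovers[c1]) == 2
                and len(leftovers[c2]) == 2
                and p1 == p2
            ):
                pa, pb = sorted(common)
                events.append(
                    RearrangementEvent(
                        "RTA", (pa, pb), f"{c1}+{c2}",
                        f"{c1}:{'/'.join(e.signature for e in leftovers[c1])} ~ "
                        f"{c2}:{'/'.join(e.signature for e in leftovers[c2])}",
                    )
                )
                handled.update((c1, c2))
                break
    for chrom in chroms:
        if chrom in handled:
            continue
        elems = leftovers[chrom]
        split = [
            p for e in elems for p in e.protos if len(set(proto_sites[p])) > 1
        ]
        if split:
            for p in sorted(set(split)):
                events.append(
                    RearrangementEvent(
                        "FISSION", (p,), chrom,
                        "/".join(e.signature for e in elems),
                    )
                )
        else:
            events.append(
                RearrangementEvent(
                    "UNRESOLVED",
                    tuple(sorted({p for e in elems for p in e.protos})),
                    chrom,
                    "/".join(e.signature for e in elems),
                )
            )

    n_proto = len(painting.proto_lengths)
    n_extant = sum(1 for c in painting.segments if painting.segments[c])
    counts = {"EEJ": 0, "NCF": 0, "RTA": 0, "FISSION": 0, "UNRESOLVED": 0}
    for e in events:
        counts[e.kind] += 1
    # fission counts proto splits; RTA is paired over two chromosomes already
    expected = n_proto - counts["EEJ"] - counts["NCF"] + counts["FISSION"]
    arithmetic = {
        "n_proto": n_proto,
        "n_extant": n_extant,
        **counts,
        "expected_n": expected,
        "balanced": expected == n_extant and counts["UNRESOLVED"] == 0,
    }
    return events, arithmetic


# ---------------------------------------------------------------------------
# Ancestor reconstruction from a conserved post-WGD genome
# ---------------------------------------------------------------------------

def _merge_intervals(
    ivals: list[tuple[int, int]], strict: bool = True
) -> list[tuple[int, int]]:
    """Merge overlapping intervals; with ``strict`` only genuine overlaps
    merge (touching intervals stay apart — a fusion junction is a touch)."""
    merged: list[list[int]] = []
    for lo, hi in sorted(ivals):
        if merged and (lo < merged[-1][1] if strict else lo <= merged[-1][1]):
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def reconstruct_ancestor(
    conserved: GenomeTable,
    self_blocks: Sequence[SyntenyBlock],
    multiplicity: int,
    wgd_age: float | None = None,
    age_window: float = 0.2,
    outgroup_blocks: Sequence[SyntenyBlock] | None = None,
    min_collinear_fraction: float = 0.6,
    min_block_size: int = 5,
    karyotype_id: str = "ANC",
) -> tuple[KaryotypeMap, dict]:
    """Reconstruct an ancestral karyotype from the self-synteny of a genome
    that retains ``multiplicity`` complete copies of it.

    Step 1 verifies the multiplicity from the intra-genomic modal depth.
    Step 2 groups the homeologous block network into proto-chromosomes:
    block-side intervals on each chromosome are merged into regions, every
    block connects its two regions, and the connected components of that
    graph (restricted to blocks at the WGD's Ks age, when given) are the
    proto-chromosomes; each is ordered by its most anchor-rich copy.
    Step 3 validates that every proto has ``multiplicity`` copies (median
    family copy count) and, when outgroup blocks are supplied, that the
    proto is collinear with the outgroup over at least
    ``min_collinear_fraction`` of its families.
    """
    observed = self_depth_mode(self_blocks, conserved, min_block_size) + 1
    if observed != multiplicity:
        raise ValidationError(
            f"intra-genomic modal depth implies multiplicity {observed}, "
            f"claimed {multiplicity}"
        )
    blocks = [b for b in self_blocks if b.anchor_count >= min_block_size]
    if wgd_age is not None:
        blocks = [
            b for b in blocks
            if b.median_ks is None or abs(b.median_ks - wgd_age) <= age_window
        ]
    # region nodes: strictly-overlap-merged block-side intervals, then
    # adjacency merging restricted to regions sharing a partner chromosome
    # (continuity on an intact copy spans a partner's fusion junction, while
    # the junction itself joins regions with different partners)
    side_ivals: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for b in blocks:
        side_ivals[b.chrom_a].append(b.span_a)
        side_ivals[b.chrom_b].append(b.span_b)
    regions: dict[str, list[tuple[int, int]]] = {
        c: _merge_intervals(v, strict=True) for c, v in side_ivals.items()
    }

    def region_of(chrom: str, span: tuple[int, int]) -> tuple[str, int, int]:
        mid = (span[0] + span[1]) // 2
        for lo, hi in regions[chrom]:
            if lo <= mid < hi:
                return (chrom, lo, hi)
        raise AssertionError("block span not inside its merged region")

    adjacency_gap = 25
    while True:
        partners: dict[tuple[str, int, int], set[str]] = defaultdict(set)
        for b in blocks:
            ra = region_of(b.chrom_a, b.span_a)
            rb = region_of(b.chrom_b, b.span_b)
            partners[ra].add(rb[0])
            partners[rb].add(ra[0])
        changed = False
        for chrom, ivals in regions.items():
            for i in range(len(ivals) - 1):
                (lo1, hi1), (lo2, hi2) = ivals[i], ivals[i + 1]
                if lo2 - hi1 > adjacency_gap:
                    continue
                if partners[(chrom, lo1, hi1)] & partners[(chrom, lo2, hi2)]:
                    regions[chrom] = (
                        ivals[: i] + [(lo1, hi2)] + ivals[i + 2 :]
                    )
                    changed = True
                    break
            if changed:
                break
        if not changed:
            break

    g = nx.Graph()
    for b in blocks:
        ra = region_of(b.chrom_a, b.span_a)
        rb = region_of(b.chrom_b, b.span_b)
        g.add_edge(ra, rb)
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    proto_ids = [f"{karyotype_id}{i + 1:02d}" for i in range(len(components))]
    segs: list[tuple[str, str, int, int, str]] = []
    report: dict = {"protos": {}, "failures": []}
    # families covered by outgroup synteny, for validation
    out_syntenic: set[str] = set()
    if outgroup_blocks is not None:
        for b in outgroup_blocks:
            if b.anchor_count < min_block_size:
                continue
            for a in b.anchors:
                if a.gene_a in conserved:
                    fam = conserved.gene(a.gene_a).family_id
                    if fam:
                        out_syntenic.add(fam)
    comp_index = {region: i for i, comp in enumerate(components) for region in comp}
    comp_blocks: dict[int, list[SyntenyBlock]] = defaultdict(list)
    for b in blocks:
        comp_blocks[comp_index[region_of(b.chrom_a, b.span_a)]].append(b)
    for idx, (proto, comp) in enumerate(zip(proto_ids, components)):
        fams: dict[str, int] = defaultdict(int)
        for chrom, lo, hi in comp:
            segs.append((conserved.genome_id, chrom, lo, hi, proto))
            for gene in conserved.chromosome_genes(chrom)[lo:hi]:
                if gene.family_id:
                    fams[gene.family_id] += 1
        # proto copy number: modal block coverage (either axis) of this
        # component's genes, +1 for the copy a gene itself sits on
        spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for b in comp_blocks.get(idx, []):
            spans[b.chrom_a].append(b.span_a)
            spans[b.chrom_b].append(b.span_b)
        depths = []
        for chrom, lo, hi in comp:
            for gene in conserved.chromosome_genes(chrom)[lo:hi]:
                d = sum(1 for s_lo, s_hi in spans[chrom] if s_lo <= gene.rank < s_hi)
                if d >= 1:
                    depths.append(d)
        from collections import Counter as _Counter

        copies = (
            _Counter(depths).most_common(1)[0][0] + 1 if depths else 1
        )
        entry = {
            "regions": len(comp),
            "families": len(fams),
            "copy_count": copies,
        }
        if copies != multiplicity:
            report["failures"].append(
                f"{proto}: modal copy count {copies} != {multiplicity}"
            )
        if outgroup_blocks is not None and fams:
            frac = sum(1 for f in fams if f in out_syntenic) / len(fams)
            entry["outgroup_collinear_fraction"] = frac
            if frac < min_collinear_fraction:
                report["failures"].append(
                    f"{proto}: outgroup collinearity {frac:.2f} < {min_collinear_fraction}"
                )
        report["protos"][proto] = entry
    report["n_protos"] = len(proto_ids)
    report["valid"] = not report["failures"]
    kmap = KaryotypeMap(karyotype_id, proto_ids, segs)
    return kmap, report


def trajectory_report(
    classified: Mapping[str, tuple[list[RearrangementEvent], dict]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-lineage event comparison against one shared ancestor.

    Returns (per-lineage summary, shared-event table).  Events are keyed by
    (kind, involved protos); keys observed in two or more lineages are
    candidate events that predate the corresponding splits.
    """
    rows = []
    key_lineages: dict[tuple, list[str]] = defaultdict(list)
    for lineage in sorted(classified):
        events, arithmetic = classified[lineage]
        rows.append(
            {
                "lineage": lineage,
                "EEJ": arithmetic["EEJ"],
                "NCF": arithmetic["NCF"],
                "RTA": arithmetic["RTA"],
                "FISSION": arithmetic["FISSION"],
                "UNRESOLVED": arithmetic["UNRESOLVED"],
                "n_extant": arithmetic["n_extant"],
                "balanced": arithmetic["balanced"],
            }
        )
        for e in events:
            if e.kind in ("EEJ", "NCF", "RTA"):
                key_lineages[(e.kind, tuple(sorted(e.protos)))].append(lineage)
    summary = pd.DataFrame(rows)
    shared_rows = [
        {
            "kind": kind,
            "protos": "+".join(protos),
            "n_lineages": len(lineages),
            "lineages": ",".join(sorted(lineages)),
            "shared": len(lineages) > 1,
        }
        for (kind, protos), lineages in sorted(key_lineages.items())
    ]
    shared = pd.DataFrame(
        shared_rows,
        columns=["kind", "protos", "n_lineages", "lineages", "shared"],
    )
    return summary, shared
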