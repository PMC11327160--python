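"""Syntenic-depth profiles and ratio-based polyploidy inference.

The polyploidy level of a lineage relative to a reference that shares only
older events is read from the *modal syntenic depth ratio*: a query that
underwent one extra whole-genome duplication covers every reference region
with two collinear blocks (ratio 2:1), a triplication with three (3:1), a
triplication followed by a duplication with six (6:1), and so on.  The
ratio is then decomposed into an ordered product of x2 / x3 events whose
number is constrained by the count of post-reference Ks peaks, and
cross-lineage comparisons with Ks-age matching decide which events are
shared and which are lineage-specific.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genome_model import GenomeTable, ValidationError
from .synteny import SyntenyBlock

__all__ = [
    "DepthProfile",
    "PloidyCall",
    "SharedEventReport",
    "syntenic_depth",
    "self_depth_mode",
    "depth_ratio",
    "decompose_ploidy",
    "shared_event_test",
]


@dataclass
class DepthProfile:
    """Per-gene block-coverage depths for a query/reference comparison.

    ``depth_on_reference[g]`` counts the blocks whose reference-axis span
    contains reference gene ``g`` — i.e. how many query copies cover it;
    ``depth_on_query`` is the symmetric count.  Modes are taken over covered
    genes only (depth >= 1), since fractionation-induced zeros would
    otherwise dominate.
    """

    query_id: str
    reference_id: str
    depth_on_reference: dict[str, int]
    depth_on_query: dict[str, int]

    @staticmethod
    def _mode(depths: dict[str, int]) -> int:
        covered = [d for d in depths.values() if d >= 1]
        if not covered:
            return 0
        counts = Counter(covered)
        top = max(counts.values())
        return min(d for d, c in counts.items() if c == top)

    @property
    def modal_query_copies(self) -> int:
        """Modal number of query blocks covering a reference gene."""
        return self._mode(self.depth_on_reference)

    @property
    def modal_reference_copies(self) -> int:
        """Modal number of reference blocks covering a query gene."""
        return self._mode(self.depth_on_query)

    @property
    def covered_fraction_reference(self) -> float:
        if not self.depth_on_reference:
            return 0.0
        n = sum(1 for d in self.depth_on_reference.values() if d >= 1)
        return n / len(self.depth_on_reference)

    @property
    def covered_fraction_query(self) -> float:
        if not self.depth_on_query:
            return 0.0
        n = sum(1 for d in self.depth_on_query.values() if d >= 1)
        return n / len(self.depth_on_query)


def syntenic_depth(
    blocks: Sequence[SyntenyBlock],
    query: GenomeTable,
    reference: GenomeTable,
    min_block_size: int = 5,
) -> DepthProfile:
    """Count, for every gene of each genome, the synteny blocks whose rank
    span on that genome's axis contains the gene.

    ``blocks`` must have been chained with the query on the A axis and the
    reference on the B axis.  Blocks below ``min_block_size`` anchors are
    ignored as noise.
    """
    kept = [b for b in blocks if b.anchor_count >= min_block_size]
    ref_chroms = set(reference.chromosomes)
    qry_chroms = set(query.chromosomes)
    for b in kept:
        if b.chrom_a not in qry_chroms or b.chrom_b not in ref_chroms:
            raise ValidationError(
                f"block {b.block_id} on ({b.chrom_a},{b.chrom_b}) does not match "
                f"genomes ({query.genome_id},{reference.genome_id})"
            )
    spans_by_ref: dict[str, list[tuple[int, int]]] = defaultdict(list)
    spans_by_qry: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for b in kept:
        spans_by_qry[b.chrom_a].append(b.span_a)
        spans_by_ref[b.chrom_b].append(b.span_b)
    depth_ref = {}
    for chrom in reference.chromosomes:
        spans = spans_by_ref.get(chrom, [])
        for g in reference.chromosome_genes(chrom):
            depth_ref[g.gene_id] = sum(1 for lo, hi in spans if lo <= g.rank < hi)
    depth_qry = {}
    for chrom in query.chromosomes:
        spans = spans_by_qry.get(chrom, [])
        for g in query.chromosome_genes(chrom):
            depth_qry[g.gene_id] = sum(1 for lo, hi in spans if lo <= g.rank < hi)
    return DepthProfile(query.genome_id, reference.genome_id, depth_ref, depth_qry)


def self_depth_mode(
    blocks: Sequence[SyntenyBlock], genome: GenomeTable, min_block_size: int = 5
) -> int:
    """Modal number of intra-genomic blocks covering a gene on either dot-plot
    axis, over covered genes.  A genome carrying one unfractionated WGD reads
    1 (each gene lies in the single block pairing it with its homeolog); no
    residual duplication reads 0."""
    kept = [b for b in blocks if b.anchor_count >= min_block_size]
    depth: dict[str, int] = {g.gene_id: 0 for g in genome.genes}
    spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for b in kept:
        spans[b.chrom_a].append(b.span_a)
        spans[b.chrom_b].append(b.span_b)
    for chrom in genome.chromosomes:
        for g in genome.chromosome_genes(chrom):
            depth[g.gene_id] = sum(
                1 for lo, hi in spans.get(chrom, []) if lo <= g.rank < hi
            )
    covered = [d for d in depth.values() if d >= 1]
    if not covered:
        return 0
    counts = Counter(covered)
    top = max(counts.values())
    return min(d for d, c in counts.items() if c == top)


def depth_ratio(
    profile: DepthProfile, min_covered_fraction: float = 0.3
) -> tuple[int, int]:
    """The (query : reference) modal depth ratio.

    The query side is the modal number of query blocks per covered reference
    gene; the reference side the converse.  Raises when coverage is too thin
    in either direction for the mode to be meaningful.
    """
    if profile.covered_fraction_reference < min_covered_fraction:
        raise ValidationError(
            f"reference coverage {profile.covered_fraction_reference:.2f} below "
            f"{min_covered_fraction}; review block parameters"
        )
    if profile.covered_fraction_query < min_covered_fraction:
        raise ValidationError(
            f"query coverage {profile.covered_fraction_query:.2f} below "
            f"{min_covered_fraction}; review block parameters"
        )
    q = profile.modal_query_copies
    r = profile.modal_reference_copies
    if q < 1 or r < 1:
        raise ValidationError("modal depth < 1 despite coverage; inconsistent input")
    return q, r


@dataclass
class PloidyCall:
    """A ratio decomposed into post-reference polyploidy multiplicities."""

    ratio: tuple[int, int]
    multiplicities: list[int]  # oldest first; empty if no post-reference event
    ambiguous: bool = False
    candidates: list[list[int]] = field(default_factory=list)
    peak_ages: list[float] = field(default_factory=list)  # oldest first

    @property
    def fold(self) -> int:
        out = 1
        for m in self.multiplicities:
            out *= m
        return out


def _factorizations(target: int, n_factors: int) -> list[list[int]]:
    """All ordered sequences over {2, 3} of length n_factors with the given
    product (brute enumeration; the search space is 2^n_factors)."""
    if n_factors == 0:
        return [[]] if target == 1 else []
    out = []
    for f in (2, 3):
        if target % f == 0:
            for rest in _factorizations(target // f, n_factors - 1):
                out.append([f] + rest)
    return out


def decompose_ploidy(
    ratio: tuple[int, int],
    n_post_reference_ks_peaks: int,
    peak_ages: Sequence[float] = (),
) -> PloidyCall:
    """Decompose a modal depth ratio into x2/x3 events constrained by the
    number of post-reference Ks peaks.

    A unique ordered factorization yields an unambiguous call with factors
    mapped oldest-peak-first; several factorizations are surfaced as an
    ambiguity (cross-species comparison is the sanctioned resolver); none is
    an inconsistency.
    """
    q, r = ratio
    if q < 1 or r < 1:
        raise ValidationError("ratio components must be >= 1")
    if n_post_reference_ks_peaks < 0:
        raise ValidationError("peak count must be >= 0")
    if q % r != 0:
        raise ValidationError(
            f"query depth {q} not divisible by reference depth {r}: "
            "reciprocal lineage-specific events suspected; use shared_event_test"
        )
    target = q // r
    cands = _factorizations(target, n_post_reference_ks_peaks)
    ages = sorted(peak_ages, reverse=True)
    if not cands:
        raise ValidationError(
            f"no ordered factorization of {target} into {n_post_reference_ks_peaks} "
            "factors from {2,3}: ratio and Ks peak count are inconsistent"
        )
    if len(cands) == 1:
        return PloidyCall(ratio, cands[0], False, cands, list(ages))
    return PloidyCall(ratio, cands[0], True, cands, list(ages))


@dataclass
class SharedEventReport:
    shared: list[tuple[int, float, float]]  # (multiplicity, age_a, age_b)
    independent_a: list[tuple[int, float]]
    independent_b: list[tuple[int, float]]
    consistent: bool
    rule: str
    age_tolerance: float


def shared_event_test(
    cross_ratio: tuple[int, int],
    call_a: PloidyCall,
    call_b: PloidyCall,
    age_tolerance: float = 0.15,
) -> SharedEventReport:
    """Decide, for each post-reference event of two ingroup lineages, whether
    it predates their split (shared) or is lineage-specific (independent).

    Events of equal multiplicity whose paralog-peak Ks ages agree within
    ``age_tolerance`` are paired as shared (oldest first); the rest are
    independent.  The observed cross-lineage ratio is then checked against
    the pairing: with g the product of shared multiplicities and P_a, P_b
    the lineages' total folds, an orthologous-depth convention predicts
    P_a/g : P_b/g while a paralog-inclusive convention predicts P_a : P_b
    for fully shared histories; a ratio matching neither is reported as
    inconsistent, with no call.
    """
    events_a = list(zip(call_a.multiplicities, call_a.peak_ages))
    events_b = list(zip(call_b.multiplicities, call_b.peak_ages))
    if not events_a or not events_b:
        # nothing to pair: any event present on one side only is independent
        return SharedEventReport(
            shared=[],
            independent_a=events_a,
            independent_b=list(events_b),
            consistent=True,
            rule="one lineage has no post-reference event",
            age_tolerance=age_tolerance,
        )
    used_b: set[int] = set()
    shared: list[tuple[int, float, float]] = []
    indep_a: list[tuple[int, float]] = []
    for mult_a, age_a in events_a:  # oldest first by construction
        match = None
        for j, (mult_b, age_b) in enumerate(events_b):
            if j in used_b or mult_b != mult_a:
                continue
            if abs(age_a - age_b) <= age_tolerance:
                match = j
                break
        if match is None:
            indep_a.append((mult_a, age_a))
        else:
            used_b.add(match)
            shared.append((mult_a, age_a, events_b[match][1]))
    indep_b = [e for j, e in enumerate(events_b) if j not in used_b]
    g = 1
    for m, _, _ in shared:
        g *= m
    fold_a, fold_b = call_a.fold, call_b.fold
    q, r = cross_ratio

    def same_ratio(x: tuple[int, int], y: tuple[int, int]) -> bool:
        return x[0] * y[1] == x[1] * y[0]

    ortho_ok = same_ratio((q, r), (fold_a // g, fold_b // g))
    para_ok = same_ratio((q, r), (fold_a, fold_b))
    consistent = ortho_ok or para_ok
    rule = (
        "age-matched events paired as shared; cross ratio checked against "
        + ("orthologous-depth convention" if ortho_ok else
           "paralog-inclusive convention" if para_ok else "no convention (inconsistent)")
    )
    return SharedEventReport(
        shared=shared,
        independent_a=indep_a,
        independent_b=indep_b,
        consistent=consistent,
        rule=rule,
        age_tolerance=age_tolerance,
    )
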