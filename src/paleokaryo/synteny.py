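"""Anchor construction and collinear synteny-block chaining.

A synteny *anchor* is a homologous gene pair placed at its (rank_a, rank_b)
position in the gene-order dot plot of two genomes (or of a genome against
itself).  Blocks are maximal chains of anchors monotone in both rank axes —
strictly increasing in both for a *parallel* block, increasing in A and
decreasing in B for an *antiparallel* one (an inverted region) — with
consecutive rank gaps bounded on both axes.

Chaining is sparse dynamic programming with chain score = anchor count,
extracted greedily best-chain-first so each anchor lands in at most one
block; ties are broken deterministically.  Tandem arrays (rank-adjacent
genes of one family) are collapsed to a single anchor carrier beforehand so
they cannot inflate syntenic depth downstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_model import GenomeTable, HomologPair, ValidationError

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "build_anchors",
    "chain_blocks",
    "dotplot_export",
    "write_blocks",
    "read_blocks",
]


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    rank_a: int
    chrom_b: str
    rank_b: int
    score: float
    ks: float | None = None


@dataclass
class SyntenyBlock:
    block_id: str
    chrom_a: str
    chrom_b: str
    orientation: str  # "parallel" | "antiparallel"
    anchors: list[Anchor]
    median_ks: float | None = None
    saturated: bool = False

    @property
    def anchor_count(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        """Half-open rank interval covered on the A axis."""
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks) + 1

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks) + 1


def _tandem_representative(genome: GenomeTable) -> dict[str, str]:
    """Map each gene to the representative of its tandem run (a maximal run
    of rank-adjacent genes sharing a family); singletons map to themselves."""
    rep: dict[str, str] = {}
    for chrom in genome.chromosomes:
        genes = genome.chromosome_genes(chrom)
        i = 0
        while i < len(genes):
            j = i
            while (
                j + 1 < len(genes)
                and genes[j + 1].family_id is not None
                and genes[j + 1].family_id == genes[i].family_id
            ):
                j += 1
            for k in range(i, j + 1):
                rep[genes[k].gene_id] = genes[i].gene_id
            i = j + 1
    return rep


def build_anchors(
    genome_a: GenomeTable,
    genome_b: GenomeTable,
    homologs: Sequence[HomologPair],
    cscore_threshold: float = 0.99,
    collapse_tandem: bool = True,
    self_diag_window: int = 10,
) -> list[Anchor]:
    """Filter homolog pairs into dot-plot anchors with a c-score cutoff.

    A pair (a, b) is kept iff score(a,b) >= threshold * max(best score of a
    against genome B, best score of b against genome A) — i.e. it must be
    within the threshold of *both* genes' best hits.  Self-comparison
    identity pairs, and near-diagonal self pairs within
    ``self_diag_window`` ranks (tandem/proximal duplicates, which are not
    collinearity evidence), are discarded.  Tandem runs are collapsed to
    their highest-scoring carrier unless disabled.
    """
    if not (0 < cscore_threshold <= 1):
        raise ValidationError("cscore_threshold must be in (0, 1]")
    best_a: dict[str, float] = defaultdict(float)
    best_b: dict[str, float] = defaultdict(float)
    self_cmp = genome_a.genome_id == genome_b.genome_id
    for p in homologs:
        if p.gene_a not in genome_a or p.gene_b not in genome_b:
            raise ValidationError(
                f"homolog pair ({p.gene_a}, {p.gene_b}) references unknown gene"
            )
        if self_cmp and p.gene_a == p.gene_b:
            continue
        best_a[p.gene_a] = max(best_a[p.gene_a], p.score)
        best_b[p.gene_b] = max(best_b[p.gene_b], p.score)
        if self_cmp:
            # in a self dot plot each gene appears on both axes
            best_a[p.gene_b] = max(best_a[p.gene_b], p.score)
            best_b[p.gene_a] = max(best_b[p.gene_a], p.score)
    anchors: list[Anchor] = []
    for p in homologs:
        if self_cmp and p.gene_a == p.gene_b:
            continue
        if p.score < cscore_threshold * max(best_a[p.gene_a], best_b[p.gene_b]):
            continue
        ga, gb = genome_a.gene(p.gene_a), genome_b.gene(p.gene_b)
        if (
            self_cmp
            and ga.chromosome == gb.chromosome
            and abs(ga.rank - gb.rank) <= self_diag_window
        ):
            continue
        anchors.append(
            Anchor(
                p.gene_a, p.gene_b, ga.chromosome, ga.rank,
                gb.chromosome, gb.rank, p.score, p.ks,
            )
        )
    if collapse_tandem:
        rep_a = _tandem_representative(genome_a)
        rep_b = _tandem_representative(genome_b)
        grouped: dict[tuple[str, str], Anchor] = {}
        for a in anchors:
            key = (rep_a[a.gene_a], rep_b[a.gene_b])
            prev = grouped.get(key)
            if prev is None or (a.score, a.gene_a, a.gene_b) > (
                prev.score, prev.gene_a, prev.gene_b
            ):
                grouped[key] = a
        anchors = list(grouped.values())
    anchors.sort(key=lambda a: (a.chrom_a, a.rank_a, a.chrom_b, a.rank_b))
    return anchors


def _best_chain(
    anchors: list[Anchor], orientation: str, max_gap: int
) -> list[int]:
    """Indices of the best monotone chain among ``anchors`` (sorted by
    rank_a, rank_b).  O(m^2) DP; score = chain length."""
    m = len(anchors)
    score = [1] * m
    prev = [-1] * m
    sign = 1 if orientation == "parallel" else -1
    for i in range(m):
        ai = anchors[i]
        for j in range(i):
            aj = anchors[j]
            da = ai.rank_a - aj.rank_a
            db = sign * (ai.rank_b - aj.rank_b)
            if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                continue
            if score[j] + 1 > score[i]:
                score[i] = score[j] + 1
                prev[i] = j
    if m == 0:
        return []
    end = max(range(m), key=lambda i: (score[i], -anchors[i].rank_a, -anchors[i].rank_b))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    chain.reverse()
    return chain


def chain_blocks(
    anchors: Sequence[Anchor],
    min_block_size: int = 5,
    max_gap: int = 25,
) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks per chromosome pair.

    Greedy best-chain-first extraction within each (chrom_a, chrom_b) pair,
    alternating over both orientations until no chain of at least
    ``min_block_size`` anchors remains; each anchor is used at most once.
    """
    if min_block_size < 2:
        raise ValidationError("min_block_size must be >= 2")
    if max_gap < 1:
        raise ValidationError("max_gap must be >= 1")
    groups: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
    for a in anchors:
        groups[(a.chrom_a, a.chrom_b)].append(a)
    blocks: list[SyntenyBlock] = []
    counter = 0
    for key in sorted(groups):
        pool = sorted(groups[key], key=lambda a: (a.rank_a, a.rank_b))
        while True:
            best = None
            for orientation in ("parallel", "antiparallel"):
                chain = _best_chain(pool, orientation, max_gap)
                if len(chain) >= min_block_size and (
                    best is None or len(chain) > len(best[0])
                ):
                    best = (chain, orientation)
            if best is None:
                break
            chain, orientation = best
            chosen = [pool[i] for i in chain]
            counter += 1
            blocks.append(
                SyntenyBlock(
                    block_id=f"B{counter:05d}",
                    chrom_a=key[0],
                    chrom_b=key[1],
                    orientation=orientation,
                    anchors=chosen,
                )
            )
            used = set(chain)
            pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


def dotplot_export(
    blocks: Sequence[SyntenyBlock],
    path: str | Path,
    png_path: str | Path | None = None,
) -> None:
    """Write the anchors of all blocks as a dot-plot TSV (and optional PNG)."""
    rows = []
    for b in blocks:
        for a in b.anchors:
            rows.append(
                (a.chrom_a, a.rank_a, a.chrom_b, a.rank_b, b.block_id, b.orientation)
            )
    df = pd.DataFrame(
        rows, columns=["chrom_a", "rank_a", "chrom_b", "rank_b", "block_id", "orientation"]
    )
    df.to_csv(path, sep="\t", index=False)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        if not df.empty:
            for (_, blk), sub in df.groupby(["chrom_a", "block_id"]):
                ax.plot(sub["rank_a"], sub["rank_b"], ".", markersize=2)
        ax.set_xlabel("rank (genome A)")
        ax.set_ylabel("rank (genome B)")
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


BLOCK_COLUMNS = [
    "block_id", "chrom_a", "chrom_b", "orientation", "median_ks",
    "gene_a", "gene_b", "rank_a", "rank_b", "score", "ks",
]


def write_blocks(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    rows = []
    for b in blocks:
        for a in b.anchors:
            rows.append(
                (b.block_id, b.chrom_a, b.chrom_b, b.orientation, b.median_ks,
                 a.gene_a, a.gene_b, a.rank_a, a.rank_b, a.score, a.ks)
            )
    pd.DataFrame(rows, columns=BLOCK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_blocks(path: str | Path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t")
    blocks: list[SyntenyBlock] = []
    for bid, sub in df.groupby("block_id", sort=True):
        first = sub.iloc[0]
        anchors = [
            Anchor(
                str(r.gene_a), str(r.gene_b), str(r.chrom_a), int(r.rank_a),
                str(r.chrom_b), int(r.rank_b), float(r.score),
                None if pd.isna(r.ks) else float(r.ks),
            )
            for r in sub.itertuples(index=False)
        ]
        anchors.sort(key=lambda a: (a.rank_a, a.rank_b))
        blocks.append(
            SyntenyBlock(
                block_id=str(bid),
                chrom_a=str(first.chrom_a),
                chrom_b=str(first.chrom_b),
                orientation=str(first.orientation),
                anchors=anchors,
                median_ks=None if pd.isna(first.median_ks) else float(first.median_ks),
            )
        )
    return blocks
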