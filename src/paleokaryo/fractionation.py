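"""Subgenome assignment, biased-fractionation statistics, the core-set-of-
orthogroups (CSO) retention/loss pipeline, and gene-duplication-mode
classification.

After a shared whole-genome duplication, each descendant genome decomposes
into two subgenomes keyed to the doubled ancestral karyotype.  The
subgenome retaining more genes is labelled LF (least fractionated), the
other MF (most fractionated); biased loss shows up as an excess of absent
orthogroups on the MF side and a complementary retention pattern across
the two sides.  Gene duplicates are classified into the standard modes —
WGD (collinear), tandem (TD), proximal (PD), transposed (TRD, one copy at
the ancestral outgroup-syntenic locus), dispersed (DSD) — with precedence
WGD > TD > PD > TRD > DSD; singletons are UD.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (
    GenomeTable,
    HomologPair,
    OrthogroupMatrix,
    ValidationError,
)
from .karyotype import KaryotypePainting
from .synteny import SyntenyBlock

__all__ = [
    "SubgenomeAssignment",
    "CSOMatrix",
    "assign_subgenomes",
    "build_cso",
    "retention_sets",
    "fractionation_stats",
    "classify_duplicates",
    "mode_tally_by_family",
    "CATEGORIES",
]

CATEGORIES = ("Absent", "Single Copy", "Two Copies", "Multiple")
MODES = ("WGD", "TD", "PD", "TRD", "DSD", "UD")


def category_of(count: int) -> str:
    """CSO cell category as a pure function of the copy count."""
    if count < 0:
        raise ValidationError("negative copy count")
    if count == 0:
        return "Absent"
    if count == 1:
        return "Single Copy"
    if count == 2:
        return "Two Copies"
    return "Multiple"


@dataclass
class SubgenomeAssignment:
    """Per-gene subgenome labels for one genome after a shared WGD."""

    genome_id: str
    labels: dict[str, str]  # gene_id -> subgenome label, or "unassigned"
    subgenome_counts: dict[str, int]
    lf: str  # label of the least-fractionated (dominant) subgenome
    mf: str
    tie: bool
    binomial_p: float

    @property
    def significant(self) -> bool:
        return self.binomial_p < 0.05


def assign_subgenomes(
    painting: KaryotypePainting,
    genome: GenomeTable,
    subgenome_of_proto: Mapping[str, str],
) -> SubgenomeAssignment:
    """Assign every gene to the subgenome of the doubled-ancestor copy whose
    painted segment covers it.

    ``subgenome_of_proto`` maps each doubled-ancestor proto id to its copy
    label (e.g. ``P03.A -> A``).  LF/MF polarity is decided by total
    assigned gene counts with a two-sided binomial test for whether the
    asymmetry exceeds chance; an exact tie takes the alphabetically first
    label as LF, with a warning flag.
    """
    labels: dict[str, str] = {}
    counts: dict[str, int] = defaultdict(int)
    for chrom in genome.chromosomes:
        for g in genome.chromosome_genes(chrom):
            proto = painting.proto_of(chrom, g.rank)
            sub = subgenome_of_proto.get(proto) if proto is not None else None
            if sub is None:
                labels[g.gene_id] = "unassigned"
            else:
                labels[g.gene_id] = sub
                counts[sub] += 1
    if len(counts) < 2:
        raise ValidationError(
            "fewer than two subgenomes received assignments; the genome may "
            "not share the target WGD (modal self-depth 1)"
        )
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    lf, mf = ordered[0][0], ordered[1][0]
    tie = ordered[0][1] == ordered[1][1]
    n = ordered[0][1] + ordered[1][1]
    p = float(stats.binomtest(ordered[0][1], n, 0.5).pvalue) if n else 1.0
    return SubgenomeAssignment(
        genome_id=genome.genome_id,
        labels=labels,
        subgenome_counts=dict(counts),
        lf=lf,
        mf=mf,
        tie=tie,
        binomial_p=p,
    )


@dataclass
class CSOMatrix:
    """Core set of orthogroups: copy counts, categories and outgroup clusters.

    ``counts`` is orthogroups x units; ``categories`` the per-cell category;
    ``cluster`` keys each CSO to 1/2/3 by the first outgroup's copy number
    (1 -> cluster 1, 2 -> cluster 2, >=3 -> cluster 3, 0 -> cluster 1).
    """

    counts: pd.DataFrame
    categories: pd.DataFrame
    cluster: pd.Series
    subgenome_units: list[str]
    outgroup_units: list[str]


def build_cso(
    matrix: OrthogroupMatrix,
    subgenome_units: Sequence[str],
    required_units: Sequence[str],
    min_units: int = 8,
) -> CSOMatrix:
    """Admit orthogroups present in at least ``min_units`` subgenome units
    and in every required (outgroup) unit, and categorise each cell."""
    for u in list(subgenome_units) + list(required_units):
        if u not in matrix.counts.columns:
            raise ValidationError(f"required unit {u!r} missing from matrix")
    counts = matrix.counts
    present_sub = (counts[list(subgenome_units)] >= 1).sum(axis=1)
    present_req = (counts[list(required_units)] >= 1).all(axis=1)
    keep = counts[(present_sub >= min_units) & present_req]
    keep = keep[list(subgenome_units) + list(required_units)]
    categories = keep.map(category_of)
    first_out = list(required_units)[0]
    cluster = keep[first_out].clip(lower=1).clip(upper=3).rename("cluster")
    return CSOMatrix(
        counts=keep,
        categories=categories,
        cluster=cluster,
        subgenome_units=list(subgenome_units),
        outgroup_units=list(required_units),
    )


def retention_sets(
    cso: CSOMatrix | pd.DataFrame,
    a_units: Sequence[str],
    b_units: Sequence[str],
    presence_threshold: float = 0.5,
) -> dict:
    """Venn partition of CSOs by retention class.

    A CSO is *retained* in a class iff it is present (count >= 1) in
    strictly more than ``presence_threshold`` of that class's units.  The
    complementary count is A-only + B-only.
    """
    counts = cso.counts if isinstance(cso, CSOMatrix) else cso
    if not a_units or not b_units:
        raise ValidationError("both subgenome classes must be non-empty")
    in_a = (counts[list(a_units)] >= 1).mean(axis=1) > presence_threshold
    in_b = (counts[list(b_units)] >= 1).mean(axis=1) > presence_threshold
    a_only = counts.index[in_a & ~in_b]
    b_only = counts.index[~in_a & in_b]
    both = counts.index[in_a & in_b]
    neither = counts.index[~in_a & ~in_b]
    return {
        "A_only": list(a_only),
        "B_only": list(b_only),
        "both": list(both),
        "neither": list(neither),
        "sizes": {
            "A_only": len(a_only),
            "B_only": len(b_only),
            "both": len(both),
            "neither": len(neither),
        },
        "complementary": len(a_only) + len(b_only),
        "total": len(counts),
    }


def fractionation_stats(
    cso: CSOMatrix,
    pairs: Sequence[tuple[str, str]],
    presence_threshold: float = 0.5,
) -> dict:
    """Per-cluster, per-category comparison of the A-class vs B-class
    subgenome units across species pairs.

    For every (A-unit, B-unit) pair the number of CSOs in each category is
    tallied per outgroup cluster; categories are compared across pairs with
    a two-sided Wilcoxon signed-rank test (skipped, with notice, below 5
    pairs).  The complementarity fraction from :func:`retention_sets` is
    attached.
    """
    tables: dict[int, pd.DataFrame] = {}
    tests: dict[int, dict[str, float | None]] = {}
    clusters = sorted(cso.cluster.unique())
    for cl in clusters:
        idx = cso.cluster.index[cso.cluster == cl]
        rows = []
        for a_unit, b_unit in pairs:
            for side, unit in (("A", a_unit), ("B", b_unit)):
                cats = cso.categories.loc[idx, unit].value_counts()
                rows.append(
                    {
                        "pair": f"{a_unit}|{b_unit}",
                        "side": side,
                        "unit": unit,
                        **{c: int(cats.get(c, 0)) for c in CATEGORIES},
                    }
                )
        tables[int(cl)] = pd.DataFrame(rows)
        tests[int(cl)] = {}
        for cat in CATEGORIES:
            a_vals = [r[cat] for r in rows if r["side"] == "A"]
            b_vals = [r[cat] for r in rows if r["side"] == "B"]
            if len(pairs) < 5:
                tests[int(cl)][cat] = None
                continue
            diff = np.asarray(a_vals) - np.asarray(b_vals)
            if np.all(diff == 0):
                tests[int(cl)][cat] = 1.0
            else:
                tests[int(cl)][cat] = float(
                    stats.wilcoxon(a_vals, b_vals, alternative="two-sided").pvalue
                )
    a_units = [p[0] for p in pairs]
    b_units = [p[1] for p in pairs]
    venn = retention_sets(cso, a_units, b_units, presence_threshold)
    return {
        "tables": tables,
        "wilcoxon_p": tests,
        "test_skipped": len(pairs) < 5,
        "venn_sizes": venn["sizes"],
        "complementary": venn["complementary"],
        "complementary_fraction": venn["complementary"] / venn["total"]
        if venn["total"]
        else 0.0,
    }


def classify_duplicates(
    genome: GenomeTable,
    homologs: Sequence[HomologPair],
    intra_blocks: Sequence[SyntenyBlock],
    outgroup_blocks: Sequence[SyntenyBlock] | None = None,
    proximal_window: int = 10,
    ks_gate: float = 0.3,
) -> dict[str, str]:
    """Assign every gene one duplication mode with precedence
    WGD > TD > PD > TRD > DSD; genes without a within-genome homolog are UD.

    * WGD: the gene participates in an anchor of an intra-genome collinear
      block.
    * TD: a homolog is rank-adjacent on the same chromosome.
    * PD: a homolog lies within ``proximal_window`` ranks on the same
      chromosome.
    * TRD: the gene is not syntenic with the outgroup but has a homolog
      that is (the partner sits at the ancestral locus).
    * DSD: any remaining gene with a homolog.

    Anchors whose pair Ks deviates from their block's median by more than
    ``ks_gate`` are ignored for the WGD test (a young small-scale pair that
    chains into an older collinear block is not a WGD duplicate).  The
    outgroup ancestral-locus test uses anchor membership, so the outgroup
    blocks should be chained from a permissive homolog set (low c-score)
    lest a duplicate out-compete its parent's ortholog pair.
    """
    in_block: set[str] = set()
    for b in intra_blocks:
        for a in b.anchors:
            if (
                ks_gate is not None
                and b.median_ks is not None
                and a.ks is not None
                and abs(a.ks - b.median_ks) > ks_gate
            ):
                continue
            in_block.add(a.gene_a)
            in_block.add(a.gene_b)
    neighbours: dict[str, list[tuple[float, str]]] = defaultdict(list)
    for p in homologs:
        if p.gene_a == p.gene_b:
            continue
        neighbours[p.gene_a].append((p.score, p.gene_b))
        neighbours[p.gene_b].append((p.score, p.gene_a))
    wants_trd = outgroup_blocks is not None
    out_syntenic: set[str] = set()
    if wants_trd:
        for b in outgroup_blocks:
            for a in b.anchors:
                out_syntenic.add(a.gene_a)
    modes: dict[str, str] = {}
    for chrom in genome.chromosomes:
        for g in genome.chromosome_genes(chrom):
            partners = neighbours.get(g.gene_id, [])
            if not partners:
                modes[g.gene_id] = "UD"
                continue
            if g.gene_id in in_block:
                modes[g.gene_id] = "WGD"
                continue
            dists = []
            for _score, p_id in partners:
                if p_id in genome:
                    h = genome.gene(p_id)
                    if h.chromosome == g.chromosome:
                        dists.append(abs(h.rank - g.rank))
            # the transposed/dispersed split is decided by the closest
            # (best-scoring) partner: the duplication partner itself, not a
            # distant family member
            best = max(partners, key=lambda sp: (sp[0], sp[1]))[1]
            if any(d == 1 for d in dists):
                modes[g.gene_id] = "TD"
            elif any(1 < d <= proximal_window for d in dists):
                modes[g.gene_id] = "PD"
            elif (
                wants_trd
                and g.gene_id not in out_syntenic
                and best in out_syntenic
            ):
                modes[g.gene_id] = "TRD"
            else:
                modes[g.gene_id] = "DSD"
    return modes


def mode_tally_by_family(
    modes: Mapping[str, str],
    family_of: Mapping[str, str | None],
    subgenome_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Contingency table family x mode (x subgenome when provided); totals
    equal the number of classified genes."""
    rows = []
    for gene, mode in modes.items():
        rows.append(
            {
                "family": family_of.get(gene) or "NA",
                "mode": mode,
                "subgenome": subgenome_of.get(gene, "NA") if subgenome_of else "NA",
            }
        )
    df = pd.DataFrame(rows, columns=["family", "mode", "subgenome"])
    tally = (
        df.groupby(["family", "mode", "subgenome"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return tally
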