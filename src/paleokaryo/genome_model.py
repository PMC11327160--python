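"""Shared domain types and file I/O for gene-order genomics.

The universal substrate for every downstream analysis is the
:class:`GenomeTable`: an ordered collection of genes on named chromosomes,
indexed by *rank* (position in gene order along the chromosome) rather than
base pairs.  Synteny, depth, and karyotype painting all operate on ranks;
base-pair coordinates are retained for reporting only.

Coordinates are 0-based half-open throughout (BED native; GFF3 converted on
read/write).
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneRecord",
    "GenomeTable",
    "HomologPair",
    "KaryotypeMap",
    "OrthogroupMatrix",
    "read_gene_table",
    "write_gene_table",
    "read_homologs",
    "write_homologs",
    "read_karyotype_map",
    "write_karyotype_map",
    "read_orthogroups",
    "write_orthogroups",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene on one chromosome of one genome.

    ``rank`` is the 0-based index of the gene along its chromosome in
    coordinate order; ``family_id`` groups homologous genes across and
    within genomes (may be ``None`` for unassigned genes).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValidationError(f"{self.gene_id}: negative coordinate")
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.rank < 0:
            raise ValidationError(f"{self.gene_id}: negative rank")


@dataclass
class GenomeTable:
    """Ordered genes on chromosomes for one genome.

    Invariants: gene ids unique; ranks per chromosome are consecutive from 0;
    every chromosome with genes appears in ``chromosome_lengths``.
    """

    genome_id: str
    genes: list[GeneRecord]
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()
        self._reindex()

    def _validate(self) -> None:
        seen: set[str] = set()
        per_chrom: dict[str, list[int]] = defaultdict(list)
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(
                    f"duplicate gene_id {g.gene_id!r} in genome {self.genome_id!r}"
                )
            seen.add(g.gene_id)
            per_chrom[g.chromosome].append(g.rank)
        for chrom, ranks in per_chrom.items():
            if sorted(ranks) != list(range(len(ranks))):
                raise ValidationError(
                    f"ranks on {self.genome_id}:{chrom} are not consecutive from 0"
                )
            if chrom not in self.chromosome_lengths:
                # infer a length from the right-most gene
                self.chromosome_lengths[chrom] = max(
                    g.end for g in self.genes if g.chromosome == chrom
                )

    def _reindex(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        by_chrom: dict[str, list[GeneRecord]] = defaultdict(list)
        for g in self.genes:
            by_chrom[g.chromosome].append(g)
        self._by_chrom = {
            c: sorted(gs, key=lambda g: g.rank) for c, gs in by_chrom.items()
        }

    # -- accessors -------------------------------------------------------
    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    @property
    def n_chromosomes(self) -> int:
        return len(self._by_chrom)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def chromosome_genes(self, chromosome: str) -> list[GeneRecord]:
        """Genes on ``chromosome`` in rank order."""
        return self._by_chrom[chromosome]

    def families(self) -> dict[str, list[GeneRecord]]:
        fams: dict[str, list[GeneRecord]] = defaultdict(list)
        for g in self.genes:
            if g.family_id is not None:
                fams[g.family_id].append(g)
        return dict(fams)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chromosome": [g.chromosome for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "rank": [g.rank for g in self.genes],
                "family_id": [g.family_id for g in self.genes],
            }
        )


def genome_from_gene_list(
    genome_id: str,
    rows: Iterable[tuple[str, str, int, int, str, str | None]],
) -> GenomeTable:
    """Build a GenomeTable from (gene_id, chromosome, start, end, strand,
    family_id) rows, recomputing ranks from start coordinates per chromosome.

    Ties on start are broken by end then gene_id so ranking is deterministic.
    """
    per_chrom: dict[str, list[tuple]] = defaultdict(list)
    for row in rows:
        per_chrom[row[1]].append(row)
    genes: list[GeneRecord] = []
    for chrom in sorted(per_chrom):
        ordered = sorted(per_chrom[chrom], key=lambda r: (r[2], r[3], r[0]))
        for rank, (gid, c, start, end, strand, fam) in enumerate(ordered):
            genes.append(GeneRecord(gid, c, start, end, strand, rank, fam))
    return GenomeTable(genome_id, genes)


@dataclass(frozen=True)
class HomologPair:
    """A homologous gene pair with a similarity score and, optionally, Ks."""

    gene_a: str
    gene_b: str
    score: float
    ks: float | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"({self.gene_a},{self.gene_b}): negative score")
        if self.ks is not None and self.ks < 0:
            raise ValidationError(f"({self.gene_a},{self.gene_b}): negative ks")


@dataclass
class KaryotypeMap:
    """Assignment of extant chromosome rank intervals to proto-chromosomes.

    ``segment_assignments`` rows are (genome_id, chromosome, rank_start,
    rank_end, proto) with half-open rank intervals that must not overlap
    within a chromosome.
    """

    karyotype_id: str
    proto_chromosomes: list[str]
    segment_assignments: list[tuple[str, str, int, int, str]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        per_chrom: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
        protos = set(self.proto_chromosomes)
        for gid, chrom, lo, hi, proto in self.segment_assignments:
            if lo >= hi:
                raise ValidationError(
                    f"empty rank interval [{lo},{hi}) on {gid}:{chrom}"
                )
            if proto not in protos:
                raise ValidationError(f"unknown proto-chromosome {proto!r}")
            per_chrom[(gid, chrom)].append((lo, hi))
        for key, ivals in per_chrom.items():
            ivals.sort()
            for (lo1, hi1), (lo2, _) in zip(ivals, ivals[1:]):
                if lo2 < hi1:
                    raise ValidationError(f"overlapping intervals on {key}")

    def proto_of(self, genome_id: str, chromosome: str, rank: int) -> str | None:
        for gid, chrom, lo, hi, proto in self.segment_assignments:
            if gid == genome_id and chrom == chromosome and lo <= rank < hi:
                return proto
        return None


@dataclass
class OrthogroupMatrix:
    """Orthogroup x unit copy-count matrix (units are genomes or subgenomes).

    Backed by a pandas DataFrame of non-negative integers; optionally keeps
    the member gene ids behind every cell for OrthoFinder-dialect round trips.
    """

    counts: pd.DataFrame
    members: dict[tuple[str, str], list[str]] | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("negative copy count")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate unit ids")
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate orthogroup ids")
        self.counts = self.counts.astype(int)

    @property
    def orthogroups(self) -> list[str]:
        return list(self.counts.index)

    @property
    def units(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path, format: str = "BED", genome_id: str | None = None) -> GenomeTable:
    """Read a gene-position table (BED6 or GFF3) into a GenomeTable.

    Ranks are recomputed from sorted start coordinates per chromosome; the
    BED ``name``/GFF3 ``ID`` field becomes ``gene_id``.  An optional 7th BED
    column carries the family id.
    """
    path = Path(path)
    fmt = format.upper()
    gid = genome_id or path.stem
    rows: list[tuple[str, str, int, int, str, str | None]] = []
    if fmt == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ParseError(f"{path}:{lineno}: expected >=6 BED columns")
                chrom, start, end, name, _score, strand = parts[:6]
                fam = parts[6] if len(parts) > 6 and parts[6] not in ("", ".") else None
                try:
                    s, e = int(start), int(end)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                if s >= e:
                    raise ParseError(f"{path}:{lineno}: start >= end")
                rows.append((name, chrom, s, e, strand, fam))
    elif fmt == "GFF3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
                if ftype not in ("gene", "mRNA"):
                    continue
                if ftype == "mRNA":
                    # only used when no gene rows exist; handled by dedup below
                    pass
                attr = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                if "ID" not in attr:
                    raise ParseError(f"{path}:{lineno}: {ftype} row lacks ID attribute")
                try:
                    s, e = int(start) - 1, int(end)  # GFF3 is 1-based closed
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
                if s >= e:
                    raise ParseError(f"{path}:{lineno}: start >= end")
                fam = attr.get("family")
                rows.append((ftype, attr["ID"], chrom, s, e, strand, fam))
        gene_rows = [r[1:] for r in rows if r[0] == "gene"]
        if gene_rows:
            rows = gene_rows
        else:
            rows = [r[1:] for r in rows]
    else:
        raise ValueError(f"unknown gene-table format {format!r}")
    try:
        return genome_from_gene_list(gid, rows)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_gene_table(genome: GenomeTable, path: str | Path, format: str = "BED") -> None:
    path = Path(path)
    fmt = format.upper()
    with open(path, "w") as fh:
        if fmt == "BED":
            for chrom in genome.chromosomes:
                for g in genome.chromosome_genes(chrom):
                    fam = g.family_id if g.family_id is not None else "."
                    fh.write(
                        f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{fam}\n"
                    )
        elif fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for chrom in genome.chromosomes:
                for g in genome.chromosome_genes(chrom):
                    attrs = f"ID={g.gene_id}"
                    if g.family_id is not None:
                        attrs += f";family={g.family_id}"
                    fh.write(
                        f"{g.chromosome}\tpaleokaryo\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                    )
        else:
            raise ValueError(f"unknown gene-table format {format!r}")


HOMOLOG_COLUMNS = ["gene_a", "gene_b", "score", "ks"]


def read_homologs(path: str | Path) -> list[HomologPair]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HOMOLOG_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    pairs = []
    for row in df.itertuples(index=False):
        ks = getattr(row, "ks", None)
        if ks is not None and pd.isna(ks):
            ks = None
        pairs.append(HomologPair(str(row.gene_a), str(row.gene_b), float(row.score), ks))
    return pairs


def write_homologs(pairs: Sequence[HomologPair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in pairs],
            "gene_b": [p.gene_b for p in pairs],
            "score": [p.score for p in pairs],
            "ks": [p.ks for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_karyotype_map(path: str | Path) -> KaryotypeMap:
    """Read a karyotype map TSV with a ``# karyotype_id:`` header comment and
    columns (genome_id, chromosome, rank_start, rank_end, proto_chromosome)."""
    path = Path(path)
    karyotype_id = path.stem
    protos: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# karyotype_id:"):
            karyotype_id = first.split(":", 1)[1].strip()
        second = fh.readline()
        if second.startswith("# proto_chromosomes:"):
            protos = second.split(":", 1)[1].split()
    df = pd.read_csv(path, sep="\t", comment="#")
    segs = [
        (str(r.genome_id), str(r.chromosome), int(r.rank_start), int(r.rank_end), str(r.proto_chromosome))
        for r in df.itertuples(index=False)
    ]
    if not protos:
        protos = sorted({s[4] for s in segs})
    return KaryotypeMap(karyotype_id, protos, segs)


def write_karyotype_map(kmap: KaryotypeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# karyotype_id: {kmap.karyotype_id}\n")
        fh.write(f"# proto_chromosomes: {' '.join(kmap.proto_chromosomes)}\n")
        fh.write("genome_id\tchromosome\trank_start\trank_end\tproto_chromosome\n")
        for gid, chrom, lo, hi, proto in kmap.segment_assignments:
            fh.write(f"{gid}\t{chrom}\t{lo}\t{hi}\t{proto}\n")


def read_orthogroups(path: str | Path) -> OrthogroupMatrix:
    """Read an OrthoFinder-dialect Orthogroups.tsv (comma+space gene lists)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    units = list(df.columns[1:])
    members: dict[tuple[str, str], list[str]] = {}
    counts = pd.DataFrame(0, index=df[og_col], columns=units)
    for row in df.itertuples(index=False):
        og = row[0]
        for unit, cell in zip(units, row[1:]):
            genes = [g for g in (cell.split(", ") if cell else []) if g]
            members[(og, unit)] = genes
            counts.loc[og, unit] = len(genes)
    counts.index.name = og_col
    return OrthogroupMatrix(counts, members)


def write_orthogroups(matrix: OrthogroupMatrix, path: str | Path) -> None:
    units = matrix.units
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(units) + "\n")
        for og in matrix.orthogroups:
            cells = []
            for unit in units:
                if matrix.members is not None and (og, unit) in matrix.members:
                    genes = matrix.members[(og, unit)]
                else:
                    n = int(matrix.counts.loc[og, unit])
                    genes = [f"{og}.{unit}.{i}" for i in range(n)]
                cells.append(", ".join(genes))
            fh.write(str(og) + "\t" + "\t".join(cells) + "\n")
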