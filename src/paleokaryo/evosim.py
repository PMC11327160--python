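"""Genome-evolution simulator: polyploidy, rearrangement, fractionation,
small-scale duplication, and synonymous divergence on gene orders.

The simulator evolves a set of *lineages*, each an ordered gene layout on
named chromosomes, through a sequence of dated events:

``WGD``/``WGT``
    whole-genome duplication (x2) / triplication (x3); every chromosome is
    copied into labelled subgenomes and every paralog pair created carries a
    synonymous divergence (Ks) drawn around the event age.
``EEJ``/``NCF``
    descending dysploidy: end-to-end joining concatenates a donor chromosome
    onto a host terminus; nested chromosome fusion inserts the whole donor
    into the host interior (painting signature host-donor-host).  Each
    reduces the chromosome number by one.
``RTA``/``INV``
    count-neutral rearrangement: reciprocal translocation of chromosome arms,
    and segmental inversion.
``LOSS``
    post-polyploid fractionation: per-subgenome biased gene loss, retaining
    at least one copy per ancestral family.
``TD``/``PD``/``TRD``/``DSD``
    small-scale duplication (tandem / proximal / transposed / dispersed).

Each gene carries the label it took at every event it lived through, so the
divergence age of any two genes in a family is the age of the oldest event
at which their label paths separate.  Synthetic Ks values are drawn from
Normal(age, rel_sigma * age) truncated at zero, which reproduces the
unimodal per-event Ks peaks that mixture fitting downstream is asked to
recover.  Homolog similarity scores are synthesised from Ks as
``100 * (1 - ks / ks_max)`` so that c-score filtering can be exercised
without sequence alignment.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome_model import (
    GeneRecord,
    GenomeTable,
    HomologPair,
    KaryotypeMap,
    ValidationError,
)

__all__ = [
    "Event",
    "Lineage",
    "ScenarioResult",
    "simulate_ancestor",
    "generate_codon_pair",
    "run_scenario",
    "load_scenario",
]

POLYPLOIDY_LABELS = "ABC"
GENE_BP = 1000  # nominal gene length; genes are laid out every 2 * GENE_BP
DEFAULT_REL_SIGMA = 0.1
DEFAULT_KS_MAX = 3.0
SSD_KINDS = ("TD", "PD", "TRD", "DSD")


@dataclass
class Event:
    """One dated event in a lineage's history (shared registry entry)."""

    event_id: int
    kind: str
    age_ks: float
    params: dict = field(default_factory=dict)


@dataclass
class SimGene:
    uid: int
    family: str
    proto: str  # ancestor chromosome of the founding gene
    strand: str
    labels: dict[int, str] = field(default_factory=dict)
    mode: str | None = None  # SSD mode for genes created by TD/PD/TRD/DSD


class Lineage:
    """A single evolving genome: ordered chromosomes of :class:`SimGene`.

    All randomness flows through the lineage's ``numpy`` Generator, so a
    fixed seed reproduces the full history byte-for-byte.
    """

    def __init__(self, seed: int):
        self.rng = np.random.default_rng(seed)
        self.chromosomes: dict[str, list[SimGene]] = {}
        self.events: list[Event] = []
        self._uid = 0
        self._event_id = 0
        self._ssd_involved: set[int] = set()  # uids already in an SSD event
        # frozen copies taken right after each polyploidy event: the
        # ploidy-matched ancestor proxies used for karyotype painting
        self.poly_snapshots: list["Lineage"] = []

    # -- internals -------------------------------------------------------
    def _next_uid(self) -> int:
        self._uid += 1
        return self._uid

    def _register(self, kind: str, age_ks: float | None, **params) -> Event:
        if age_ks is None:
            # undated structural events inherit the age of the previous event
            age_ks = self.events[-1].age_ks if self.events else 0.0
        if self.events and age_ks > self.events[-1].age_ks + 1e-12:
            raise ValidationError(
                f"event ages must be non-increasing: {kind} at {age_ks} after "
                f"{self.events[-1].kind} at {self.events[-1].age_ks}"
            )
        ev = Event(self._event_id, kind, age_ks, params)
        self._event_id += 1
        self.events.append(ev)
        return ev

    def _require(self, *chroms: str) -> None:
        for c in chroms:
            if c not in self.chromosomes:
                raise ValidationError(f"chromosome {c!r} does not exist")

    # -- construction ----------------------------------------------------
    def init_ancestor(self, n_chromosomes: int, genes_per_chromosome: int) -> None:
        if n_chromosomes < 1 or genes_per_chromosome < 1:
            raise ValidationError("chromosome and gene counts must be >= 1")
        for i in range(1, n_chromosomes + 1):
            chrom = f"P{i:02d}"
            genes = []
            for j in range(genes_per_chromosome):
                genes.append(
                    SimGene(
                        uid=self._next_uid(),
                        family=f"F{i:02d}_{j:04d}",
                        proto=chrom,
                        strand="+" if (i + j) % 2 == 0 else "-",
                    )
                )
            self.chromosomes[chrom] = genes

    def copy(self) -> "Lineage":
        """Deep copy sharing no mutable state (events list is copied; event
        ids continue from a common counter so merged histories stay unique)."""
        other = Lineage(0)
        other.rng = copy.deepcopy(self.rng)
        other.chromosomes = {
            c: [copy.copy(g) for g in gs] for c, gs in self.chromosomes.items()
        }
        for g_list in other.chromosomes.values():
            for g in g_list:
                g.labels = dict(g.labels)
        other.events = list(self.events)
        other._uid = self._uid
        other._event_id = self._event_id
        other._ssd_involved = set(self._ssd_involved)
        other.poly_snapshots = list(self.poly_snapshots)  # frozen, shareable
        return other

    def split(self, lineage_ids: Sequence[str], age_ks: float) -> dict[str, "Lineage"]:
        """Speciation: every gene in each daughter takes the daughter's id as
        its label at the split event, dating cross-lineage orthologs."""
        ev = self._register("SPLIT", age_ks, lineages=list(lineage_ids))
        daughters: dict[str, Lineage] = {}
        for k, lid in enumerate(lineage_ids):
            d = self.copy()
            d.rng = np.random.default_rng(self.rng.integers(0, 2**31 - 1))
            for genes in d.chromosomes.values():
                for g in genes:
                    g.labels[ev.event_id] = lid
            daughters[lid] = d
        return daughters

    # -- events ----------------------------------------------------------
    def apply_polyploidy(self, multiplicity: int, age_ks: float) -> Event:
        if multiplicity not in (2, 3):
            raise ValidationError("multiplicity must be 2 (WGD) or 3 (WGT)")
        if age_ks <= 0:
            raise ValidationError("age_ks must be positive")
        kind = "WGD" if multiplicity == 2 else "WGT"
        ev = self._register(kind, age_ks, multiplicity=multiplicity)
        new_chroms: dict[str, list[SimGene]] = {}
        for chrom in sorted(self.chromosomes):
            for label in POLYPLOIDY_LABELS[:multiplicity]:
                genes = []
                for g in self.chromosomes[chrom]:
                    ng = copy.copy(g)
                    ng.labels = dict(g.labels)
                    ng.labels[ev.event_id] = label
                    ng.uid = self._next_uid()
                    genes.append(ng)
                new_chroms[f"{chrom}.{label}"] = genes
        self.chromosomes = new_chroms
        snap = self.copy()
        snap.poly_snapshots = []
        self.poly_snapshots.append(snap)
        return ev

    def apply_fusion(
        self,
        kind: str,
        donor: str,
        host: str,
        insertion_rank: int | None = None,
        age_ks: float | None = None,
        reverse_donor: bool | None = None,
    ) -> Event:
        if kind not in ("EEJ", "NCF"):
            raise ValidationError("fusion kind must be EEJ or NCF")
        if donor == host:
            raise ValidationError("donor and host must differ")
        self._require(donor, host)
        donor_genes = self.chromosomes[donor]
        host_genes = self.chromosomes[host]
        if reverse_donor is None:
            reverse_donor = bool(self.rng.integers(0, 2))
        if reverse_donor:
            donor_genes = [copy.copy(g) for g in reversed(donor_genes)]
            for g in donor_genes:
                g.strand = "-" if g.strand == "+" else "+"
        if kind == "EEJ":
            self.chromosomes[host] = host_genes + donor_genes
        else:
            if insertion_rank is None:
                insertion_rank = int(self.rng.integers(1, len(host_genes)))
            if not (0 < insertion_rank < len(host_genes)):
                raise ValidationError(
                    "NCF insertion must be strictly internal (terminal insertion is EEJ)"
                )
            self.chromosomes[host] = (
                host_genes[:insertion_rank] + donor_genes + host_genes[insertion_rank:]
            )
        del self.chromosomes[donor]
        return self._register(
            kind, age_ks, donor=donor, host=host, insertion_rank=insertion_rank
        )

    def apply_rta(
        self, chrom_a: str, chrom_b: str, break_a: int, break_b: int, age_ks: float | None = None
    ) -> Event:
        self._require(chrom_a, chrom_b)
        a, b = self.chromosomes[chrom_a], self.chromosomes[chrom_b]
        if not (0 < break_a < len(a)) or not (0 < break_b < len(b)):
            raise ValidationError("RTA breaks must be strictly internal")
        self.chromosomes[chrom_a] = a[:break_a] + b[break_b:]
        self.chromosomes[chrom_b] = b[:break_b] + a[break_a:]
        return self._register(
            "RTA", age_ks, chrom_a=chrom_a, chrom_b=chrom_b,
            break_a=break_a, break_b=break_b,
        )

    def apply_inversion(
        self, chromosome: str, rank_start: int, rank_end: int, age_ks: float | None = None
    ) -> Event:
        self._require(chromosome)
        genes = self.chromosomes[chromosome]
        if not (0 <= rank_start < rank_end <= len(genes)):
            raise ValidationError("inversion interval is empty or out of range")
        seg = [copy.copy(g) for g in reversed(genes[rank_start:rank_end])]
        for g in seg:
            g.strand = "-" if g.strand == "+" else "+"
        self.chromosomes[chromosome] = genes[:rank_start] + seg + genes[rank_end:]
        return self._register(
            "INV", age_ks, chromosome=chromosome,
            rank_start=rank_start, rank_end=rank_end,
        )

    def fractionate(
        self,
        retention: Mapping[str, float],
        event: Event | None = None,
        age_ks: float | None = None,
    ) -> Event:
        """Biased post-polyploid gene loss.

        Each gene duplicated by ``event`` (default: the most recent
        polyploidy) is independently retained with its subgenome's
        probability; families that would lose every copy are resampled so
        orthology stays detectable.
        """
        for p in retention.values():
            if not (0.0 <= p <= 1.0):
                raise ValidationError("retention probabilities must be in [0,1]")
        if event is None:
            poly = [e for e in self.events if e.kind in ("WGD", "WGT")]
            if not poly:
                raise ValidationError("no polyploidy event to fractionate")
            event = poly[-1]
        fam_genes: dict[str, list[tuple[str, int]]] = {}
        for chrom in sorted(self.chromosomes):
            for idx, g in enumerate(self.chromosomes[chrom]):
                if event.event_id in g.labels:
                    fam_genes.setdefault(g.family, []).append((chrom, idx))
        doomed: set[tuple[str, int]] = set()
        for fam in sorted(fam_genes):
            positions = fam_genes[fam]
            while True:
                kill = []
                for chrom, idx in positions:
                    g = self.chromosomes[chrom][idx]
                    p = retention.get(g.labels[event.event_id], 1.0)
                    if self.rng.random() >= p:
                        kill.append((chrom, idx))
                if len(kill) < len(positions) or not positions:
                    doomed.update(kill)
                    break
                # every copy lost: resample so the family survives
        for chrom in sorted(self.chromosomes):
            self.chromosomes[chrom] = [
                g for idx, g in enumerate(self.chromosomes[chrom])
                if (chrom, idx) not in doomed
            ]
        self.chromosomes = {c: gs for c, gs in self.chromosomes.items() if gs}
        return self._register(
            "LOSS", age_ks, retention=dict(retention), of_event=event.event_id,
            removed=len(doomed),
        )

    def apply_small_scale_duplication(
        self,
        kind: str,
        age_ks: float,
        n_events: int = 1,
        proximal_window: int = 10,
    ) -> list[Event]:
        """Plant ``n_events`` small-scale duplications of the given mode.

        TD inserts the copy rank-adjacent to its parent; PD within
        ``proximal_window`` ranks (but not adjacent); TRD places the copy on
        another chromosome while the parent keeps its ancestral locus; DSD
        anywhere outside the proximal window.
        """
        if kind not in SSD_KINDS:
            raise ValidationError(f"unknown duplication kind {kind!r}")
        if proximal_window <= 1:
            raise ValidationError("proximal_window must be > 1")
        out = []
        for _ in range(n_events):
            chroms = sorted(self.chromosomes)
            # each event hits a locus not already involved in an SSD event,
            # so every planted duplicate keeps its own partner identifiable
            for _attempt in range(1000):
                chrom = chroms[int(self.rng.integers(0, len(chroms)))]
                genes = self.chromosomes[chrom]
                idx = int(self.rng.integers(0, len(genes)))
                parent = genes[idx]
                if parent.uid not in self._ssd_involved:
                    break
            ev = self._register(kind, age_ks, parent_uid=parent.uid)
            child = copy.copy(parent)
            child.labels = dict(parent.labels)
            parent.labels[ev.event_id] = "p"
            child.labels[ev.event_id] = "c"
            child.uid = self._next_uid()
            child.mode = kind
            if kind == "TD":
                genes.insert(idx + 1, child)
            elif kind == "PD":
                offset = int(self.rng.integers(2, proximal_window + 1))
                pos = min(idx + offset, len(genes))
                genes.insert(pos, child)
            elif kind == "TRD":
                others = [c for c in chroms if c != chrom]
                if not others:
                    raise ValidationError("TRD requires >= 2 chromosomes")
                target = others[int(self.rng.integers(0, len(others)))]
                tgenes = self.chromosomes[target]
                tgenes.insert(int(self.rng.integers(0, len(tgenes) + 1)), child)
            else:
                # DSD: both copies end up dispersed — the new copy lands at a
                # random non-proximal position and the parent leaves its
                # ancestral locus too, so neither retains collinear context
                # (the transposed mode is the one that keeps the parent at
                # the outgroup-syntenic ancestral locus); the parent's mode
                # becomes dispersed as well, since it leaves its locus
                parent.mode = "DSD"
                genes.pop(idx)
                for moved in (parent, child):
                    target = chroms[int(self.rng.integers(0, len(chroms)))]
                    tgenes = self.chromosomes[target]
                    while True:
                        pos = int(self.rng.integers(0, len(tgenes) + 1))
                        if target != chrom or abs(pos - idx) > proximal_window:
                            break
                    tgenes.insert(pos, moved)
            self._ssd_involved.update((parent.uid, child.uid))
            out.append(ev)
        return out

    def plant_ssd_events(
        self,
        n_per_kind: Mapping[str, int],
        age_range: tuple[float, float] = (0.05, 0.5),
        proximal_window: int = 10,
    ) -> list[Event]:
        """Plant small-scale duplications of several modes interleaved over a
        span of ages (oldest applied first), emulating duplications accruing
        over time rather than in a single burst; distinct ages keep each
        duplicate's closest homolog its own partner."""
        kinds: list[str] = []
        for kind in SSD_KINDS:
            kinds.extend([kind] * int(n_per_kind.get(kind, 0)))
        self.rng.shuffle(kinds)
        lo, hi = age_range
        ages = sorted(self.rng.uniform(lo, hi, size=len(kinds)), reverse=True)
        out = []
        for kind, age in zip(kinds, ages):
            out.extend(
                self.apply_small_scale_duplication(
                    kind, float(age), n_events=1, proximal_window=proximal_window
                )
            )
        return out

    # -- queries ---------------------------------------------------------
    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    def divergence_age(self, a: SimGene, b: SimGene) -> float | None:
        """Age of the oldest event at which the two genes' label paths
        separate; ``None`` if the paths never separate (same gene)."""
        for ev in self.events:  # events stored oldest-first
            la, lb = a.labels.get(ev.event_id), b.labels.get(ev.event_id)
            if la is not None and lb is not None and la != lb:
                return ev.age_ks
        return None

    # -- emission --------------------------------------------------------
    def to_genome_table(self, genome_id: str) -> GenomeTable:
        records = []
        for chrom in sorted(self.chromosomes):
            for rank, g in enumerate(self.chromosomes[chrom]):
                start = rank * 2 * GENE_BP
                records.append(
                    GeneRecord(
                        gene_id=f"{genome_id}_{g.uid:06d}",
                        chromosome=chrom,
                        start=start,
                        end=start + GENE_BP,
                        strand=g.strand,
                        rank=rank,
                        family_id=g.family,
                    )
                )
        return GenomeTable(genome_id, records)

    def truth_table(self, genome_id: str) -> pd.DataFrame:
        """Per-gene ground truth: ancestral family, proto-chromosome,
        subgenome label per polyploidy event, and SSD mode."""
        poly = [e for e in self.events if e.kind in ("WGD", "WGT")]
        rows = []
        for chrom in sorted(self.chromosomes):
            for rank, g in enumerate(self.chromosomes[chrom]):
                row = {
                    "gene_id": f"{genome_id}_{g.uid:06d}",
                    "chromosome": chrom,
                    "rank": rank,
                    "family": g.family,
                    "proto": g.proto,
                    "mode": g.mode,
                }
                for ev in poly:
                    row[f"subgenome_e{ev.event_id}"] = g.labels.get(ev.event_id)
                rows.append(row)
        return pd.DataFrame(rows)

    def karyotype_map(self, genome_id: str, karyotype_id: str) -> KaryotypeMap:
        """Karyotype map assigning each chromosome's rank runs to the
        majority... for simulated genomes runs are exact proto runs."""
        segs = []
        protos: set[str] = set()
        for chrom in sorted(self.chromosomes):
            genes = self.chromosomes[chrom]
            lo = 0
            for i in range(1, len(genes) + 1):
                if i == len(genes) or genes[i].proto != genes[lo].proto:
                    segs.append((genome_id, chrom, lo, i, genes[lo].proto))
                    protos.add(genes[lo].proto)
                    lo = i
        return KaryotypeMap(karyotype_id, sorted(protos), segs)


def simulate_ancestor(
    n_chromosomes: int, genes_per_chromosome: int, seed: int
) -> Lineage:
    """A root genome of single-copy genes: ``n_chromosomes`` proto-chromosomes
    each carrying ``genes_per_chromosome`` genes of distinct families."""
    lin = Lineage(seed)
    lin.init_ancestor(n_chromosomes, genes_per_chromosome)
    return lin


# ---------------------------------------------------------------------------
# Homolog synthesis
# ---------------------------------------------------------------------------

def _draw_ks(rng: np.random.Generator, age: float, rel_sigma: float) -> float:
    if age <= 0:
        return 0.0
    while True:
        ks = rng.normal(age, rel_sigma * age)
        if ks > 0:
            return float(ks)


def homolog_pairs(
    lin_a: Lineage,
    genome_a: str,
    lin_b: Lineage | None = None,
    genome_b: str | None = None,
    rel_sigma: float = DEFAULT_REL_SIGMA,
    ks_max: float = DEFAULT_KS_MAX,
    seed: int = 0,
) -> list[HomologPair]:
    """Synthesise homolog pairs (within one lineage, or between two) from
    true families, with Ks drawn around the pair's divergence age and score
    = 100 * (1 - ks / ks_max), floored at 0.

    Cross-lineage divergence is read from the shared event registry (the
    daughters of a split carry a common event history).
    """
    rng = np.random.default_rng(seed)

    def collect(lin: Lineage, gid: str):
        fams: dict[str, list[tuple[str, SimGene]]] = {}
        for chrom in sorted(lin.chromosomes):
            for g in lin.chromosomes[chrom]:
                fams.setdefault(g.family, []).append((f"{gid}_{g.uid:06d}", g))
        return fams

    fams_a = collect(lin_a, genome_a)
    pairs: list[HomologPair] = []
    if lin_b is None:
        # intra-genome paralogs
        for fam in sorted(fams_a):
            members = fams_a[fam]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    age = lin_a.divergence_age(members[i][1], members[j][1])
                    if age is None:
                        continue
                    ks = _draw_ks(rng, age, rel_sigma)
                    score = max(0.0, 100.0 * (1.0 - ks / ks_max))
                    pairs.append(HomologPair(members[i][0], members[j][0], score, ks))
    else:
        # merged event registry: daughters share ids for common history
        merged: dict[int, Event] = {e.event_id: e for e in lin_a.events}
        for e in lin_b.events:
            merged.setdefault(e.event_id, e)
        events = sorted(merged.values(), key=lambda e: (-e.age_ks, e.event_id))

        def div_age(ga: SimGene, gb: SimGene) -> float | None:
            for ev in events:
                la, lb = ga.labels.get(ev.event_id), gb.labels.get(ev.event_id)
                if la is not None and lb is not None and la != lb:
                    return ev.age_ks
            return None

        fams_b = collect(lin_b, genome_b or "B")
        for fam in sorted(set(fams_a) & set(fams_b)):
            for id_a, ga in fams_a[fam]:
                for id_b, gb in fams_b[fam]:
                    age = div_age(ga, gb)
                    # a None age across genomes means the same gene observed
                    # at two times (e.g. lineage vs ancestor snapshot): ks ~ 0
                    ks = 0.0 if age is None else _draw_ks(rng, age, rel_sigma)
                    score = max(0.0, 100.0 * (1.0 - ks / ks_max))
                    pairs.append(HomologPair(id_a, id_b, score, ks))
    return pairs


# ---------------------------------------------------------------------------
# Codon-pair substrate for the Nei-Gojobori estimator
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_STOPS = {"TAA", "TAG", "TGA"}


def _random_codon_sequence(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        codon = "".join(_BASES[i] for i in rng.integers(0, 4, 3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def generate_codon_pair(
    n_codons: int, target_ds: float, seed: int
) -> tuple[str, str]:
    """Two in-frame, stop-free codon sequences differing only by synonymous
    substitutions, placed until the Nei-Gojobori Ks of the pair first
    reaches ``target_ds``.

    Fourfold-degenerate third positions are mutated first; the translated
    proteins of the two sequences are identical by construction.  Raises if
    the target is unreachable, reporting the maximum achievable estimate.
    """
    from .ksdist import ng_ks  # local import to avoid a cycle at module load

    if n_codons < 10:
        raise ValidationError("n_codons must be >= 10")
    if target_ds < 0:
        raise ValidationError("target_ds must be >= 0")
    rng = np.random.default_rng(seed)
    seq_a = _random_codon_sequence(rng, n_codons)
    if target_ds == 0:
        return seq_a, seq_a

    from .ksdist import GENETIC_CODE, synonymous_alternatives

    codons_b = [seq_a[i : i + 3] for i in range(0, len(seq_a), 3)]
    # candidate synonymous single-nucleotide edits, fourfold sites first
    fourfold, other = [], []
    for ci, codon in enumerate(codons_b):
        for pos in range(3):
            alts = synonymous_alternatives(codon, pos)
            if not alts:
                continue
            entry = (ci, pos, alts)
            (fourfold if len(alts) == 3 else other).append(entry)
    rng.shuffle(fourfold)
    rng.shuffle(other)
    best = 0.0
    for ci, pos, alts in fourfold + other:
        codon = codons_b[ci]
        if codon != seq_a[3 * ci : 3 * ci + 3]:
            continue  # one edit per codon keeps the NG86 bookkeeping simple
        new_base = alts[int(rng.integers(0, len(alts)))]
        codons_b[ci] = codon[:pos] + new_base + codon[pos + 1 :]
        est = ng_ks(seq_a, "".join(codons_b))
        if est.ds is None:  # saturated: revert the last edit
            codons_b[ci] = codon
            break
        best = est.ds
        if best >= target_ds:
            return seq_a, "".join(codons_b)
    raise ValidationError(
        f"target_ds {target_ds} unreachable; maximum achievable ~ {best:.4f}"
    )


# ---------------------------------------------------------------------------
# Declarative scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    genomes: dict[str, GenomeTable]
    lineages: dict[str, Lineage]
    truth: dict[str, pd.DataFrame]
    event_log: dict[str, list[Event]]
    homologs: dict[tuple[str, str], list[HomologPair]]
    ancestor: Lineage


def _apply_event(lin: Lineage, spec: Mapping) -> None:
    kind = spec["kind"]
    age = spec.get("age")
    age = float(age) if age is not None else None
    if kind in ("WGD", "WGT"):
        lin.apply_polyploidy(2 if kind == "WGD" else 3, age)
    elif kind in ("EEJ", "NCF"):
        chroms = sorted(lin.chromosomes)
        donor = spec.get("donor")
        host = spec.get("host")
        if donor is None or host is None:
            # prefer chromosomes untouched by earlier structural events so
            # that each event leaves a separable signature (the sampled
            # trajectories mirror real ones, where fusions hit distinct
            # chromosomes far more often than they stack)
            used = {
                c
                for e in lin.events
                if e.kind in ("EEJ", "NCF", "RTA")
                for c in (
                    e.params.get("host"), e.params.get("chrom_a"),
                    e.params.get("chrom_b"),
                )
            }
            free = [c for c in chroms if c not in used]
            pool = free if len(free) >= 2 else chroms
            pick = lin.rng.choice(len(pool), size=2, replace=False)
            donor, host = pool[pick[0]], pool[pick[1]]
        if donor not in lin.chromosomes or host not in lin.chromosomes:
            raise ValidationError(f"scenario event {spec} names a missing chromosome")
        insertion_rank = spec.get("insertion_rank")
        if kind == "NCF" and insertion_rank is None:
            # nested insertions land well inside the host so both flanks
            # stay paintable
            n = len(lin.chromosomes[host])
            margin = min(25, max(1, n // 4))
            insertion_rank = int(lin.rng.integers(margin, n - margin + 1))
        lin.apply_fusion(kind, donor, host, insertion_rank, age)
    elif kind == "RTA":
        chroms = sorted(lin.chromosomes)
        a = spec.get("chrom_a")
        b = spec.get("chrom_b")
        if a is None or b is None:
            used = {
                c
                for e in lin.events
                if e.kind in ("EEJ", "NCF", "RTA")
                for c in (
                    e.params.get("host"), e.params.get("chrom_a"),
                    e.params.get("chrom_b"),
                )
            }
            free = [c for c in chroms if c not in used]
            pool = free if len(free) >= 2 else chroms
            pick = lin.rng.choice(len(pool), size=2, replace=False)
            a, b = pool[pick[0]], pool[pick[1]]
        if a not in lin.chromosomes or b not in lin.chromosomes:
            raise ValidationError(f"scenario event {spec} names a missing chromosome")

        def draw_break(chrom: str) -> int:
            n = len(lin.chromosomes[chrom])
            margin = min(15, max(1, n // 4))
            return int(lin.rng.integers(margin, n - margin + 1))

        ba = spec.get("break_a") or draw_break(a)
        bb = spec.get("break_b") or draw_break(b)
        lin.apply_rta(a, b, ba, bb, age)
    elif kind == "INV":
        chroms = sorted(lin.chromosomes)
        c = spec.get("chromosome") or chroms[int(lin.rng.integers(0, len(chroms)))]
        if c not in lin.chromosomes:
            raise ValidationError(f"scenario event {spec} names a missing chromosome")
        genes = lin.chromosomes[c]
        n = len(genes)
        lo = spec.get("rank_start")
        hi = spec.get("rank_end")
        if lo is None or hi is None:
            # invert within a single ancestral segment (inversions nested in
            # fusion products rather than spanning their junctions)
            pivot = int(lin.rng.integers(0, n))
            proto = genes[pivot].proto
            lo = pivot
            while lo > 0 and genes[lo - 1].proto == proto:
                lo -= 1
            hi = pivot + 1
            while hi < n and genes[hi].proto == proto:
                hi += 1
            if hi - lo > 2:
                sub_lo = int(lin.rng.integers(lo, hi - 1))
                sub_hi = int(lin.rng.integers(sub_lo + 2, hi + 1))
                lo, hi = sub_lo, sub_hi
        lin.apply_inversion(c, lo, hi, age)
    elif kind == "LOSS":
        lin.fractionate(spec["retention"], age_ks=age)
    elif kind in SSD_KINDS:
        lin.apply_small_scale_duplication(
            kind, age, n_events=int(spec.get("n", 1)),
            proximal_window=int(spec.get("proximal_window", 10)),
        )
    else:
        raise ValidationError(f"unknown scenario event kind {kind!r}")


def run_scenario(config: Mapping, seed: int) -> ScenarioResult:
    """Execute a declarative scenario.

    Config keys: ``ancestor`` {n_chromosomes, genes_per_chromosome};
    ``shared_events`` (ordered, oldest first, applied to the root);
    ``split_age``; ``lineages`` mapping lineage id -> ordered event list;
    optional ``rel_sigma``, ``ks_max``, ``homologs`` (list of [a, b] pairs
    or [a, a] for self-comparison; default: all self + all cross pairs).
    """
    anc_cfg = config.get("ancestor", {})
    root = simulate_ancestor(
        int(anc_cfg.get("n_chromosomes", 11)),
        int(anc_cfg.get("genes_per_chromosome", 200)),
        seed,
    )
    for spec in config.get("shared_events", []):
        _apply_event(root, spec)
    ancestor_snapshot = root.copy()
    lineage_cfg = config.get("lineages", {"L1": []})
    split_age = float(config.get("split_age", 1.0))
    if len(lineage_cfg) > 1:
        daughters = root.split(sorted(lineage_cfg), split_age)
    else:
        daughters = {next(iter(lineage_cfg)): root}
    for lid in sorted(lineage_cfg):
        for spec in lineage_cfg[lid]:
            _apply_event(daughters[lid], spec)
    rel_sigma = float(config.get("rel_sigma", DEFAULT_REL_SIGMA))
    ks_max = float(config.get("ks_max", DEFAULT_KS_MAX))
    genomes = {lid: lin.to_genome_table(lid) for lid, lin in daughters.items()}
    truth = {lid: lin.truth_table(lid) for lid, lin in daughters.items()}
    wanted = config.get("homologs")
    if wanted is None:
        lids = sorted(daughters)
        wanted = [[l, l] for l in lids] + [
            [lids[i], lids[j]] for i in range(len(lids)) for j in range(i + 1, len(lids))
        ]
    homologs: dict[tuple[str, str], list[HomologPair]] = {}
    for k, (a, b) in enumerate(wanted):
        sub_seed = (seed * 1000003 + 7919 * k) % (2**31 - 1)
        if a == b:
            homologs[(a, b)] = homolog_pairs(
                daughters[a], a, rel_sigma=rel_sigma, ks_max=ks_max, seed=sub_seed
            )
        else:
            homologs[(a, b)] = homolog_pairs(
                daughters[a], a, daughters[b], b,
                rel_sigma=rel_sigma, ks_max=ks_max, seed=sub_seed,
            )
    return ScenarioResult(
        genomes=genomes,
        lineages=daughters,
        truth=truth,
        event_log={lid: list(lin.events) for lid, lin in daughters.items()},
        homologs=homologs,
        ancestor=ancestor_snapshot,
    )


def load_scenario(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
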