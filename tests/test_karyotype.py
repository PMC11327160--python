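"""Chromosome painting, fusion/translocation classification, ancestor
reconstruction and cross-lineage trajectory comparison."""

from collections import Counter

import numpy as np
import pytest

from paleokaryo import evosim, karyotype, ksdist, synteny
from paleokaryo.genome_model import ValidationError


def paint_lineage(lin, snapshot, seed, cscore=0.99):
    """Blocks + painting of a lineage against an ancestor snapshot proxy."""
    genome = lin.to_genome_table("EXT")
    proxy = snapshot.to_genome_table("ANC")
    pairs = evosim.homolog_pairs(lin, "EXT", snapshot, "ANC", seed=seed)
    anchors = synteny.build_anchors(genome, proxy, pairs, cscore)
    blocks = synteny.chain_blocks(anchors, 5, 25)
    return karyotype.paint_chromosomes(blocks, genome, proxy), genome, proxy


def post_wgd_lineage(seed, n=11, g=200, age=1.0):
    lin = evosim.simulate_ancestor(n, g, seed)
    lin.apply_polyploidy(2, age)
    return lin


class TestPainting:
    def test_identity_history_paints_one_proto_per_chromosome(self):
        lin = post_wgd_lineage(1, n=4, g=80)
        snapshot = lin.copy()
        painting, genome, _ = paint_lineage(lin, snapshot, 1)
        for chrom in genome.chromosomes:
            segs = painting.segments[chrom]
            assert len(segs) == 1
            assert segs[0].proto == chrom

    def test_eej_painting_reads_donor_after_host(self):
        lin = post_wgd_lineage(2, n=4, g=80)
        snapshot = lin.copy()
        lin.apply_fusion("EEJ", "P02.A", "P01.A", reverse_donor=False)
        painting, _, _ = paint_lineage(lin, snapshot, 2)
        protos = [s.proto for s in painting.segments["P01.A"]]
        assert protos == ["P01.A", "P02.A"]

    def test_ncf_painting_reads_host_donor_host(self):
        lin = post_wgd_lineage(3, n=4, g=80)
        snapshot = lin.copy()
        lin.apply_fusion("NCF", "P02.A", "P01.A", insertion_rank=40)
        painting, _, _ = paint_lineage(lin, snapshot, 3)
        protos = [s.proto for s in painting.segments["P01.A"]]
        assert protos == ["P01.A", "P02.A", "P01.A"]

    def test_painting_is_a_partition(self):
        lin = post_wgd_lineage(4, n=5, g=100)
        snapshot = lin.copy()
        lin.apply_fusion("EEJ", "P03.A", "P02.B")
        lin.fractionate({"A": 0.8, "B": 0.6})
        painting, genome, _ = paint_lineage(lin, snapshot, 4)
        for chrom in genome.chromosomes:
            segs = painting.segments[chrom]
            n = len(genome.chromosome_genes(chrom))
            assert segs[0].rank_start == 0
            assert segs[-1].rank_end == n
            for a, b in zip(segs, segs[1:]):
                assert a.rank_end == b.rank_start  # no overlap, no gap


class TestClassification:
    @pytest.mark.parametrize(
        "n_eej,n_ncf,expected_n",
        [(2, 4, 16), (3, 5, 14), (4, 1, 17), (2, 0, 20)],
    )
    def test_fusion_inventories_reproduce_extant_counts(self, n_eej, n_ncf, expected_n):
        """The per-species fusion inventories on a 22-chromosome post-WGD
        karyotype yield the observed haploid numbers (n=16/14/17/20)."""
        seed = 500 + 10 * n_eej + n_ncf
        lin = post_wgd_lineage(seed)
        snapshot = lin.copy()
        chroms = sorted(lin.chromosomes)
        order = list(lin.rng.permutation(len(chroms)))
        k = 0
        for _ in range(n_eej):
            lin.apply_fusion("EEJ", chroms[order[k]], chroms[order[k + 1]])
            k += 2
        for _ in range(n_ncf):
            host = chroms[order[k + 1]]
            size = len(lin.chromosomes[host])
            lin.apply_fusion(
                "NCF", chroms[order[k]], host,
                int(lin.rng.integers(25, size - 25)),
            )
            k += 2
        painting, _, _ = paint_lineage(lin, snapshot, seed)
        events, arithmetic = karyotype.classify_events(painting)
        assert arithmetic["EEJ"] == n_eej
        assert arithmetic["NCF"] == n_ncf
        assert arithmetic["n_extant"] == expected_n
        assert arithmetic["balanced"]

    def test_no_event_genome_yields_empty_event_list(self):
        lin = post_wgd_lineage(6, n=4, g=80)
        snapshot = lin.copy()
        painting, _, _ = paint_lineage(lin, snapshot, 6)
        events, arithmetic = karyotype.classify_events(painting)
        assert events == []
        assert arithmetic["balanced"]

    def test_rta_detected_as_single_paired_event(self):
        lin = post_wgd_lineage(7, n=4, g=100)
        snapshot = lin.copy()
        lin.apply_rta("P01.A", "P02.A", 50, 60)
        painting, _, _ = paint_lineage(lin, snapshot, 7)
        events, arithmetic = karyotype.classify_events(painting)
        kinds = Counter(e.kind for e in events)
        assert kinds == {"RTA": 1}
        assert set(events[0].protos) == {"P01.A", "P02.A"}

    def test_eej_chain_of_three_protos(self):
        # two successive end-to-end joins onto one chromosome (the A6+C6+B6
        # pattern): both junctions must be read as EEJ
        lin = post_wgd_lineage(8, n=4, g=80)
        snapshot = lin.copy()
        lin.apply_fusion("EEJ", "P02.A", "P01.A")
        lin.apply_fusion("EEJ", "P03.A", "P01.A")
        painting, _, _ = paint_lineage(lin, snapshot, 8)
        events, arithmetic = karyotype.classify_events(painting)
        assert arithmetic["EEJ"] == 2 and arithmetic["NCF"] == 0
        assert arithmetic["balanced"]

    def test_event_recovery_battery(self):
        """Random histories (<=3 fusions, <=2 RTA, <=2 inversions, retention
        >=0.5): EEJ/NCF counts recovered exactly in >=90% of scenarios."""
        ok = 0
        reps = 20
        for i in range(reps):
            seed = 2000 + i
            rng = np.random.default_rng(seed)
            n_eej = int(rng.integers(0, 3))
            n_ncf = int(rng.integers(0, max(1, 4 - n_eej)))
            events = [
                {"kind": "WGD", "age": 1.0},
                {"kind": "LOSS", "retention": {
                    "A": float(rng.uniform(0.5, 1.0)),
                    "B": float(rng.uniform(0.5, 1.0))}},
            ]
            events += [{"kind": "EEJ"}] * n_eej + [{"kind": "NCF"}] * n_ncf
            events += [{"kind": "RTA"}] * int(rng.integers(0, 3))
            events += [{"kind": "INV"}] * int(rng.integers(0, 3))
            cfg = {"ancestor": {"n_chromosomes": 11, "genes_per_chromosome": 200},
                   "lineages": {"L": events}, "homologs": []}
            res = evosim.run_scenario(cfg, seed)
            cfg0 = {"ancestor": {"n_chromosomes": 11, "genes_per_chromosome": 200},
                    "lineages": {"L": [{"kind": "WGD", "age": 1.0}]}, "homologs": []}
            snap = evosim.run_scenario(cfg0, seed).lineages["L"]
            painting, _, _ = paint_lineage(res.lineages["L"], snap, seed)
            _, arithmetic = karyotype.classify_events(painting)
            ok += arithmetic["EEJ"] == n_eej and arithmetic["NCF"] == n_ncf
        assert ok >= 0.9 * reps


class TestReconstruction:
    def build_self_blocks(self, lin, seed):
        genome = lin.to_genome_table("CONS")
        pairs = evosim.homolog_pairs(lin, "CONS", seed=seed)
        blocks = synteny.chain_blocks(
            synteny.build_anchors(genome, genome, pairs, 0.99), 5, 25
        )
        for b in blocks:
            ksdist.annotate_block_ks(b, [a.ks for a in b.anchors])
        return genome, blocks

    def accuracy(self, lin, genome, kmap):
        truth = lin.truth_table("CONS")
        proto_of = {}
        for gid, chrom, lo, hi, proto in kmap.segment_assignments:
            for g in genome.chromosome_genes(chrom)[lo:hi]:
                proto_of[g.gene_id] = proto
        truth["recon"] = truth.gene_id.map(proto_of)
        ok = tot = 0
        for _, sub in truth.groupby("proto"):
            c = Counter(sub.recon.dropna())
            if c:
                ok += c.most_common(1)[0][1]
            tot += len(sub)
        return ok / tot

    def test_recovers_protos_without_fusions(self):
        lin = post_wgd_lineage(30)
        lin.fractionate({"A": 0.8, "B": 0.6})
        genome, blocks = self.build_self_blocks(lin, 30)
        kmap, report = karyotype.reconstruct_ancestor(genome, blocks, 2, wgd_age=1.0)
        assert report["n_protos"] == 11
        assert report["valid"]
        assert self.accuracy(lin, genome, kmap) >= 0.95

    def test_recovers_protos_despite_six_fusions(self):
        lin = post_wgd_lineage(31)
        lin.fractionate({"A": 0.8, "B": 0.6})
        chroms = sorted(lin.chromosomes)
        order = list(lin.rng.permutation(len(chroms)))
        # draw fusion pairs that never fuse both copies of one proto pair:
        # reciprocal cross-nesting of matching copies leaves the homeologous
        # block graph cyclic and the two protos genuinely inseparable
        pairs = []
        used_proto_pairs = set()
        i = 0
        while len(pairs) < 6 and i + 1 < len(order):
            a, b = chroms[order[i]], chroms[order[i + 1]]
            key = frozenset((a.split(".")[0], b.split(".")[0]))
            if key not in used_proto_pairs:
                used_proto_pairs.add(key)
                pairs.append((a, b))
                i += 2
            else:
                i += 1
        for k, (donor, host) in enumerate(pairs):
            if k < 4:
                lin.apply_fusion("EEJ", donor, host)
            else:
                size = len(lin.chromosomes[host])
                lin.apply_fusion("NCF", donor, host,
                                 int(lin.rng.integers(25, size - 25)))
        genome, blocks = self.build_self_blocks(lin, 31)
        kmap, report = karyotype.reconstruct_ancestor(genome, blocks, 2, wgd_age=1.0)
        assert report["n_protos"] == 11
        assert self.accuracy(lin, genome, kmap) >= 0.95

    def test_outgroup_validation_passes_for_true_ancestor(self):
        root = evosim.simulate_ancestor(6, 150, 32)
        d = root.split(["CONS", "OUT"], 1.6)
        lin, out = d["CONS"], d["OUT"]
        lin.apply_polyploidy(2, 1.0)
        lin.fractionate({"A": 0.85, "B": 0.7})
        genome, blocks = self.build_self_blocks(lin, 32)
        opairs = evosim.homolog_pairs(lin, "CONS", out, "OUT", seed=33)
        oblocks = synteny.chain_blocks(
            synteny.build_anchors(genome, out.to_genome_table("OUT"), opairs, 0.99),
            5, 25,
        )
        kmap, report = karyotype.reconstruct_ancestor(
            genome, blocks, 2, wgd_age=1.0, outgroup_blocks=oblocks
        )
        assert report["valid"]
        for entry in report["protos"].values():
            assert entry["outgroup_collinear_fraction"] >= 0.6

    def test_wrong_multiplicity_claim_is_rejected(self):
        lin = post_wgd_lineage(34, n=5, g=100)
        genome, blocks = self.build_self_blocks(lin, 34)
        with pytest.raises(ValidationError, match="multiplicity"):
            karyotype.reconstruct_ancestor(genome, blocks, 3)

    def test_reconstruction_is_deterministic(self):
        lin = post_wgd_lineage(35, n=5, g=100)
        lin.fractionate({"A": 0.8, "B": 0.7})
        genome, blocks = self.build_self_blocks(lin, 35)
        k1, _ = karyotype.reconstruct_ancestor(genome, blocks, 2, wgd_age=1.0)
        k2, _ = karyotype.reconstruct_ancestor(genome, blocks, 2, wgd_age=1.0)
        assert k1.segment_assignments == k2.segment_assignments


class TestTrajectory:
    def run_lineages(self, seed, n_lineages=3, drop_second_fusion_in=None):
        root = post_wgd_lineage(seed, n=11, g=120)
        snapshot = root.copy()
        # two pre-split fusions shared by (almost) everyone
        root.apply_fusion("EEJ", "P01.A", "P02.A", reverse_donor=False)
        pre_second = root.copy()
        root.apply_fusion("EEJ", "P03.B", "P04.B", reverse_donor=False)
        lids = [f"L{i}" for i in range(n_lineages)]
        classified = {}
        for i, lid in enumerate(lids):
            lin = (pre_second if lid == drop_second_fusion_in else root).copy()
            lin.rng = np.random.default_rng(seed + i)
            # one lineage-specific fusion each
            chroms = sorted(lin.chromosomes)
            lin.apply_fusion("EEJ", chroms[2 * i + 4], chroms[2 * i + 5])
            painting, _, _ = paint_lineage(lin, snapshot, seed + i)
            classified[lid] = karyotype.classify_events(painting)
        return classified

    def test_pre_split_fusion_reported_shared(self):
        classified = self.run_lineages(40, n_lineages=2)
        summary, shared = karyotype.trajectory_report(classified)
        shared_keys = shared[shared.shared]
        assert any(
            set(p.split("+")) == {"P01.A", "P02.A"} for p in shared_keys.protos
        )
        # lineage-specific fusions are not shared
        assert (shared.n_lineages == 1).sum() >= 2

    def test_single_lineage_intersection_empty(self):
        classified = self.run_lineages(41, n_lineages=1)
        _, shared = karyotype.trajectory_report(classified)
        assert not shared.empty or shared.empty  # table well-formed
        assert (shared["shared"] == False).all()  # noqa: E712

    def test_fusion_missing_from_one_of_eight_lineages(self):
        classified = self.run_lineages(42, n_lineages=8, drop_second_fusion_in="L3")
        _, shared = karyotype.trajectory_report(classified)
        row = shared[shared.protos.map(lambda p: set(p.split("+")) == {"P03.B", "P04.B"})]
        assert len(row) == 1
        assert int(row.n_lineages.iloc[0]) == 7
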