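"""Simulator semantics: polyploidy, rearrangement, fractionation, small-scale
duplication, divergence bookkeeping, and scenario determinism."""

import collections

import numpy as np
import pytest
from scipy import stats

from paleokaryo import evosim
from paleokaryo.evosim import (
    Lineage,
    generate_codon_pair,
    homolog_pairs,
    run_scenario,
    simulate_ancestor,
)
from paleokaryo.genome_model import ValidationError
from paleokaryo.ksdist import GENETIC_CODE, ng_ks


def gene_ids(lin):
    return sorted(g.family for gs in lin.chromosomes.values() for g in gs)


class TestAncestor:
    def test_construction(self):
        lin = simulate_ancestor(11, 200, seed=1)
        assert lin.n_chromosomes == 11
        assert lin.n_genes() == 2200
        fams = gene_ids(lin)
        assert len(set(fams)) == 2200  # all families singleton

    def test_degenerate_single_gene(self):
        lin = simulate_ancestor(1, 1, seed=0)
        assert lin.n_chromosomes == 1 and lin.n_genes() == 1

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValidationError):
            simulate_ancestor(0, 5, seed=0)
        with pytest.raises(ValidationError):
            simulate_ancestor(5, 0, seed=0)

    def test_same_seed_identical_output(self):
        a = simulate_ancestor(3, 50, seed=9).to_genome_table("x")
        b = simulate_ancestor(3, 50, seed=9).to_genome_table("x")
        assert a.to_frame().equals(b.to_frame())


class TestPolyploidy:
    def test_wgd_doubles_chromosomes(self):
        lin = simulate_ancestor(11, 20, seed=1)
        lin.apply_polyploidy(2, 1.0)
        assert lin.n_chromosomes == 22
        assert lin.n_genes() == 440

    def test_wgt_triples_seven_to_twentyone(self):
        # the gamma-triplication analog: 7 eudicot proto-chromosomes -> 21
        lin = simulate_ancestor(7, 20, seed=1)
        lin.apply_polyploidy(3, 1.8)
        assert lin.n_chromosomes == 21

    def test_invalid_multiplicity(self):
        lin = simulate_ancestor(2, 10, seed=1)
        with pytest.raises(ValidationError):
            lin.apply_polyploidy(4, 1.0)

    def test_pair_ks_mean_near_event_age(self):
        lin = simulate_ancestor(5, 200, seed=2)
        lin.apply_polyploidy(2, 1.0)
        pairs = homolog_pairs(lin, "G", seed=2)
        ks = np.array([p.ks for p in pairs])
        assert len(ks) == 1000
        se = ks.std(ddof=1) / np.sqrt(len(ks))
        assert abs(ks.mean() - 1.0) < 2 * se + 1e-9


class TestFusion:
    def test_eej_concatenates(self):
        lin = simulate_ancestor(2, 5, seed=1)
        a_fams = [g.family for g in lin.chromosomes["P01"]]
        b_fams = [g.family for g in lin.chromosomes["P02"]]
        lin.apply_fusion("EEJ", "P02", "P01", reverse_donor=False)
        assert lin.n_chromosomes == 1
        assert [g.family for g in lin.chromosomes["P01"]] == a_fams + b_fams

    def test_ncf_inserts_internally(self):
        lin = simulate_ancestor(2, 6, seed=1)
        a_fams = [g.family for g in lin.chromosomes["P01"]]
        b_fams = [g.family for g in lin.chromosomes["P02"]]
        lin.apply_fusion("NCF", "P02", "P01", insertion_rank=2, reverse_donor=False)
        assert lin.n_chromosomes == 1
        assert [g.family for g in lin.chromosomes["P01"]] == (
            a_fams[:2] + b_fams + a_fams[2:]
        )

    def test_terminal_ncf_is_rejected_as_eej(self):
        lin = simulate_ancestor(2, 6, seed=1)
        with pytest.raises(ValidationError, match="EEJ"):
            lin.apply_fusion("NCF", "P02", "P01", insertion_rank=0)

    def test_chromosome_count_bookkeeping(self):
        # 22 chromosomes, 2 EEJ + 4 NCF -> 16
        lin = simulate_ancestor(11, 30, seed=4)
        lin.apply_polyploidy(2, 1.0)
        chroms = sorted(lin.chromosomes)
        for i in range(2):
            lin.apply_fusion("EEJ", chroms[2 * i], chroms[2 * i + 1])
        for i in range(2, 6):
            lin.apply_fusion("NCF", chroms[2 * i], chroms[2 * i + 1], insertion_rank=10)
        assert lin.n_chromosomes == 16


class TestRtaInversion:
    def test_rta_count_neutral_and_involutive(self):
        lin = simulate_ancestor(2, 10, seed=1)
        before = {c: [g.family for g in gs] for c, gs in lin.chromosomes.items()}
        multiset_before = sorted(f for fs in before.values() for f in fs)
        lin.apply_rta("P01", "P02", 4, 6)
        assert lin.n_chromosomes == 2
        multiset_after = sorted(
            g.family for gs in lin.chromosomes.values() for g in gs
        )
        assert multiset_after == multiset_before
        lin.apply_rta("P01", "P02", 4, 6)  # inverse exchange at the junction
        after = {c: [g.family for g in gs] for c, gs in lin.chromosomes.items()}
        assert after == before

    def test_rta_terminal_break_rejected(self):
        lin = simulate_ancestor(2, 10, seed=1)
        with pytest.raises(ValidationError):
            lin.apply_rta("P01", "P02", 0, 5)

    def test_inversion_twice_is_identity(self):
        lin = simulate_ancestor(1, 12, seed=1)
        before = [(g.family, g.strand) for g in lin.chromosomes["P01"]]
        lin.apply_inversion("P01", 3, 9)
        lin.apply_inversion("P01", 3, 9)
        assert [(g.family, g.strand) for g in lin.chromosomes["P01"]] == before

    def test_single_gene_inversion_flips_strand_only(self):
        lin = simulate_ancestor(1, 5, seed=1)
        fam_before = [g.family for g in lin.chromosomes["P01"]]
        strand_before = lin.chromosomes["P01"][2].strand
        lin.apply_inversion("P01", 2, 3)
        assert [g.family for g in lin.chromosomes["P01"]] == fam_before
        assert lin.chromosomes["P01"][2].strand != strand_before


class TestFractionation:
    def test_full_retention_is_identity(self):
        lin = simulate_ancestor(3, 40, seed=1)
        lin.apply_polyploidy(2, 1.0)
        n = lin.n_genes()
        lin.fractionate({"A": 1.0, "B": 1.0})
        assert lin.n_genes() == n

    def test_biased_retention_within_binomial_bounds(self):
        lin = simulate_ancestor(10, 200, seed=6)  # 2,000 duplicated families
        lin.apply_polyploidy(2, 1.0)
        lin.fractionate({"A": 0.8, "B": 0.5})
        counts = collections.Counter()
        wgd_id = lin.events[0].event_id
        for gs in lin.chromosomes.values():
            for g in gs:
                counts[g.labels[wgd_id]] += 1
        # the keep-one-copy rule conditions each family on survival, so the
        # per-copy retention is p / (1 - q) with q the probability that every
        # copy is lost (derived from the sampling scheme, q = 0.2 * 0.5)
        q = (1 - 0.8) * (1 - 0.5)
        for label, p in (("A", 0.8), ("B", 0.5)):
            pc = p / (1 - q)
            mean = 2000 * pc
            sd = np.sqrt(2000 * pc * (1 - pc))
            assert abs(counts[label] - mean) < 4 * sd

    def test_every_family_keeps_a_copy(self):
        lin = simulate_ancestor(4, 100, seed=7)
        lin.apply_polyploidy(2, 1.0)
        lin.fractionate({"A": 0.1, "B": 0.1})
        fams = {g.family for gs in lin.chromosomes.values() for g in gs}
        assert len(fams) == 400

    def test_higher_retention_side_dominates(self):
        lin = simulate_ancestor(6, 150, seed=8)
        lin.apply_polyploidy(2, 1.0)
        lin.fractionate({"A": 0.9, "B": 0.5})
        wgd_id = lin.events[0].event_id
        counts = collections.Counter(
            g.labels[wgd_id] for gs in lin.chromosomes.values() for g in gs
        )
        assert counts["A"] > counts["B"]


class TestSmallScaleDuplication:
    def test_td_child_is_rank_adjacent(self):
        lin = simulate_ancestor(2, 50, seed=9)
        lin.apply_small_scale_duplication("TD", 0.2)
        dup = [
            (c, i) for c, gs in lin.chromosomes.items()
            for i, g in enumerate(gs) if g.mode == "TD"
        ]
        assert len(dup) == 1
        c, i = dup[0]
        child = lin.chromosomes[c][i]
        sibs = [g for g in lin.chromosomes[c] if g.family == child.family]
        assert len(sibs) == 2
        ranks = sorted(
            j for j, g in enumerate(lin.chromosomes[c]) if g.family == child.family
        )
        assert ranks[1] - ranks[0] == 1

    def test_trd_parent_keeps_locus(self):
        lin = simulate_ancestor(3, 50, seed=10)
        before = {g.uid: (c, i) for c, gs in lin.chromosomes.items()
                  for i, g in enumerate(gs)}
        ev = lin.apply_small_scale_duplication("TRD", 0.2)[0]
        parent_uid = ev.params["parent_uid"]
        after = {g.uid: (c, i) for c, gs in lin.chromosomes.items()
                 for i, g in enumerate(gs)}
        assert after[parent_uid][0] == before[parent_uid][0]
        child = [g for gs in lin.chromosomes.values() for g in gs if g.mode == "TRD"]
        assert len(child) == 1

    @pytest.mark.parametrize("kind", ["TD", "PD", "TRD", "DSD"])
    def test_each_event_adds_one_gene(self, kind):
        lin = simulate_ancestor(3, 50, seed=11)
        n = lin.n_genes()
        lin.apply_small_scale_duplication(kind, 0.2, n_events=5)
        assert lin.n_genes() == n + 5


class TestCodonPairs:
    def test_zero_target_identical(self):
        a, b = generate_codon_pair(50, 0.0, seed=1)
        assert a == b

    def test_translation_unchanged(self):
        a, b = generate_codon_pair(150, 0.6, seed=2)
        prot_a = [GENETIC_CODE[a[i:i + 3]] for i in range(0, len(a), 3)]
        prot_b = [GENETIC_CODE[b[i:i + 3]] for i in range(0, len(b), 3)]
        assert prot_a == prot_b

    def test_unreachable_target_reports_maximum(self):
        with pytest.raises(ValidationError, match="maximum achievable"):
            generate_codon_pair(10, 50.0, seed=3)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValidationError):
            generate_codon_pair(5, 0.1, seed=0)


class TestScenarios:
    CFG = {
        "ancestor": {"n_chromosomes": 5, "genes_per_chromosome": 60},
        "split_age": 1.2,
        "lineages": {
            "A": [{"kind": "WGD", "age": 0.6},
                  {"kind": "LOSS", "retention": {"A": 0.8, "B": 0.6}}],
            "B": [],
        },
        "homologs": [["A", "B"], ["A", "A"]],
    }

    def test_determinism(self):
        r1 = run_scenario(self.CFG, seed=5)
        r2 = run_scenario(self.CFG, seed=5)
        for lid in r1.genomes:
            assert r1.genomes[lid].to_frame().equals(r2.genomes[lid].to_frame())
        assert r1.homologs.keys() == r2.homologs.keys()
        for key in r1.homologs:
            assert r1.homologs[key] == r2.homologs[key]

    def test_gamma_only_keeps_ancestral_chromosome_count(self):
        cfg = {
            "ancestor": {"n_chromosomes": 7, "genes_per_chromosome": 30},
            "shared_events": [{"kind": "WGT", "age": 1.8}],
            "split_age": 1.2,
            "lineages": {"X": [], "Y": []},
            "homologs": [],
        }
        res = run_scenario(cfg, seed=1)
        assert res.genomes["X"].n_chromosomes == 21
        assert res.genomes["Y"].n_chromosomes == 21

    def test_lineage_specific_triploidy_labels(self):
        cfg = {
            "ancestor": {"n_chromosomes": 4, "genes_per_chromosome": 30},
            "shared_events": [{"kind": "WGT", "age": 1.8}],
            "split_age": 1.2,
            "lineages": {"Q": [{"kind": "WGT", "age": 0.66}], "O": []},
            "homologs": [],
        }
        res = run_scenario(cfg, seed=2)
        truth = res.truth["Q"]
        poly_cols = [c for c in truth.columns if c.startswith("subgenome_e")]
        assert len(poly_cols) == 2  # shared gamma + lineage-specific WGT
        own = poly_cols[-1]
        per_family = truth.groupby("family")[own].nunique()
        assert per_family.max() == 3  # three subgenome labels per ancestral gene

    def test_chromosome_count_bookkeeping_random_scenarios(self):
        for seed in range(6):
            rng = np.random.default_rng(300 + seed)
            n_eej = int(rng.integers(0, 3))
            n_ncf = int(rng.integers(0, 3))
            events = [{"kind": "WGD", "age": 1.0}]
            events += [{"kind": "EEJ"}] * n_eej + [{"kind": "NCF"}] * n_ncf
            events += [{"kind": "RTA"}, {"kind": "INV"}]
            cfg = {
                "ancestor": {"n_chromosomes": 6, "genes_per_chromosome": 80},
                "lineages": {"L": events},
                "homologs": [],
            }
            res = run_scenario(cfg, seed=300 + seed)
            assert res.genomes["L"].n_chromosomes == 12 - n_eej - n_ncf

    def test_gene_multiset_conserved_by_structural_events(self):
        lin = simulate_ancestor(4, 50, seed=13)
        lin.apply_polyploidy(2, 1.0)
        before = sorted(g.uid for gs in lin.chromosomes.values() for g in gs)
        chroms = sorted(lin.chromosomes)
        lin.apply_fusion("EEJ", chroms[0], chroms[1])
        lin.apply_fusion("NCF", chroms[2], chroms[3], insertion_rank=20)
        lin.apply_rta(chroms[4], chroms[5], 10, 30)
        lin.apply_inversion(chroms[6], 5, 25)
        after = sorted(g.uid for gs in lin.chromosomes.values() for g in gs)
        assert after == before

    def test_older_events_have_stochastically_larger_ks(self):
        lin = simulate_ancestor(5, 200, seed=14)
        old = lin.apply_polyploidy(2, 1.0)
        young = lin.apply_polyploidy(2, 0.4)
        pairs = homolog_pairs(lin, "G", seed=14)
        genes = {f"G_{g.uid:06d}": g for gs in lin.chromosomes.values() for g in gs}
        ks_old, ks_young = [], []
        for p in pairs:
            age = lin.divergence_age(genes[p.gene_a], genes[p.gene_b])
            (ks_old if age == 1.0 else ks_young).append(p.ks)
        u = stats.mannwhitneyu(ks_old[:500], ks_young[:500], alternative="greater")
        assert u.pvalue < 0.01

    def test_inconsistent_scenario_names_event(self):
        cfg = {
            "ancestor": {"n_chromosomes": 2, "genes_per_chromosome": 10},
            "lineages": {"L": [{"kind": "EEJ", "donor": "P09", "host": "P01"}]},
            "homologs": [],
        }
        with pytest.raises(ValidationError):
            run_scenario(cfg, seed=1)
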