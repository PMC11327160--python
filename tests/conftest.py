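"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import pytest

from paleokaryo import evosim, ksdist, synteny
from paleokaryo.genome_model import GeneRecord, GenomeTable


@pytest.fixture(scope="session")
def toy_genome() -> GenomeTable:
    genes = [
        GeneRecord("g1", "chr1", 0, 100, "+", 0, "famA"),
        GeneRecord("g2", "chr1", 200, 300, "-", 1, "famB"),
        GeneRecord("g3", "chr1", 400, 500, "+", 2, "famC"),
        GeneRecord("g4", "chr2", 0, 150, "+", 0, "famA"),
    ]
    return GenomeTable("toy", genes)


@pytest.fixture(scope="session")
def wgd_selfcomp():
    """A genome carrying one WGD (age 1.0) with mild biased fractionation,
    plus its self-comparison homologs and chained blocks."""
    lin = evosim.simulate_ancestor(6, 150, seed=42)
    wgd = lin.apply_polyploidy(2, 1.0)
    lin.fractionate({"A": 0.85, "B": 0.65})
    genome = lin.to_genome_table("SELF")
    pairs = evosim.homolog_pairs(lin, "SELF", seed=42)
    anchors = synteny.build_anchors(genome, genome, pairs, 0.99)
    blocks = synteny.chain_blocks(anchors, 5, 25)
    for b in blocks:
        ksdist.annotate_block_ks(b, [a.ks for a in b.anchors])
    return {"lineage": lin, "wgd": wgd, "genome": genome, "pairs": pairs,
            "blocks": blocks}


@pytest.fixture(scope="session")
def triploid_vs_reference():
    """Query lineage with one post-split triploidization vs an event-free
    reference, with cross-genome homologs and blocks (query on the A axis)."""
    cfg = {
        "ancestor": {"n_chromosomes": 8, "genes_per_chromosome": 150},
        "split_age": 1.5,
        "lineages": {
            "REF": [],
            "QRY": [
                {"kind": "WGT", "age": 0.8},
                {"kind": "LOSS", "retention": {"A": 0.8, "B": 0.7, "C": 0.7}},
            ],
        },
        "homologs": [["QRY", "REF"]],
    }
    res = evosim.run_scenario(cfg, seed=7)
    pairs = res.homologs[("QRY", "REF")]
    anchors = synteny.build_anchors(res.genomes["QRY"], res.genomes["REF"], pairs, 0.99)
    blocks = synteny.chain_blocks(anchors, 5, 25)
    return {"result": res, "blocks": blocks}
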