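"""End-to-end pipeline: simulate -> synteny -> Ks -> ploidy -> karyotype ->
fractionation, with seeded stages and a single JSON report.

The pipeline runs a declarative simulation scenario (see
:mod:`paleokaryo.evosim`), chains synteny blocks for every requested
comparison, fits Ks peaks to the self-comparisons, computes modal depth
ratios and ploidy calls against a designated reference lineage, paints each
lineage against the shared pre-split ancestor and classifies its fusion
history, and (when subgenome analysis is configured) tallies the
fractionation statistics.  Every stage writes its outputs under the output
directory with the config hash and seed embedded, and leaves a marker file
so a failed run can be diagnosed stage by stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from . import evosim, fractionation, karyotype, ksdist, ploidy, synteny
from .genome_model import ValidationError, write_gene_table

__all__ = ["PipelineConfig", "run_pipeline", "make_figures"]

STAGES = ("simulate", "synteny", "ks", "ploidy", "karyotype", "report")


@dataclass
class PipelineConfig:
    scenario: dict
    seed: int
    out_dir: Path
    reference: str | None = None  # lineage used as depth-ratio reference
    cscore: float = 0.99
    # depth must see every equally aged co-ortholog copy, so the blocks that
    # feed syntenic_depth are chained from a permissive homolog set
    depth_cscore: float = 0.5
    min_block_size: int = 5
    max_gap: int = 25
    k_max: int = 5
    min_segment_genes: int = 10

    def validate(self) -> None:
        if not (0 < self.cscore <= 1):
            raise ValidationError("cscore must be in (0, 1]")
        if self.min_block_size < 2:
            raise ValidationError("min_block_size must be >= 2")
        if self.max_gap < 1:
            raise ValidationError("max_gap must be >= 1")
        if self.k_max < 1:
            raise ValidationError("k_max must be >= 1")
        lineages = self.scenario.get("lineages", {})
        if self.reference is not None and self.reference not in lineages:
            raise ValidationError(f"reference {self.reference!r} not a lineage")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "scenario": self.scenario,
                "seed": self.seed,
                "cscore": self.cscore,
                "min_block_size": self.min_block_size,
                "max_gap": self.max_gap,
                "k_max": self.k_max,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "STAGES.done"
    done: list[str] = []

    def mark(stage: str) -> None:
        done.append(stage)
        marker.write_text("\n".join(done) + "\n")

    provenance = {"config_hash": config.config_hash, "seed": config.seed}
    report: dict = {"provenance": provenance}

    # simulate ------------------------------------------------------------
    result = evosim.run_scenario(config.scenario, _stage_seed(config.seed, "simulate"))
    for lid, genome in sorted(result.genomes.items()):
        write_gene_table(genome, out / f"{lid}.bed", "BED")
    mark("simulate")

    # synteny -------------------------------------------------------------
    blocks: dict[tuple[str, str], list[synteny.SyntenyBlock]] = {}
    for (a, b), pairs in sorted(result.homologs.items()):
        anchors = synteny.build_anchors(
            result.genomes[a], result.genomes[b], pairs, config.cscore
        )
        blocks[(a, b)] = synteny.chain_blocks(
            anchors, config.min_block_size, config.max_gap
        )
        for blk in blocks[(a, b)]:
            ksdist.annotate_block_ks(blk, [x.ks for x in blk.anchors])
        synteny.write_blocks(blocks[(a, b)], out / f"blocks.{a}-{b}.tsv")
    mark("synteny")

    # ks ------------------------------------------------------------------
    ks_models: dict[str, dict] = {}
    for (a, b), blks in sorted(blocks.items()):
        if a != b:
            continue
        medians = [blk.median_ks for blk in blks if blk.median_ks is not None]
        stream = "block_medians"
        values = medians
        if len(values) < 50:
            # small genomes yield few blocks: fall back to per-pair Ks
            values = [x.ks for blk in blks for x in blk.anchors if x.ks is not None]
            stream = "pair_ks"
        if len(values) >= 50:
            model = ksdist.fit_ks_peaks(
                values, config.k_max, seed=_stage_seed(config.seed, f"ks:{a}")
            )
            ks_models[a] = {
                "k": model.k,
                "components": model.components,
                "bic": model.bic,
                "n_points": model.n_points,
                "stream": stream,
            }
    report["ks_models"] = ks_models
    mark("ks")

    # ploidy --------------------------------------------------------------
    ratios: dict[str, dict] = {}
    ref = config.reference
    if ref is not None:
        for lid in sorted(result.genomes):
            if lid == ref:
                continue
            key = (lid, ref) if (lid, ref) in blocks else (ref, lid)
            if key not in blocks:
                continue
            depth_anchors = synteny.build_anchors(
                result.genomes[key[0]], result.genomes[key[1]],
                result.homologs[key], config.depth_cscore,
            )
            depth_blocks = synteny.chain_blocks(
                depth_anchors, config.min_block_size, config.max_gap
            )
            profile = ploidy.syntenic_depth(
                depth_blocks, result.genomes[key[0]], result.genomes[key[1]],
                config.min_block_size,
            )
            qr = ploidy.depth_ratio(profile)
            # orient the ratio query-first regardless of block orientation
            ratio = qr if key[0] == lid else (qr[1], qr[0])
            ratios[lid] = {"ratio": list(ratio), "reference": ref}
    report["depth_ratios"] = ratios
    mark("ploidy")

    # karyotype ------------------------------------------------------------
    classified: dict[str, tuple] = {}
    for lid, lin in sorted(result.lineages.items()):
        # paint against the ploidy-matched ancestor: the snapshot taken right
        # after the lineage's most recent polyploidy (or the shared pre-split
        # ancestor for lineages without one)
        anc = lin.poly_snapshots[-1] if lin.poly_snapshots else result.ancestor
        proxy = anc.to_genome_table("ANCPROXY")
        pairs = evosim.homolog_pairs(
            lin, lid, anc, "ANCPROXY",
            seed=_stage_seed(config.seed, f"paint:{lid}"),
        )
        anchors = synteny.build_anchors(
            result.genomes[lid], proxy, pairs, config.cscore
        )
        blks = synteny.chain_blocks(anchors, config.min_block_size, config.max_gap)
        painting = karyotype.paint_chromosomes(
            blks, result.genomes[lid], proxy,
            min_segment_genes=config.min_segment_genes,
        )
        events, arithmetic = karyotype.classify_events(painting)
        classified[lid] = (events, arithmetic)
    summary, shared = karyotype.trajectory_report(classified)
    report["karyotype"] = {
        "summary": summary.to_dict(orient="records"),
        "shared_events": shared.to_dict(orient="records"),
    }
    mark("karyotype")

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    mark("report")
    return report


def make_figures(report: Mapping, out_dir: str | Path) -> list[Path]:
    """Static figures from a pipeline report: Ks histograms with fitted
    mixture curves (one per self-comparison).  Deterministic given the
    report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for lid, model in sorted(report.get("ks_models", {}).items()):
        fig, ax = plt.subplots(figsize=(6, 4))
        xs = np.linspace(0.0, 3.0, 400)
        total = np.zeros_like(xs)
        for w, mu, sd in model["components"]:
            pdf = w * np.exp(-0.5 * ((xs - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
            ax.plot(xs, pdf, lw=1)
            total += pdf
        ax.plot(xs, total, "k--", lw=1)
        ax.set_xlabel("Ks")
        ax.set_ylabel("density")
        ax.set_title(f"{lid}: fitted Ks peaks (k={model['k']})")
        path = out / f"ks_{lid}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
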