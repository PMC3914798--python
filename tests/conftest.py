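"""Shared fixtures: a small simulated world exercised by most suites.

Everything is generated at test time from seeds; nothing is read from
disk except files the tests themselves write to tmp paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import settings

import targetfirst as tf

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@dataclass
class SimWorld:
    """A simulated genome with targets, variants, reads and target build."""

    cfg: tf.SimConfig
    sim: tf.SimGenome
    haps: tf.Haplotypes
    pairs: list[tf.ReadPair]
    regions: list[tf.GenomicInterval]
    target: dict[str, str]
    tmap: tf.TargetMap

    @property
    def genome(self) -> dict[str, str]:
        return self.sim.genome


def build_world(cfg: tf.SimConfig, pad: int = 550) -> SimWorld:
    sim = tf.simulate_genome(cfg)
    haps = tf.inject_variants(sim.genome, cfg)
    pairs = tf.simulate_reads(haps, cfg)
    target_models = [
        (g, chrom, exons)
        for g, chrom, _, exons in sim.gene_models
        if g in sim.target_genes
    ]
    exons = [
        tf.GenomicInterval(chrom, s, e)
        for _, chrom, ex in target_models
        for s, e in ex
    ]
    regions = tf.pad_and_merge(
        exons, pad, {c: len(s) for c, s in sim.genome.items()}
    )
    contigs, tmap = tf.extract_target(sim.genome, regions)
    return SimWorld(cfg, sim, haps, pairs, regions, dict(contigs), tmap)


@pytest.fixture(scope="session")
def small_world() -> SimWorld:
    """30 kb genome, 4 target genes, one off-target paralog, 20x reads."""
    cfg = tf.SimConfig(
        genome_length=30_000,
        n_genes=4,
        coverage=20,
        seed=7,
        paralogs=[tf.ParalogSpec("GENE1", identity=0.95,
                                 inside_target=False)],
    )
    return build_world(cfg)


@pytest.fixture(scope="session")
def small_iterative(small_world: SimWorld) -> tf.IterativeResult:
    """Full iterative run (with step 3) on the small world."""
    aligner = tf.BuiltinAligner(flm=small_world.cfg.flm)
    return tf.run_iterative(
        small_world.pairs,
        small_world.genome,
        small_world.target,
        small_world.regions,
        small_world.tmap,
        aligner,
        finish=True,
    )
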