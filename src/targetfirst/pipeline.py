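"""The three-step iterative workflow.

Step 1 aligns *all* read pairs to the compact target reference and keeps
any pair with at least one mapped mate — a cheap, permissive capture.
Step 2 realigns the captured reads to the whole genome: reads that were
only *forcibly* mapped in step 1 (their true locus is elsewhere, e.g. an
off-target paralog) relocate and their pairs are removed from the target
set, while genuinely on-target pairs stay put.  Variants in the target
regions are called from the retained alignments and reported immediately.
Step 3 — deferrable — aligns the remaining pairs to the whole genome,
merges everything into one whole-genome alignment set and calls variants
genome-wide.

The *relocated fraction* (step-1-mapped reads whose whole-genome position
differs from the liftover of their step-1 position) quantifies how much
correction step 2 performs; it is reported in two tallies, counting reads
unmapped at step 2 as relocated (primary) or not.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .aligner import (
    AlignerContract,
    AlignerContractError,
    ReadAlignment,
    ReadPair,
)
from .caller import CallerParams, VariantCall, call_variants, write_vcf
from .reference_builder import GenomicInterval, TargetMap

logger = logging.getLogger(__name__)


@dataclass
class StepStats:
    n_pairs_input: int = 0
    n_pairs_step1_mapped: int = 0
    n_reads_relocated: int = 0              # incl. unmapped-at-step-2
    n_reads_relocated_mapped_only: int = 0  # excl. unmapped-at-step-2
    n_reads_retained: int = 0
    n_reads_removed: int = 0
    relocated_fraction: float = 0.0
    relocated_fraction_mapped_only: float = 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class Step1Result:
    selected_alignments: list[ReadAlignment]
    selected_pairs: list[ReadPair]
    unselected_names: set[str]
    unselected_pairs: list[ReadPair]
    stats: StepStats


@dataclass
class Step2Result:
    retained: list[ReadAlignment]
    removed: list[ReadAlignment]
    stats: StepStats


def _region_trees(
    regions: Sequence[GenomicInterval],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.seq_name, IntervalTree()).addi(r.start, r.end)
    return trees


def _overlaps_regions(
    trees: dict[str, IntervalTree], aln: ReadAlignment
) -> bool:
    if not aln.is_mapped:
        return False
    tree = trees.get(aln.seq_name)
    if tree is None:
        return False
    start, end = aln.reference_span()
    return bool(tree.overlap(start, end))


# ---------------------------------------------------------------------------
# step 1
# ---------------------------------------------------------------------------

def step1_select(
    pairs: Sequence[ReadPair],
    target_reference: dict[str, str],
    aligner: AlignerContract,
    read_level: bool = False,
) -> Step1Result:
    """Align all pairs to the target reference; keep pairs that map.

    Selection is pair-level by default: a pair is selected iff at least one
    mate maps anywhere on the target reference (MAPQ is ignored — a forced
    MAPQ-0 mapping is still selected; step 2, not MAPQ, does the
    correcting).  ``read_level=True`` keeps only the mapped mates.
    """
    pairs = list(pairs)
    by_name = {p.name: p for p in pairs}
    if len(by_name) != len(pairs):
        raise ValueError("duplicate read names in input")
    selected_alignments: list[ReadAlignment] = []
    selected_pairs: list[ReadPair] = []
    unselected_names: set[str] = set()
    unselected_pairs: list[ReadPair] = []
    n_seen = 0
    n_mapped_pairs = 0
    for a1, a2 in aligner.align(pairs, target_reference):
        if a1.read_name != a2.read_name or a1.read_name not in by_name:
            raise AlignerContractError(
                f"aligner emitted unexpected pair {a1.read_name!r}"
            )
        n_seen += 1
        keep1, keep2 = a1.is_mapped, a2.is_mapped
        if not read_level and (keep1 or keep2):
            keep1 = keep2 = True
        if a1.is_mapped or a2.is_mapped:
            n_mapped_pairs += 1
            if keep1:
                selected_alignments.append(a1)
            if keep2:
                selected_alignments.append(a2)
            selected_pairs.append(by_name[a1.read_name])
        else:
            unselected_names.add(a1.read_name)
            unselected_pairs.append(by_name[a1.read_name])
    if n_seen != len(pairs):
        raise AlignerContractError(
            f"aligner returned {n_seen} pairs for {len(pairs)} inputs"
        )
    stats = StepStats(
        n_pairs_input=len(pairs), n_pairs_step1_mapped=n_mapped_pairs
    )
    logger.info(
        "step1 target_selection: input_pairs=%d selected_pairs=%d",
        len(pairs), n_mapped_pairs,
    )
    return Step1Result(
        selected_alignments, selected_pairs, unselected_names,
        unselected_pairs, stats,
    )


def bam_to_fastq(alignments: Iterable[ReadAlignment]) -> list[ReadPair]:
    """Restore selected alignments to as-sequenced FASTQ pairs.

    Reverse-flagged records are reverse-complemented (qualities reversed);
    output order follows first appearance of each read name.  Raises on an
    orphan mate.
    """
    mates: dict[str, dict[int, tuple[str, str]]] = {}
    order: list[str] = []
    for a in alignments:
        if a.read_name not in mates:
            mates[a.read_name] = {}
            order.append(a.read_name)
        if a.mate in mates[a.read_name]:
            raise ValueError(f"duplicate mate {a.mate} for {a.read_name!r}")
        mates[a.read_name][a.mate] = a.as_sequenced()
    out = []
    for name in order:
        m = mates[name]
        if set(m) != {1, 2}:
            raise ValueError(f"orphan mate for read {name!r}")
        (s1, q1), (s2, q2) = m[1], m[2]
        out.append(ReadPair(name, s1, q1, s2, q2))
    return out


# ---------------------------------------------------------------------------
# step 2
# ---------------------------------------------------------------------------

def step2_realign_filter(
    selected_pairs: Sequence[ReadPair],
    genome: dict[str, str],
    target_regions: Sequence[GenomicInterval],
    target_map: TargetMap,
    aligner: AlignerContract,
    step1_alignments: Sequence[ReadAlignment],
    stats: StepStats | None = None,
) -> Step2Result:
    """Realign step-1-selected reads to the whole genome and filter.

    A pair is retained iff at least one mate's genome alignment overlaps a
    target region by >= 1 base; removed pairs keep their genome alignments
    (merged back in step 3, never aligned a third time).  The relocation
    statistic compares each step-1-mapped read's genome position against
    the liftover of its step-1 position — exact (sequence, position)
    comparison, no tolerance window.
    """
    stats = stats or StepStats(n_pairs_input=len(selected_pairs))
    step1_pos: dict[tuple[str, int], tuple[str, int] | None] = {}
    for a in step1_alignments:
        if a.is_mapped:
            step1_pos[(a.read_name, a.mate)] = target_map.lift_to_genome(
                a.seq_name, a.pos
            )
    trees = _region_trees(target_regions)
    retained: list[ReadAlignment] = []
    removed: list[ReadAlignment] = []
    names_seen = set()
    n_reloc = n_reloc_mapped = n_step1_mapped = 0
    for a1, a2 in aligner.align(selected_pairs, genome):
        names_seen.add(a1.read_name)
        for a in (a1, a2):
            key = (a.read_name, a.mate)
            if key not in step1_pos:
                continue  # mate was unmapped in step 1: no relocation basis
            n_step1_mapped += 1
            lifted = step1_pos[key]
            if not a.is_mapped:
                n_reloc += 1
            elif (a.seq_name, a.pos) != lifted:
                n_reloc += 1
                n_reloc_mapped += 1
        keep = _overlaps_regions(trees, a1) or _overlaps_regions(trees, a2)
        if keep:
            retained.extend((a1, a2))
        else:
            removed.extend((a1, a2))
    missing = {p.name for p in selected_pairs} - names_seen
    if missing:
        raise AlignerContractError(
            f"step-2 aligner lost {len(missing)} pairs (e.g. "
            f"{sorted(missing)[:3]})"
        )
    stats.n_reads_retained = len(retained)
    stats.n_reads_removed = len(removed)
    stats.n_reads_relocated = n_reloc
    stats.n_reads_relocated_mapped_only = n_reloc_mapped
    stats.relocated_fraction = (
        n_reloc / n_step1_mapped if n_step1_mapped else 0.0
    )
    stats.relocated_fraction_mapped_only = (
        n_reloc_mapped / n_step1_mapped if n_step1_mapped else 0.0
    )
    logger.info(
        "step2 genome_realignment: retained_reads=%d removed_reads=%d "
        "relocated_fraction=%.4f",
        len(retained), len(removed), stats.relocated_fraction,
    )
    return Step2Result(retained, removed, stats)


# ---------------------------------------------------------------------------
# early variant report + step 3
# ---------------------------------------------------------------------------

def report_target_variants(
    retained: Sequence[ReadAlignment],
    genome: dict[str, str],
    target_regions: Sequence[GenomicInterval],
    out_vcf: str | Path | None = None,
    params: CallerParams | None = None,
    sample_name: str = "SAMPLE",
    provenance: Sequence[str] = (),
) -> list[VariantCall]:
    """Call and (optionally) immediately write target-region variants."""
    calls = call_variants(retained, genome, target_regions, params)
    if out_vcf is not None:
        write_vcf(
            calls,
            {c: len(s) for c, s in genome.items()},
            out_vcf,
            sample_name=sample_name,
            provenance=list(provenance)
            + ["targetfirst_step=early_target_report"],
        )
    logger.info("early_report: n_calls=%d", len(calls))
    return calls


def step3_process_remainder(
    unselected_pairs: Sequence[ReadPair],
    removed: Sequence[ReadAlignment],
    retained: Sequence[ReadAlignment],
    genome: dict[str, str],
    aligner: AlignerContract,
    params: CallerParams | None = None,
) -> tuple[list[ReadAlignment], list[VariantCall]]:
    """Align the remainder, merge all alignments, call genome-wide.

    Returns the merged coordinate-sorted whole-genome alignment list (every
    input mate appears exactly once, mapped or unmapped) and the
    whole-genome calls.
    """
    remainder: list[ReadAlignment] = []
    for a1, a2 in aligner.align(unselected_pairs, genome):
        remainder.extend((a1, a2))
    merged = list(retained) + list(removed) + remainder
    merged.sort(
        key=lambda a: (
            (0, a.seq_name, a.pos) if a.is_mapped else (1, "", 0),
            a.read_name,
            a.mate,
        )
    )
    whole = [
        GenomicInterval(c, 0, len(s)) for c, s in sorted(genome.items())
    ]
    calls = call_variants(merged, genome, whole, params)
    logger.info(
        "step3 remainder: merged_reads=%d whole_genome_calls=%d",
        len(merged), len(calls),
    )
    return merged, calls


# ---------------------------------------------------------------------------
# whole workflows
# ---------------------------------------------------------------------------

@dataclass
class IterativeResult:
    early_calls: list[VariantCall]
    step1: Step1Result
    step2: Step2Result
    stats: StepStats
    merged_alignments: list[ReadAlignment] | None = None
    whole_genome_calls: list[VariantCall] | None = None


def run_iterative(
    pairs: Sequence[ReadPair],
    genome: dict[str, str],
    target_reference: dict[str, str],
    target_regions: Sequence[GenomicInterval],
    target_map: TargetMap,
    aligner: AlignerContract,
    params: CallerParams | None = None,
    read_level: bool = False,
    finish: bool = False,
) -> IterativeResult:
    """Steps 1 and 2 plus the early target report; step 3 iff ``finish``."""
    s1 = step1_select(pairs, target_reference, aligner,
                      read_level=read_level)
    fastq_pairs = bam_to_fastq(s1.selected_alignments) \
        if read_level else s1.selected_pairs
    s2 = step2_realign_filter(
        fastq_pairs, genome, target_regions, target_map, aligner,
        s1.selected_alignments, stats=s1.stats,
    )
    early = report_target_variants(
        s2.retained, genome, target_regions, params=params
    )
    result = IterativeResult(early, s1, s2, s2.stats)
    if finish:
        merged, wg_calls = step3_process_remainder(
            s1.unselected_pairs, s2.removed, s2.retained, genome,
            aligner, params,
        )
        result.merged_alignments = merged
        result.whole_genome_calls = wg_calls
    return result


def run_standard(
    pairs: Sequence[ReadPair],
    genome: dict[str, str],
    aligner: AlignerContract,
    params: CallerParams | None = None,
    regions: Sequence[GenomicInterval] | None = None,
) -> tuple[list[ReadAlignment], list[VariantCall]]:
    """The comparison baseline: direct whole-genome alignment + calling."""
    alignments: list[ReadAlignment] = []
    for a1, a2 in aligner.align(pairs, genome):
        alignments.extend((a1, a2))
    if regions is None:
        regions = [
            GenomicInterval(c, 0, len(s)) for c, s in sorted(genome.items())
        ]
    calls = call_variants(alignments, genome, regions, params)
    return alignments, calls


def call_after_step1(
    step1_alignments: Sequence[ReadAlignment],
    genome: dict[str, str],
    target_reference: dict[str, str],
    target_map: TargetMap,
    params: CallerParams | None = None,
) -> list[VariantCall]:
    """Variant calls straight from step-1 alignments, lifted to the genome.

    This is the "skip step 2" ablation: forced alignments contribute, so
    paralog divergence shows up as false target-region variants.  Calls are
    made in target-contig coordinates and lifted; the lifted positions land
    inside the target regions by construction.
    """
    contig_regions = [
        GenomicInterval(c, 0, len(s))
        for c, s in sorted(target_reference.items())
    ]
    calls = call_variants(
        step1_alignments, target_reference, contig_regions, params
    )
    lifted = []
    for c in calls:
        seq, pos = target_map.lift_to_genome(c.seq_name, c.pos)
        lifted.append(
            VariantCall(
                seq, pos, c.ref, c.alt, c.genotype, c.qual, c.depth,
                c.ref_fwd, c.ref_rev, c.alt_fwd, c.alt_rev,
            )
        )
    lifted.sort(key=lambda v: (v.seq_name, v.pos, v.ref, v.alt))
    return lifted


def restrict_calls(
    calls: Iterable[VariantCall], regions: Sequence[GenomicInterval]
) -> list[VariantCall]:
    trees = _region_trees(regions)
    out = []
    for c in calls:
        tree = trees.get(c.seq_name)
        if tree is not None and tree.overlap(c.pos, c.pos + len(c.ref)):
            out.append(c)
    return out
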