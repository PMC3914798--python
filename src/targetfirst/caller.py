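"""Built-in pileup genotyper.

A deliberately small diploid caller: reads are piled up per position, the
most frequent non-reference allele at each site becomes the candidate ALT,
and the genotype is assigned from the alt-allele fraction f (hom-ref below
0.2, het in [0.2, 0.8], hom-alt above).  QUAL is the phred-scaled
likelihood ratio of the called genotype against the next best under a
binomial read-sampling model with the column's mean base-error rate;
QD = QUAL / depth.  Strand counts for REF and ALT are carried through to
the VCF (INFO/SB) because the downstream QC cascade filters on quality-by-
depth, strand bias and depth.

Indels are left-anchored: a read's insertion or deletion immediately after
position p is recorded as that read's observation *at* p, replacing its
plain base there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .aligner import ReadAlignment, parse_cigar
from .reference_builder import GenomicInterval

PHRED = 10.0 / math.log(10.0)


@dataclass
class CallerParams:
    min_bq: int = 13          # base quality below this: base ignored
    min_mq: int = 10          # read MAPQ below this: read ignored
    min_af: float = 0.2       # alt fraction below this: hom-ref, no record
    hom_af: float = 0.8       # alt fraction above this: hom-alt
    min_depth: int = 1


@dataclass
class PileupColumn:
    """Observations overlapping one reference position.

    Each observation is (allele, error_prob, strand) where allele is a
    single base for matches/substitutions, ``+SEQ`` for an insertion after
    this position, or ``-SEQ`` for a deletion of SEQ after this position;
    strand is 0 (forward) or 1 (reverse).
    """

    seq_name: str
    pos: int
    ref_base: str
    observations: list[tuple[str, float, int]] = field(default_factory=list)


@dataclass
class VariantCall:
    """One biallelic call, VCF-style alleles, 0-based ``pos``."""

    seq_name: str
    pos: int
    ref: str
    alt: str
    genotype: str       # "0/1" or "1/1"
    qual: float
    depth: int          # ref + alt supporting reads
    ref_fwd: int
    ref_rev: int
    alt_fwd: int
    alt_rev: int

    @property
    def qd(self) -> float:
        return self.qual / self.depth if self.depth else 0.0

    @property
    def var_type(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.seq_name, self.pos, self.ref, self.alt)


def _qual_to_err(qual: str) -> np.ndarray:
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.float64) - 33.0
    return np.power(10.0, -q / 10.0)


def _walk(read: ReadAlignment) -> Iterator[tuple[str, int, int, int]]:
    """Yield (op, length, ref_offset, query_offset) per CIGAR op."""
    roff = qoff = 0
    for n, op in parse_cigar(read.cigar):
        yield op, n, roff, qoff
        if op in "MDN=X":
            roff += n
        if op in "MIS=X":
            qoff += n


# ---------------------------------------------------------------------------
# pileup (column stream — the reference implementation)
# ---------------------------------------------------------------------------

def pileup(
    alignments: Iterable[ReadAlignment],
    genome: dict[str, str],
    regions: Sequence[GenomicInterval],
    params: CallerParams | None = None,
) -> Iterator[PileupColumn]:
    """Stream pileup columns over every covered position inside ``regions``.

    Bases below ``min_bq`` and reads below ``min_mq`` are excluded.  Columns
    are yielded in (seq_name, pos) order for the sorted region list.
    """
    params = params or CallerParams()
    cols: dict[tuple[str, int], PileupColumn] = {}
    region_mask = _region_masks(genome, regions)
    for read in alignments:
        if not read.is_mapped or read.mapq < params.min_mq:
            continue
        if read.seq_name not in genome:
            raise ValueError(f"alignment on unknown sequence {read.seq_name}")
        mask = region_mask.get(read.seq_name)
        if mask is None:
            continue
        ref = genome[read.seq_name]
        err = _qual_to_err(read.qual)
        strand = 1 if read.is_reverse else 0
        maxerr = 10.0 ** (-params.min_bq / 10.0)
        ops = list(_walk(read))
        for i, (op, n, roff, qoff) in enumerate(ops):
            if op in "M=X":
                for j in range(n):
                    p = read.pos + roff + j
                    if p >= len(ref) or not mask[p]:
                        continue
                    if err[qoff + j] > maxerr:
                        continue
                    key = (read.seq_name, p)
                    col = cols.get(key)
                    if col is None:
                        col = cols[key] = PileupColumn(
                            read.seq_name, p, ref[p]
                        )
                    col.observations.append(
                        (read.seq[qoff + j], float(err[qoff + j]), strand)
                    )
            elif op in "ID":
                anchor = read.pos + roff - 1
                if anchor < 0 or anchor >= len(ref) or not mask[anchor]:
                    continue
                allele = (
                    "+" + read.seq[qoff : qoff + n] if op == "I"
                    else "-" + ref[anchor + 1 : anchor + 1 + n]
                )
                e = float(err[qoff - 1]) if qoff > 0 else maxerr
                key = (read.seq_name, anchor)
                col = cols.get(key)
                if col is None:
                    col = cols[key] = PileupColumn(
                        read.seq_name, anchor, ref[anchor]
                    )
                # replace this read's plain-base observation at the anchor
                base_obs = (read.seq[qoff - 1], float(err[qoff - 1]), strand) \
                    if qoff > 0 else None
                if base_obs is not None and base_obs in col.observations:
                    col.observations.remove(base_obs)
                col.observations.append((allele, e, strand))
    for key in sorted(cols):
        col = cols[key]
        if col.observations:
            yield col


def _region_masks(
    genome: dict[str, str], regions: Sequence[GenomicInterval]
) -> dict[str, np.ndarray]:
    masks: dict[str, np.ndarray] = {}
    for r in regions:
        if r.seq_name not in genome:
            raise ValueError(f"region on unknown sequence {r.seq_name}")
        m = masks.get(r.seq_name)
        if m is None:
            m = masks[r.seq_name] = np.zeros(
                len(genome[r.seq_name]), dtype=bool
            )
        m[r.start : min(r.end, len(m))] = True
    return masks


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------

def _genotype_likelihoods(
    n_ref: int, n_alt: int, eps: float
) -> dict[str, float]:
    """Log-likelihood of the alt-supporting read count per genotype.

    Binomial sampling of alt reads among ref+alt reads: P(alt read) is eps
    for 0/0, 1/2 for 0/1 and 1-eps for 1/1.  The binomial coefficient is
    shared and omitted (only ratios are used).
    """
    eps = min(max(eps, 1e-6), 0.25)
    out = {}
    for gt, p in (("0/0", eps), ("0/1", 0.5), ("1/1", 1.0 - eps)):
        out[gt] = n_alt * math.log(p) + n_ref * math.log1p(-p)
    return out


def genotype_from_counts(
    n_ref: int, n_alt: int, eps: float, params: CallerParams
) -> tuple[str, float] | None:
    """(genotype, qual) from supporting-read counts; None for hom-ref."""
    depth = n_ref + n_alt
    if depth < params.min_depth or n_alt == 0:
        return None
    f = n_alt / depth
    if f < params.min_af:
        return None
    gt = "1/1" if f > params.hom_af else "0/1"
    ll = _genotype_likelihoods(n_ref, n_alt, eps)
    next_best = max(v for k, v in ll.items() if k != gt)
    qual = max(0.0, PHRED * (ll[gt] - next_best))
    return gt, qual


def call_site(
    col: PileupColumn, params: CallerParams | None = None
) -> VariantCall | None:
    """Genotype one pileup column; None when no variant is called."""
    params = params or CallerParams()
    if not col.observations:
        return None
    counts: dict[str, list[int]] = {}
    err_sum = 0.0
    for allele, e, strand in col.observations:
        counts.setdefault(allele, [0, 0])[strand] += 1
        err_sum += e
    eps = err_sum / len(col.observations)
    ref_fwd, ref_rev = counts.get(col.ref_base, [0, 0])
    non_ref = {a: c for a, c in counts.items() if a != col.ref_base}
    if not non_ref:
        return None
    # most frequent non-ref allele; lexicographic tie-break
    alt_allele = max(non_ref, key=lambda a: (sum(non_ref[a]), a))
    alt_fwd, alt_rev = non_ref[alt_allele]
    res = genotype_from_counts(
        ref_fwd + ref_rev, alt_fwd + alt_rev, eps, params
    )
    if res is None:
        return None
    gt, qual = res
    ref, alt = _vcf_alleles(col.ref_base, alt_allele)
    return VariantCall(
        seq_name=col.seq_name, pos=col.pos, ref=ref, alt=alt,
        genotype=gt, qual=round(qual, 2),
        depth=ref_fwd + ref_rev + alt_fwd + alt_rev,
        ref_fwd=ref_fwd, ref_rev=ref_rev,
        alt_fwd=alt_fwd, alt_rev=alt_rev,
    )


def _vcf_alleles(ref_base: str, allele: str) -> tuple[str, str]:
    """Internal allele encoding -> VCF REF/ALT at the anchor position."""
    if allele.startswith("+"):
        return ref_base, ref_base + allele[1:]
    if allele.startswith("-"):
        return ref_base + allele[1:], ref_base
    return ref_base, allele


def call_variants(
    alignments: Iterable[ReadAlignment],
    genome: dict[str, str],
    regions: Sequence[GenomicInterval],
    params: CallerParams | None = None,
) -> list[VariantCall]:
    """Pile up and genotype every region position; sorted calls."""
    params = params or CallerParams()
    return [
        v
        for col in pileup(alignments, genome, regions, params)
        if (v := call_site(col, params)) is not None
    ]


def depth_at_sites(
    alignments: Iterable[ReadAlignment],
    sites: Sequence[tuple[str, int]],
    params: CallerParams | None = None,
) -> dict[tuple[str, int], int]:
    """Aligned read depth (MAPQ-filtered, CIGAR-aware) at specific sites."""
    params = params or CallerParams()
    wanted: dict[str, set[int]] = {}
    for seq, pos in sites:
        wanted.setdefault(seq, set()).add(pos)
    depth = {(s, p): 0 for s, p in sites}
    for read in alignments:
        if not read.is_mapped or read.mapq < params.min_mq:
            continue
        positions = wanted.get(read.seq_name)
        if not positions:
            continue
        for op, n, roff, _ in _walk(read):
            if op in "M=X":
                lo, hi = read.pos + roff, read.pos + roff + n
                for p in positions:
                    if lo <= p < hi:
                        depth[(read.seq_name, p)] += 1
    return depth


# ---------------------------------------------------------------------------
# VCF I/O (pysam)
# ---------------------------------------------------------------------------

def _vcf_header(
    contig_lengths: dict[str, int],
    sample_name: str,
    provenance: Sequence[str] = (),
):
    import pysam

    header = pysam.VariantHeader()
    for line in provenance:
        header.add_line(f"##{line}")
    header.add_line(
        '##INFO=<ID=DP,Number=1,Type=Integer,'
        'Description="Ref+alt supporting read depth">'
    )
    header.add_line(
        '##INFO=<ID=QD,Number=1,Type=Float,'
        'Description="Variant quality by depth (QUAL/DP)">'
    )
    header.add_line(
        '##INFO=<ID=SB,Number=4,Type=Integer,'
        'Description="Strand counts: ref-fwd,ref-rev,alt-fwd,alt-rev">'
    )
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    for name in sorted(contig_lengths):
        header.contigs.add(name, length=contig_lengths[name])
    header.add_sample(sample_name)
    return header


def write_vcf(
    calls: Sequence[VariantCall],
    contig_lengths: dict[str, int],
    path: str | Path,
    sample_name: str = "SAMPLE",
    provenance: Sequence[str] = (),
) -> None:
    """Write sorted calls as VCF 4.2 (INFO DP/QD/SB, FORMAT GT:DP)."""
    import pysam

    order = {n: i for i, n in enumerate(sorted(contig_lengths))}
    keys = [(order[c.seq_name], c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be coordinate-sorted for VCF output")
    header = _vcf_header(contig_lengths, sample_name, provenance)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(
                contig=c.seq_name,
                start=c.pos,
                stop=c.pos + len(c.ref),
                alleles=(c.ref, c.alt),
                qual=c.qual,
            )
            rec.info["DP"] = c.depth
            rec.info["QD"] = round(c.qd, 2)
            rec.info["SB"] = (c.ref_fwd, c.ref_rev, c.alt_fwd, c.alt_rev)
            rec.samples[sample_name]["GT"] = tuple(
                int(x) for x in c.genotype.split("/")
            )
            rec.samples[sample_name].phased = False
            rec.samples[sample_name]["DP"] = c.depth
            out.write(rec)


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Read a targetfirst VCF back into :class:`VariantCall` records."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0] if vf.header.samples else None
        for rec in vf:
            sb = rec.info.get("SB", (0, 0, 0, 0))
            if sample is not None and "GT" in rec.samples[sample]:
                gt = "/".join(
                    str(x) for x in rec.samples[sample]["GT"]
                )
            else:
                gt = "0/1"
            calls.append(
                VariantCall(
                    seq_name=rec.contig,
                    pos=rec.start,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    genotype=gt,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    depth=int(rec.info.get("DP", 0)),
                    ref_fwd=int(sb[0]), ref_rev=int(sb[1]),
                    alt_fwd=int(sb[2]), alt_rev=int(sb[3]),
                )
            )
    return calls
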