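"""Hermetic diploid genome / variant / read simulator.

Generates everything the workflow consumes, with truth carried along:

* a random genome with planted gene models (written as refFlat + gene list)
  and optional *paralogs* — near-identical copies of a target gene planted
  elsewhere, inside or outside the target gene set.  Paralogs are the
  structure that makes the second alignment step matter: reads sequenced
  from an off-target paralog are forcibly captured by the target reference
  and must be relocated by whole-genome realignment.
* injected SNVs and short indels on two haplotypes with known genotypes
  (truth VCF + array-style truth TSV);
* paired-end reads drawn from a fragment-length distribution with uniform
  per-base substitution error.  Defaults mirror a short-read WGS design:
  100 bp mates from ~397 bp fragments.  Every read name encodes its true
  source locus in *reference* coordinates, so any alignment can be audited
  against truth.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .aligner import ReadPair, revcomp
from .reference_builder import (
    FragmentLengthModel,
    GenomicInterval,
    write_fasta,
)

BASES = np.array(list("ACGT"))


@dataclass
class ParalogSpec:
    """Plant a mutated copy of ``source_gene``'s locus elsewhere.

    ``identity`` is the per-base sequence identity of the copy;
    ``inside_target`` controls whether the copy gets its own gene model in
    the *target* gene list (an on-target paralog) or remains unannotated
    off-target sequence.
    """

    source_gene: str
    identity: float = 0.95
    inside_target: bool = False
    mutation_spacing: int | None = None
    """If set, substitutions are placed deterministically every
    ``mutation_spacing`` bp instead of per-base at rate 1 - identity; this
    guarantees every read-length window of the copy carries divergence
    (useful for exact relocation accounting)."""


@dataclass
class SimConfig:
    genome_length: int = 100_000
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (120, 400)
    intron_length: tuple[int, int] = (200, 600)
    paralogs: list[ParalogSpec] = field(default_factory=list)
    snv_density: float = 0.001       # per bp
    indel_density: float = 0.0001    # per bp
    coverage: float = 30.0
    read_length: int = 100
    flm: FragmentLengthModel = field(
        default_factory=lambda: FragmentLengthModel.normal(397, 80, 250, 700)
    )
    error_rate: float = 0.001
    seed: int = 1

    def __post_init__(self) -> None:
        for rate in (self.snv_density, self.indel_density, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.flm.trunc_min < 2 * self.read_length:
            raise ValueError(
                "fragment model support must be >= 2 x read length"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "paralogs" in d:
            d["paralogs"] = [
                ParalogSpec(**p) if isinstance(p, dict) else p
                for p in d["paralogs"]
            ]
        if "flm" in d and isinstance(d["flm"], dict):
            f = d["flm"]
            kind = f.get("kind", "normal")
            if kind == "normal":
                d["flm"] = FragmentLengthModel.normal(
                    f["mean"], f["sd"], f["trunc_min"], f["trunc_max"]
                )
            elif kind == "point":
                d["flm"] = FragmentLengthModel.point(f["length"])
            else:
                d["flm"] = FragmentLengthModel.empirical(f["samples"])
        for key in ("exons_per_gene", "exon_length", "intron_length"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimGenome:
    """simulate_genome output: sequence, annotation, paralog manifest."""

    genome: dict[str, str]
    gene_models: list[tuple[str, str, int, list[tuple[int, int]]]]
    # (gene, chrom, tx_id ordinal implicit, exons) — see refflat_lines
    target_genes: list[str]
    paralog_manifest: list[dict]

    def refflat_lines(self) -> list[str]:
        lines = []
        for gene, chrom, i, exons in self.gene_models:
            starts = ",".join(str(s) for s, _ in exons) + ","
            ends = ",".join(str(e) for _, e in exons) + ","
            tx_start, tx_end = exons[0][0], exons[-1][1]
            lines.append(
                "\t".join(
                    [
                        gene, f"{gene}.t{i}", chrom, "+",
                        str(tx_start), str(tx_end),
                        str(tx_start), str(tx_end),
                        str(len(exons)), starts, ends,
                    ]
                )
            )
        return lines

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out_dir / "genome.fa",
            "refflat": out_dir / "annotation.refflat.txt",
            "genes": out_dir / "target_genes.txt",
            "paralogs": out_dir / "paralogs.json",
        }
        write_fasta(sorted(self.genome.items()), paths["genome"])
        paths["refflat"].write_text(
            "\n".join(self.refflat_lines()) + "\n"
        )
        paths["genes"].write_text("\n".join(self.target_genes) + "\n")
        paths["paralogs"].write_text(
            json.dumps(self.paralog_manifest, indent=2) + "\n"
        )
        return paths


@dataclass
class TruthVariant:
    seq_name: str
    pos: int            # 0-based, on the reference
    ref: str
    alt: str
    genotype: str       # "0/1" or "1/1"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.seq_name, self.pos, self.ref, self.alt)


@dataclass
class Haplotypes:
    """Two haplotype sequences plus per-haplotype coordinate maps.

    ``breaks[h][chrom]`` / ``offsets[h][chrom]`` translate haplotype
    coordinates back to reference coordinates across indel shifts.
    """

    seqs: list[dict[str, str]]
    variants: list[TruthVariant]
    breaks: list[dict[str, list[int]]]
    offsets: list[dict[str, list[int]]]

    def hap_to_ref(self, hap: int, chrom: str, pos: int) -> int:
        b = self.breaks[hap][chrom]
        i = bisect_right(b, pos) - 1
        return pos + self.offsets[hap][chrom][i]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate_to_identity(
    rng: np.random.Generator, seq: str, identity: float,
    spacing: int | None = None,
) -> str:
    arr = np.array(list(seq))
    if spacing is not None:
        idx = np.arange(spacing - 1, len(arr), spacing)
    else:
        idx = np.nonzero(rng.random(len(arr)) >= identity)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_genome(cfg: SimConfig, chrom: str = "chr1") -> SimGenome:
    """Random genome with planted genes and paralog copies.

    Genes (and paralog copies) are placed left to right with random
    intergenic gaps; raises if the configured footprint cannot fit.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_layouts = []  # (gene, [ (exon_len, intron_len_after) ... ])
    for g in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exons_per_gene[0],
                                cfg.exons_per_gene[1] + 1))
        exons = [
            int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            for _ in range(n_ex)
        ]
        introns = [
            int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
            for _ in range(n_ex - 1)
        ]
        gene_layouts.append((f"GENE{g + 1}", exons, introns))

    seq = _random_seq(rng, cfg.genome_length)
    models: list[tuple[str, str, int, list[tuple[int, int]]]] = []
    spans: dict[str, tuple[int, int]] = {}
    cursor = 0
    footprint = sum(
        sum(ex) + sum(intr) for _, ex, intr in gene_layouts
    )
    n_slots = cfg.n_genes + len(cfg.paralogs)
    # paralog copies reuse their source's span length; reserve generously
    max_span = max(
        (sum(ex) + sum(intr) for _, ex, intr in gene_layouts), default=0
    )
    needed = footprint + len(cfg.paralogs) * max_span
    if needed >= cfg.genome_length:
        raise ValueError(
            f"cannot pack {n_slots} gene/paralog loci "
            f"({needed} bp) into {cfg.genome_length} bp"
        )
    slack = cfg.genome_length - needed
    gap_budget = slack // (n_slots + 1)
    for gene, exons, introns in gene_layouts:
        cursor += int(rng.integers(gap_budget // 2, gap_budget + 1))
        start = cursor
        coords = []
        for i, ex_len in enumerate(exons):
            coords.append((cursor, cursor + ex_len))
            cursor += ex_len
            if i < len(introns):
                cursor += introns[i]
        models.append((gene, chrom, 1, coords))
        spans[gene] = (start, cursor)

    target_genes = [g for g, *_ in gene_layouts]
    manifest: list[dict] = []
    genome_arr = list(seq)
    for j, ps in enumerate(cfg.paralogs):
        if ps.source_gene not in spans:
            raise ValueError(f"unknown paralog source {ps.source_gene!r}")
        s, e = spans[ps.source_gene]
        src = "".join(genome_arr[s:e])
        copy = _mutate_to_identity(rng, src, ps.identity,
                                   spacing=ps.mutation_spacing)
        cursor += int(rng.integers(gap_budget // 2, gap_budget + 1))
        cstart = cursor
        genome_arr[cstart : cstart + len(copy)] = list(copy)
        cursor += len(copy)
        name = f"{ps.source_gene}P{j + 1}"
        src_model = next(m for m in models if m[0] == ps.source_gene)
        shift = cstart - s
        copy_exons = [(a + shift, b + shift) for a, b in src_model[3]]
        models.append((name, chrom, 1, copy_exons))
        if ps.inside_target:
            target_genes.append(name)
        manifest.append(
            {
                "name": name,
                "source_gene": ps.source_gene,
                "identity": ps.identity,
                "inside_target": ps.inside_target,
                "seq_name": chrom,
                "start": cstart,
                "end": cstart + len(copy),
                "source_start": s,
                "source_end": e,
            }
        )
    if cursor > cfg.genome_length:
        raise ValueError("gene packing overflowed the genome")
    return SimGenome(
        genome={chrom: "".join(genome_arr)},
        gene_models=models,
        target_genes=target_genes,
        paralog_manifest=manifest,
    )


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def inject_variants(
    genome: dict[str, str], cfg: SimConfig,
    exclude: Sequence[GenomicInterval] = (),
) -> Haplotypes:
    """Place SNVs and 1–10 bp indels on two haplotypes.

    Genotypes are het or hom with equal probability (het variants land on
    haplotype 0).  Variant sites are kept >= 12 bp apart so truth records
    stay left-normalized and non-interacting.  ``exclude`` masks regions
    (e.g. paralog copies carrying their own divergence already).
    """
    rng = np.random.default_rng(cfg.seed + 104729)
    variants: list[TruthVariant] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        n = len(seq)
        n_snv = rng.poisson(cfg.snv_density * n)
        n_indel = rng.poisson(cfg.indel_density * n)
        excluded = np.zeros(n, dtype=bool)
        for r in exclude:
            if r.seq_name == chrom:
                excluded[r.start : r.end] = True
        taken = np.zeros(n, dtype=bool)
        placed = 0
        attempts = 0
        want = [("SNV", n_snv), ("INDEL", n_indel)]
        for var_type, count in want:
            placed = 0
            while placed < count and attempts < 50 * (count + 1):
                attempts += 1
                pos = int(rng.integers(12, n - 24))
                lo, hi = pos - 12, pos + 24
                if excluded[pos] or taken[lo:hi].any():
                    continue
                ref_base = seq[pos]
                if ref_base == "N":
                    continue
                gt = "0/1" if rng.random() < 0.5 else "1/1"
                if var_type == "SNV":
                    alt = "ACGT"[
                        ("ACGT".index(ref_base) + 1 + int(rng.integers(0, 3)))
                        % 4
                    ]
                    variants.append(
                        TruthVariant(chrom, pos, ref_base, alt, gt)
                    )
                else:
                    ilen = int(rng.integers(1, 11))
                    if rng.random() < 0.5:  # insertion after pos
                        ins = _random_seq(rng, ilen)
                        variants.append(
                            TruthVariant(
                                chrom, pos, ref_base, ref_base + ins, gt
                            )
                        )
                    else:  # deletion of bases after pos
                        if pos + 1 + ilen >= n:
                            continue
                        variants.append(
                            TruthVariant(
                                chrom, pos,
                                seq[pos : pos + 1 + ilen], ref_base, gt,
                            )
                        )
                taken[lo:hi] = True
                placed += 1
    variants.sort(key=lambda v: (v.seq_name, v.pos))
    return _apply_variants(genome, variants)


def _apply_variants(
    genome: dict[str, str], variants: list[TruthVariant]
) -> Haplotypes:
    seqs: list[dict[str, str]] = []
    breaks: list[dict[str, list[int]]] = []
    offsets: list[dict[str, list[int]]] = []
    for hap in (0, 1):
        hseqs: dict[str, str] = {}
        hbreaks: dict[str, list[int]] = {}
        hoffsets: dict[str, list[int]] = {}
        for chrom in sorted(genome):
            ref = genome[chrom]
            parts: list[str] = []
            b: list[int] = [0]
            off: list[int] = [0]
            ref_cursor = 0
            hap_len = 0
            for v in variants:
                if v.seq_name != chrom:
                    continue
                if v.genotype == "0/1" and hap != 0:
                    continue
                parts.append(ref[ref_cursor : v.pos])
                hap_len += v.pos - ref_cursor
                parts.append(v.alt)
                ref_cursor = v.pos + len(v.ref)
                hap_len += len(v.alt)
                shift = len(v.ref) - len(v.alt)
                if shift != 0:
                    b.append(hap_len)
                    off.append(ref_cursor - hap_len)
            parts.append(ref[ref_cursor:])
            hseqs[chrom] = "".join(parts)
            hbreaks[chrom] = b
            hoffsets[chrom] = off
        seqs.append(hseqs)
        breaks.append(hbreaks)
        offsets.append(hoffsets)
    return Haplotypes(seqs, variants, breaks, offsets)


def write_truth(
    haps: Haplotypes,
    genome: dict[str, str],
    out_dir: str | Path,
    sample_name: str = "SIM",
) -> dict[str, Path]:
    """Write truth VCF and 4-column truth TSV (chrom, 1-based pos, ref, GT)."""
    from .caller import VariantCall, write_vcf

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "truth.vcf",
        "tsv": out_dir / "truth.tsv",
    }
    calls = [
        VariantCall(
            v.seq_name, v.pos, v.ref, v.alt, v.genotype,
            qual=100.0, depth=0,
            ref_fwd=0, ref_rev=0, alt_fwd=0, alt_rev=0,
        )
        for v in haps.variants
    ]
    write_vcf(
        calls,
        {c: len(s) for c, s in genome.items()},
        paths["vcf"],
        sample_name=sample_name,
        provenance=["source=targetfirst-simulator"],
    )
    with open(paths["tsv"], "w") as fh:
        for v in haps.variants:
            if len(v.ref) != 1 or len(v.alt) != 1:
                continue  # TSV dialect is SNV/array-style
            alleles = (
                v.alt + v.alt if v.genotype == "1/1" else v.ref + v.alt
            )
            fh.write(f"{v.seq_name}\t{v.pos + 1}\t{v.ref}\t{alleles}\n")
    return paths


def make_array_sites(
    haps: Haplotypes,
    genome: dict[str, str],
    regions: Sequence[GenomicInterval],
    n_sites: int,
    seed: int,
) -> list[tuple[str, int, str, str]]:
    """SNP-array-style truth panel inside ``regions``.

    Mixes every injected SNV lying in the regions with random hom-ref
    positions up to ``n_sites`` total.  Returns (chrom, 0-based pos, ref,
    unordered genotype string) tuples, sorted.
    """
    rng = np.random.default_rng(seed)
    sites: dict[tuple[str, int], tuple[str, str]] = {}
    variant_pos = {
        (v.seq_name, v.pos) for v in haps.variants
    }
    indel_shadow = {
        (v.seq_name, p)
        for v in haps.variants
        for p in range(v.pos, v.pos + max(len(v.ref), len(v.alt)) + 1)
    }
    for v in haps.variants:
        if len(v.ref) != 1 or len(v.alt) != 1:
            continue
        for r in regions:
            if r.seq_name == v.seq_name and r.start <= v.pos < r.end:
                gt = v.alt + v.alt if v.genotype == "1/1" else v.ref + v.alt
                sites[(v.seq_name, v.pos)] = (v.ref, gt)
                break
    flat = [
        (r.seq_name, p) for r in regions for p in range(r.start, r.end)
    ]
    order = rng.permutation(len(flat))
    for i in order:
        if len(sites) >= n_sites:
            break
        chrom, pos = flat[i]
        if (chrom, pos) in sites or (chrom, pos) in indel_shadow:
            continue
        if (chrom, pos) in variant_pos:
            continue
        ref_base = genome[chrom][pos]
        if ref_base == "N":
            continue
        sites[(chrom, pos)] = (ref_base, ref_base + ref_base)
    return sorted(
        (chrom, pos, ref, gt)
        for (chrom, pos), (ref, gt) in sites.items()
    )


def write_array_sites(
    sites: Sequence[tuple[str, int, str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom, pos, ref, gt in sites:
            fh.write(f"{chrom}\t{pos + 1}\t{ref}\t{gt}\n")


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def read_name_for(
    chrom: str, ref_start: int, ref_end: int, hap: int, serial: int
) -> str:
    """Truth-encoding read name: locus in reference coordinates."""
    return f"sim|{chrom}|{ref_start}|{ref_end}|h{hap}|{serial}"


def decode_read_name(name: str) -> tuple[str, int, int, int]:
    """(chrom, ref_start, ref_end, hap) from a simulator read name."""
    parts = name.split("|")
    if len(parts) != 6 or parts[0] != "sim":
        raise ValueError(f"not a simulator read name: {name!r}")
    return parts[1], int(parts[2]), int(parts[3]), int(parts[4][1:])


def simulate_reads(
    haps: Haplotypes,
    cfg: SimConfig,
    n_pairs: int | None = None,
    regions: Sequence[GenomicInterval] | None = None,
    name_prefix: str = "",
) -> list[ReadPair]:
    """Draw paired-end reads from the haplotypes.

    Fragments start uniformly on a uniformly chosen haplotype (optionally
    restricted to fragments whose reference span overlaps ``regions``);
    mate 1 is the fragment's 5' read, mate 2 the reverse complement of its
    3' end.  Substitution errors are applied at ``cfg.error_rate``; quality
    strings are flat at the corresponding phred score.
    """
    rng = np.random.default_rng(cfg.seed + 15485863)
    R = cfg.read_length
    chroms = sorted(haps.seqs[0])
    total_len = sum(len(haps.seqs[0][c]) for c in chroms)
    if n_pairs is None:
        n_pairs = int(round(cfg.coverage * total_len / (2 * R)))
    phred = (
        min(40, int(round(-10 * np.log10(max(cfg.error_rate, 1e-4)))))
    )
    qual = chr(33 + phred) * R
    pairs: list[ReadPair] = []
    serial = 0
    guard = 0
    max_draws = 100 * n_pairs + 1000
    if regions is not None:
        # rejection sampling: scale the draw budget by the hit probability
        span = sum(len(r) for r in regions) + len(regions) * int(
            cfg.flm.mean_length()
        )
        max_draws = int(20 * n_pairs * max(1.0, total_len / max(span, 1)))
    while len(pairs) < n_pairs and guard < max_draws:
        guard += 1
        hap = int(rng.integers(0, 2))
        # chromosome weighted by length
        u = int(rng.integers(0, total_len))
        acc = 0
        chrom = chroms[0]
        for c in chroms:
            acc += len(haps.seqs[hap][c])
            if u < acc:
                chrom = c
                break
        hseq = haps.seqs[hap][chrom]
        frag_len = int(haps_frag(rng, cfg))
        if frag_len > len(hseq):
            continue
        start = int(rng.integers(0, len(hseq) - frag_len + 1))
        ref_start = haps.hap_to_ref(hap, chrom, start)
        ref_end = haps.hap_to_ref(hap, chrom, start + frag_len - 1) + 1
        if regions is not None:
            hit = any(
                r.seq_name == chrom and ref_start < r.end and r.start < ref_end
                for r in regions
            )
            if not hit:
                continue
        frag = hseq[start : start + frag_len]
        r1 = _add_errors(rng, frag[:R], cfg.error_rate)
        r2 = _add_errors(rng, revcomp(frag[-R:]), cfg.error_rate)
        name = name_prefix + read_name_for(
            chrom, ref_start, ref_end, hap, serial
        )
        serial += 1
        pairs.append(ReadPair(name, r1, qual, r2, qual))
    if len(pairs) < n_pairs:
        raise RuntimeError("read simulation failed to place enough fragments")
    return pairs


def haps_frag(rng: np.random.Generator, cfg: SimConfig) -> int:
    return int(cfg.flm.sample(rng, 1)[0])


def _add_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)
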