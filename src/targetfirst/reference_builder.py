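"""Target Reference Genome construction.

A *target reference* is a compact FASTA built from the exons of a chosen gene
set: each exon boundary is extended ("padded") symmetrically — by default
550 bp, sized so that a whole ~400 bp sequencing fragment overlapping an exon
still fits inside the extended region — overlapping padded exons are merged,
and each merged region is extracted from the genome as its own contig.  A
:class:`TargetMap` records where every target-contig base came from, giving
exact bidirectional liftover between target and genome coordinates.

Also provides :func:`estimate_uncaptured_pair_fraction`, a closed-form
estimate (under a uniform fragment-placement model) of the fraction of read
pairs overlapping an exon that would not be fully contained in the padded
region for a given pad and fragment-length distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

TARGETMAP_FORMAT = "targetfirst-map\tv1"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open, 0-based interval on a named sequence.

    ``strand`` is informational only: target extraction is always
    forward-strand (aligners handle reverse complements).
    """

    seq_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_name}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def name(self) -> str:
        """Canonical contig name used in the target reference."""
        return f"{self.seq_name}:{self.start}-{self.end}"


@dataclass
class GeneModel:
    """One transcript of a gene: a name and its exon intervals."""

    gene_symbol: str
    transcript_id: str
    seq_name: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene model {self.transcript_id} has no exons")
        for ex in self.exons:
            if ex.seq_name != self.seq_name:
                raise ValueError(
                    f"exon {ex} of {self.transcript_id} not on {self.seq_name}"
                )


@dataclass(frozen=True)
class MapEntry:
    """One contiguous block of the target↔genome coordinate map."""

    contig: str
    contig_start: int
    genome_seq: str
    genome_start: int
    length: int


class TargetMap:
    """Ordered bidirectional liftover map between target contigs and genome.

    Entries within one contig tile it exactly from 0; genome intervals across
    all entries are pairwise disjoint (guaranteed by construction from merged
    regions, validated on load).
    """

    def __init__(self, entries: Sequence[MapEntry]):
        self.entries: list[MapEntry] = list(entries)
        self._by_contig: dict[str, list[MapEntry]] = {}
        for e in self.entries:
            self._by_contig.setdefault(e.contig, []).append(e)
        for contig, es in self._by_contig.items():
            es.sort(key=lambda e: e.contig_start)
            expect = 0
            for e in es:
                if e.contig_start != expect:
                    raise ValueError(
                        f"map entries for {contig} do not tile from 0"
                    )
                expect += e.length
        # genome-side disjointness + inverse index
        self._by_genome: dict[str, list[MapEntry]] = {}
        for e in self.entries:
            self._by_genome.setdefault(e.genome_seq, []).append(e)
        for seq, es in self._by_genome.items():
            es.sort(key=lambda e: e.genome_start)
            for a, b in zip(es, es[1:]):
                if b.genome_start < a.genome_start + a.length:
                    raise ValueError(
                        f"overlapping genome intervals in map on {seq}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TargetMap) and self.entries == other.entries

    def contigs(self) -> list[str]:
        return list(self._by_contig)

    def contig_length(self, contig: str) -> int:
        es = self._by_contig[contig]
        return es[-1].contig_start + es[-1].length

    def lift_to_genome(self, contig: str, pos: int) -> tuple[str, int]:
        """Translate a 0-based target-contig position to genome coordinates."""
        try:
            es = self._by_contig[contig]
        except KeyError:
            raise KeyError(f"unknown target contig {contig!r}") from None
        if not 0 <= pos < self.contig_length(contig):
            raise ValueError(f"position {pos} out of range for {contig}")
        # few entries per contig: linear scan is fine
        for e in es:
            if e.contig_start <= pos < e.contig_start + e.length:
                return e.genome_seq, e.genome_start + (pos - e.contig_start)
        raise AssertionError("unreachable: entries tile the contig")

    def lift_to_target(self, genome_seq: str, pos: int) -> tuple[str, int]:
        """Inverse liftover; raises KeyError if the position is not targeted."""
        for e in self._by_genome.get(genome_seq, ()):
            if e.genome_start <= pos < e.genome_start + e.length:
                return e.contig, e.contig_start + (pos - e.genome_start)
        raise KeyError(f"{genome_seq}:{pos} has no target preimage")

    def covers_genome(self, genome_seq: str, pos: int) -> bool:
        try:
            self.lift_to_target(genome_seq, pos)
            return True
        except KeyError:
            return False

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#{TARGETMAP_FORMAT}\n")
            for e in self.entries:
                fh.write(
                    f"{e.contig}\t{e.contig_start}\t{e.genome_seq}"
                    f"\t{e.genome_start}\t{e.length}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TargetMap":
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if header != f"#{TARGETMAP_FORMAT}":
                raise ValueError(f"{path}: not a target map file ({header!r})")
            for i, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 5:
                    raise ValueError(f"{path}:{i}: expected 5 columns")
                entries.append(
                    MapEntry(
                        fields[0],
                        int(fields[1]),
                        fields[2],
                        int(fields[3]),
                        int(fields[4]),
                    )
                )
        return cls(entries)


@dataclass
class FragmentLengthModel:
    """Distribution of sequencing-fragment lengths in bp.

    ``kind`` is one of ``point`` (all mass at ``mean``), ``normal``
    (discretized truncated normal) or ``empirical`` (observed lengths).
    ``trunc_min``/``trunc_max`` bound the support; for paired-end simulation
    the support must be at least twice the read length so the two mates do
    not overlap-run off the fragment.
    """

    kind: str
    mean: float | None = None
    sd: float | None = None
    samples: list[int] = field(default_factory=list)
    trunc_min: int = 1
    trunc_max: int = 10_000

    @classmethod
    def point(cls, length: int) -> "FragmentLengthModel":
        return cls("point", mean=float(length),
                   trunc_min=length, trunc_max=length)

    @classmethod
    def normal(cls, mean: float, sd: float, trunc_min: int,
               trunc_max: int) -> "FragmentLengthModel":
        return cls("normal", mean=mean, sd=sd,
                   trunc_min=trunc_min, trunc_max=trunc_max)

    @classmethod
    def empirical(cls, samples: Iterable[int]) -> "FragmentLengthModel":
        samples = [int(s) for s in samples]
        if not samples:
            raise ValueError("empirical fragment model needs >= 1 sample")
        return cls("empirical", samples=samples,
                   trunc_min=min(samples), trunc_max=max(samples))

    def support(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete support: (lengths, probabilities), probabilities sum to 1."""
        if self.kind == "point":
            return np.array([int(self.mean)]), np.array([1.0])
        if self.kind == "normal":
            lengths = np.arange(self.trunc_min, self.trunc_max + 1)
            w = stats.norm.pdf(lengths, loc=self.mean, scale=self.sd)
            total = w.sum()
            if total <= 0:
                raise ValueError("truncation leaves no mass in fragment model")
            return lengths, w / total
        if self.kind == "empirical":
            if not self.samples:
                raise ValueError("empirical fragment model has no samples")
            lengths, counts = np.unique(self.samples, return_counts=True)
            return lengths, counts / counts.sum()
        raise ValueError(f"unknown fragment model kind {self.kind!r}")

    def mean_length(self) -> float:
        lengths, p = self.support()
        return float((lengths * p).sum())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lengths, p = self.support()
        return rng.choice(lengths, size=n, p=p)


# ---------------------------------------------------------------------------
# refFlat parsing
# ---------------------------------------------------------------------------

def parse_refflat(
    path: str | Path,
    gene_list: set[str] | None = None,
    missing_out: set[str] | None = None,
) -> list[GeneModel]:
    """Parse UCSC refFlat annotation, keeping only genes in ``gene_list``.

    refFlat is 11 tab-separated columns: geneName, name, chrom, strand,
    txStart, txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds, with
    0-based starts, exclusive ends and comma-terminated coordinate lists.
    Duplicate identical exons across transcripts are retained here; they are
    deduplicated downstream by :func:`pad_and_merge`.

    Gene symbols requested but absent from the file are reported via a
    ``logging`` warning and, if ``missing_out`` is given, added to it.
    """
    models: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise ValueError(
                    f"{path}:{lineno}: expected 11 refFlat columns, "
                    f"got {len(fields)}"
                )
            gene, tx, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            seen.add(gene)
            if gene_list is not None and gene not in gene_list:
                continue
            try:
                n_exons = int(fields[8])
                starts = [int(x) for x in fields[9].split(",") if x != ""]
                ends = [int(x) for x in fields[10].split(",") if x != ""]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}")
            if len(starts) != n_exons or len(ends) != n_exons:
                raise ValueError(
                    f"{path}:{lineno}: exonCount={n_exons} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            exons = [
                GenomicInterval(chrom, s, e, strand)
                for s, e in zip(starts, ends)
            ]
            models.append(GeneModel(gene, tx, chrom, strand, exons))
    if gene_list is not None:
        missing = set(gene_list) - seen
        if missing:
            logger.warning(
                "gene symbols absent from %s: %s",
                path, ", ".join(sorted(missing)),
            )
            if missing_out is not None:
                missing_out.update(missing)
    return models


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym)
    return out


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6 reader (0-based half-open, as BED is)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "+"
            regions.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return regions


def write_bed(regions: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.seq_name}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# pad / merge / extract
# ---------------------------------------------------------------------------

def pad_and_merge(
    exons: Iterable[GenomicInterval],
    pad: int,
    seq_lengths: dict[str, int],
    merge: bool = True,
) -> list[GenomicInterval]:
    """Extend every exon by ``pad`` bp on each side, clamp to the sequence,
    and merge overlapping or book-ended intervals into maximal disjoint
    regions, sorted by (seq_name, start).

    ``merge=False`` keeps padded intervals separate (sorted, possibly
    overlapping) — the literal "extend and concatenate" reading.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    padded: list[GenomicInterval] = []
    for ex in exons:
        if ex.seq_name not in seq_lengths:
            raise KeyError(f"exon on unknown sequence {ex.seq_name!r}")
        start = max(0, ex.start - pad)
        end = min(seq_lengths[ex.seq_name], ex.end + pad)
        padded.append(GenomicInterval(ex.seq_name, start, end))
    padded.sort(key=lambda r: (r.seq_name, r.start, r.end))
    if not merge:
        return padded
    merged: list[GenomicInterval] = []
    for r in padded:
        if (
            merged
            and merged[-1].seq_name == r.seq_name
            and r.start <= merged[-1].end  # overlap or book-ended
        ):
            if r.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    r.seq_name, merged[-1].start, r.end
                )
        else:
            merged.append(GenomicInterval(r.seq_name, r.start, r.end))
    return merged


def exons_of(models: Iterable[GeneModel]) -> list[GenomicInterval]:
    """All exon intervals of a set of gene models (duplicates retained)."""
    return [ex for m in models for ex in m.exons]


def extract_target(
    genome: dict[str, str],
    regions: Sequence[GenomicInterval],
) -> tuple[list[tuple[str, str]], TargetMap]:
    """Extract each region as one forward-strand contig.

    ``genome`` maps sequence name to sequence string.  Returns the list of
    (contig_name, sequence) in region order plus the liftover map.  Regions
    must be disjoint and sorted (the output of :func:`pad_and_merge`).
    """
    contigs: list[tuple[str, str]] = []
    entries: list[MapEntry] = []
    for r in regions:
        if r.seq_name not in genome:
            raise KeyError(f"region on unknown sequence {r.seq_name!r}")
        seq = genome[r.seq_name]
        if r.end > len(seq):
            raise ValueError(
                f"region {r.name} exceeds length of {r.seq_name} "
                f"({len(seq)}); clamp upstream with pad_and_merge"
            )
        contigs.append((r.name, seq[r.start:r.end]))
        entries.append(MapEntry(r.name, 0, r.seq_name, r.start, len(r)))
    if not regions:
        logger.warning("empty region list: emitting empty target reference")
    return contigs, TargetMap(entries)


def write_fasta(
    contigs: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into memory via pyfaidx (index built on demand)."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def build_target_reference(
    genome: dict[str, str] | str | Path,
    regions: Sequence[GenomicInterval],
    out_fasta: str | Path,
    out_map: str | Path | None = None,
) -> TargetMap:
    """Build and serialize the target reference FASTA plus its liftover map.

    ``genome`` is either an in-memory dict or a FASTA path.  The map is
    written as 5-column TSV next to the FASTA (``<out_fasta>.map.tsv`` unless
    ``out_map`` is given).
    """
    if not isinstance(genome, dict):
        genome = read_fasta(genome)
    contigs, tmap = extract_target(genome, regions)
    write_fasta(contigs, out_fasta)
    if out_map is None:
        out_map = str(out_fasta) + ".map.tsv"
    tmap.to_tsv(out_map)
    return tmap


# ---------------------------------------------------------------------------
# capture model
# ---------------------------------------------------------------------------

def estimate_uncaptured_pair_fraction(
    flm: FragmentLengthModel, pad: int, exon_length: int
) -> float:
    """Expected fraction of exon-overlapping fragments not fully captured.

    Model: a fragment of length F overlaps an exon of length L with its
    start uniform over the L+F placements that overlap; it is *fully
    captured* iff it lies entirely within the exon extended by ``pad`` (P)
    on each side.  The uncaptured placements span max(0, 2(F-P)) of that
    range (clamped at L+F when F exceeds the whole padded exon), so the
    per-length fraction is min(1, max(0, 2(F-P)) / (L+F)) and the estimate
    is its expectation over the fragment-length distribution.

    A pair sequenced from the two ends of a fully captured fragment aligns
    entirely inside the padded target region; an uncaptured fragment loses
    at least part of one mate.
    """
    if exon_length <= 0:
        raise ValueError("exon_length must be > 0")
    if pad < 0:
        raise ValueError("pad must be >= 0")
    lengths, p = flm.support()
    frac = np.minimum(
        1.0,
        np.maximum(0.0, 2.0 * (lengths - pad)) / (exon_length + lengths),
    )
    return float((frac * p).sum())
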