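"""Built-in read aligner and the aligner contract.

Both workflow steps consume an *aligner contract*: a callable taking paired
reads and a reference and yielding one :class:`ReadAlignment` per mate,
mapped or unmapped.  The built-in implementation (:class:`BuiltinAligner`)
is an exact k-mer seed-and-extend aligner: non-overlapping k-mers of the
read (both orientations) are looked up in an exact-match index of the
reference, and each candidate locus is refined by banded edit-distance
alignment (via edlib) within a window around the seed diagonal.  It exists
so the whole workflow runs hermetically — it makes no attempt at parity
with production aligners, whose role it stands in for.

:class:`ExternalAligner` wraps any command-line aligner emitting SAM behind
the same contract.
"""

from __future__ import annotations

import logging
import re
import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Protocol, Sequence

import edlib

from .reference_builder import FragmentLengthModel

logger = logging.getLogger(__name__)

_COMPL = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_MATE1 = 0x40
FLAG_MATE2 = 0x80


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


@dataclass
class ReadAlignment:
    """One aligned (or unmapped) read, SAM-convention fields.

    ``seq``/``qual`` are stored in reference orientation when mapped on the
    reverse strand, per SAM; ``pos`` is the 0-based leftmost reference
    position.  ``cigar`` uses M/I/D only (no clipping: the built-in aligner
    is end-to-end within its band).
    """

    read_name: str
    mate: int  # 1 or 2
    seq: str
    qual: str
    seq_name: str | None = None
    pos: int | None = None
    is_reverse: bool = False
    cigar: str | None = None
    mapq: int = 0
    nm: int = 0
    proper_pair: bool = False
    mate_seq_name: str | None = None
    mate_pos: int | None = None
    mate_is_reverse: bool = False
    tlen: int = 0

    @property
    def is_mapped(self) -> bool:
        return self.seq_name is not None

    @property
    def flag(self) -> int:
        f = FLAG_PAIRED | (FLAG_MATE1 if self.mate == 1 else FLAG_MATE2)
        if not self.is_mapped:
            f |= FLAG_UNMAPPED
        elif self.is_reverse:
            f |= FLAG_REVERSE
        if self.mate_seq_name is None:
            f |= FLAG_MATE_UNMAPPED
        elif self.mate_is_reverse:
            f |= FLAG_MATE_REVERSE
        if self.proper_pair:
            f |= FLAG_PROPER
        return f

    def reference_span(self) -> tuple[int, int]:
        """(start, end) on the reference, from pos and CIGAR."""
        if not self.is_mapped:
            raise ValueError(f"{self.read_name}/{self.mate} is unmapped")
        return self.pos, self.pos + cigar_reference_length(self.cigar)

    def as_sequenced(self) -> tuple[str, str]:
        """(seq, qual) in original sequencing orientation."""
        if self.is_mapped and self.is_reverse:
            return revcomp(self.seq), self.qual[::-1]
        return self.seq, self.qual


_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIG_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_query_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in "MIS=X")


def cigar_reference_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in "MDN=X")


def _edlib_cigar_to_sam(cigar: str) -> str:
    """Collapse edlib's extended =/X ops into SAM M, merging runs."""
    out: list[tuple[int, str]] = []
    for n, op in parse_cigar(cigar):
        op = "M" if op in "=X" else op
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return "".join(f"{n}{op}" for n, op in out)


# ---------------------------------------------------------------------------
# seed index
# ---------------------------------------------------------------------------

class SeedIndex:
    """Exact-match k-mer index over the forward strand of a reference.

    Both strands are resolved at query time: the query's forward and
    reverse-complement k-mers are looked up against this one index.
    k-mers containing N are excluded.
    """

    def __init__(self, reference: dict[str, str], k: int = 21):
        if k % 2 == 0 or not 11 <= k <= 31:
            raise ValueError("k must be odd and in [11, 31]")
        self.k = k
        # stable, name-sorted ordering makes tie-breaks deterministic
        self.names: list[str] = sorted(reference)
        self.seqs: dict[str, str] = {
            name: reference[name].upper() for name in self.names
        }
        self.index: dict[str, list[tuple[str, int]]] = {}
        any_indexed = False
        for name in self.names:
            seq = self.seqs[name]
            if len(seq) < k:
                continue
            any_indexed = True
            idx = self.index
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                idx.setdefault(kmer, []).append((name, i))
        if not any_indexed:
            logger.warning("no reference sequence of length >= k=%d", k)

    def lengths(self) -> dict[str, int]:
        return {name: len(self.seqs[name]) for name in self.names}


@dataclass(frozen=True)
class _Candidate:
    dist: int
    seq_name: str
    pos: int
    is_reverse: bool
    cigar: str


def _find_candidates(
    index: SeedIndex,
    seq: str,
    max_edits: int,
    max_seed_hits: int = 64,
    max_candidates: int = 32,
) -> list[_Candidate]:
    """Seed both orientations and refine each locus by banded alignment.

    Returns candidates sorted by (dist, seq_name, pos, is_reverse); at most
    ``max_candidates`` survive (ties beyond that are irrelevant: MAPQ is
    already 0 with two).
    """
    k = index.k
    qlen = len(seq)
    band = 2 * max_edits
    raw: set[tuple[str, int, bool]] = set()
    for is_reverse in (False, True):
        q = revcomp(seq).upper() if is_reverse else seq.upper()
        offsets = list(range(0, qlen - k + 1, k))
        if offsets and offsets[-1] != qlen - k:
            offsets.append(qlen - k)  # cover the read tail
        for off in offsets:
            hits = index.index.get(q[off : off + k])
            if hits is None or len(hits) > max_seed_hits:
                continue
            for name, rpos in hits:
                raw.add((name, rpos - off, is_reverse))
    cands: dict[tuple[str, int, bool], _Candidate] = {}
    for name, start, is_reverse in sorted(raw):
        q = revcomp(seq).upper() if is_reverse else seq.upper()
        ref = index.seqs[name]
        wstart = max(0, start - band)
        window = ref[wstart : start + qlen + band]
        res = edlib.align(q, window, mode="HW", task="path", k=max_edits)
        if res["editDistance"] < 0:
            continue
        pos = wstart + res["locations"][0][0]
        cand = _Candidate(
            dist=res["editDistance"],
            seq_name=name,
            pos=pos,
            is_reverse=is_reverse,
            cigar=_edlib_cigar_to_sam(res["cigar"]),
        )
        key = (name, pos, is_reverse)
        if key not in cands or cand.dist < cands[key].dist:
            cands[key] = cand
    out = sorted(
        cands.values(),
        key=lambda c: (c.dist, c.seq_name, c.pos, c.is_reverse),
    )
    return out[:max_candidates]


def _mapq(best: _Candidate, cands: Sequence[_Candidate]) -> int:
    """0 on tie; min(60, 6 * (second_best - best)) otherwise; 60 if unique."""
    second = None
    for c in cands:
        if (c.seq_name, c.pos, c.is_reverse) != (
            best.seq_name, best.pos, best.is_reverse,
        ):
            second = c
            break
    if second is None:
        return 60
    gap = second.dist - best.dist
    return 0 if gap == 0 else min(60, 6 * gap)


def _to_alignment(
    name: str, mate: int, seq: str, qual: str,
    cand: _Candidate | None, mapq: int,
) -> ReadAlignment:
    if cand is None:
        return ReadAlignment(name, mate, seq, qual)
    if cand.is_reverse:
        aseq, aqual = revcomp(seq), qual[::-1]
    else:
        aseq, aqual = seq, qual
    return ReadAlignment(
        name, mate, aseq, aqual,
        seq_name=cand.seq_name, pos=cand.pos, is_reverse=cand.is_reverse,
        cigar=cand.cigar, mapq=mapq, nm=cand.dist,
    )


def align_read(
    index: SeedIndex, name: str, seq: str, qual: str,
    mate: int = 1, max_edit_frac: float = 0.05,
) -> ReadAlignment:
    """Align a single read; unmapped record when no candidate survives."""
    if len(seq) < index.k:
        return ReadAlignment(name, mate, seq, qual)
    max_edits = max(1, int(max_edit_frac * len(seq)))
    cands = _find_candidates(index, seq, max_edits)
    if not cands:
        return ReadAlignment(name, mate, seq, qual)
    best = cands[0]
    return _to_alignment(name, mate, seq, qual, best, _mapq(best, cands))


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadPair:
    """A read pair in as-sequenced orientation."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def _pair_candidates(
    c1s: Sequence[_Candidate], c2s: Sequence[_Candidate],
    len1: int, len2: int, tmin: int, tmax: int,
) -> list[tuple[int, _Candidate, _Candidate]]:
    """Proper combinations (same seq, opposite strands, fragment in bounds),
    sorted by total edit distance then position."""
    out = []
    for c1 in c1s:
        for c2 in c2s:
            if c1.seq_name != c2.seq_name or c1.is_reverse == c2.is_reverse:
                continue
            start = min(c1.pos, c2.pos)
            end = max(c1.pos + len1, c2.pos + len2)
            frag = end - start
            # FR orientation: the forward mate must be leftmost
            fwd, rev = (c1, c2) if not c1.is_reverse else (c2, c1)
            if fwd.pos > rev.pos:
                continue
            if tmin <= frag <= tmax:
                out.append((c1.dist + c2.dist, c1, c2))
    out.sort(key=lambda t: (t[0], t[1].seq_name, t[1].pos, t[2].pos))
    return out


def _set_mate_fields(a: ReadAlignment, b: ReadAlignment,
                     proper: bool) -> None:
    if b.is_mapped:
        a.mate_seq_name, a.mate_pos = b.seq_name, b.pos
        a.mate_is_reverse = b.is_reverse
    a.proper_pair = proper and a.is_mapped and b.is_mapped
    if (
        a.is_mapped and b.is_mapped
        and a.seq_name == b.seq_name
    ):
        start = min(a.pos, b.pos)
        end = max(a.reference_span()[1], b.reference_span()[1])
        span = end - start
        leftmost = a.pos < b.pos or (a.pos == b.pos and a.mate == 1)
        a.tlen = span if leftmost else -span
    else:
        a.tlen = 0


def align_pair(
    index: SeedIndex, pair: ReadPair,
    flm: FragmentLengthModel | None = None,
    max_edit_frac: float = 0.05,
) -> tuple[ReadAlignment, ReadAlignment]:
    """Align both mates independently, then rescore as a pair.

    Among each mate's candidate loci, a combination on one reference
    sequence with opposite orientations and an implied fragment length
    inside the fragment-model truncation bounds is preferred when its total
    edit distance matches the unconstrained optimum; pair-unique rescues of
    a multi-mapping mate earn the pair's MAPQ.
    """
    tmin = flm.trunc_min if flm is not None else 0
    tmax = flm.trunc_max if flm is not None else 10_000
    me1 = max(1, int(max_edit_frac * len(pair.seq1)))
    me2 = max(1, int(max_edit_frac * len(pair.seq2)))
    c1s = (
        _find_candidates(index, pair.seq1, me1)
        if len(pair.seq1) >= index.k else []
    )
    c2s = (
        _find_candidates(index, pair.seq2, me2)
        if len(pair.seq2) >= index.k else []
    )
    chosen1 = c1s[0] if c1s else None
    chosen2 = c2s[0] if c2s else None
    mapq1 = _mapq(chosen1, c1s) if chosen1 else 0
    mapq2 = _mapq(chosen2, c2s) if chosen2 else 0
    proper = False
    combos = _pair_candidates(
        c1s, c2s, len(pair.seq1), len(pair.seq2), tmin, tmax
    )
    if combos:
        best_total = combos[0][0]
        # accept the pairing when it is no worse than aligning each mate
        # independently (it resolves ties; it never overrides a strictly
        # better independent locus)
        indep = (c1s[0].dist if c1s else 0) + (c2s[0].dist if c2s else 0)
        if best_total <= indep:
            _, chosen1, chosen2 = combos[0]
            proper = True
            seconds = [t for t in combos if (
                (t[1].pos, t[1].seq_name, t[2].pos)
                != (chosen1.pos, chosen1.seq_name, chosen2.pos)
            )]
            pair_mapq = (
                60 if not seconds
                else 0 if seconds[0][0] == best_total
                else min(60, 6 * (seconds[0][0] - best_total))
            )
            # a mate whose own MAPQ was ambiguous inherits the pair's
            mapq1 = max(_mapq(chosen1, c1s), min(pair_mapq, 60)) \
                if _mapq(chosen1, c1s) == 0 else _mapq(chosen1, c1s)
            mapq2 = max(_mapq(chosen2, c2s), min(pair_mapq, 60)) \
                if _mapq(chosen2, c2s) == 0 else _mapq(chosen2, c2s)
    a1 = _to_alignment(pair.name, 1, pair.seq1, pair.qual1, chosen1, mapq1)
    a2 = _to_alignment(pair.name, 2, pair.seq2, pair.qual2, chosen2, mapq2)
    _set_mate_fields(a1, a2, proper)
    _set_mate_fields(a2, a1, proper)
    return a1, a2


# ---------------------------------------------------------------------------
# contracts
# ---------------------------------------------------------------------------

class AlignerContract(Protocol):
    """Anything that maps read pairs onto a reference.

    Implementations must emit every input read exactly once as mate 1 and
    once as mate 2 (mapped or unmapped) — read conservation is checked by
    the pipeline.
    """

    name: str
    deterministic: bool

    def align(
        self, pairs: Iterable[ReadPair], reference: dict[str, str]
    ) -> Iterator[tuple[ReadAlignment, ReadAlignment]]:
        ...


class BuiltinAligner:
    """The hermetic k-mer seed-and-extend aligner."""

    deterministic = True

    def __init__(
        self,
        k: int = 21,
        max_edit_frac: float = 0.05,
        flm: FragmentLengthModel | None = None,
    ):
        self.k = k
        self.max_edit_frac = max_edit_frac
        self.flm = flm
        self.name = f"builtin-kmer(k={k})"
        self._index_cache: tuple[int, SeedIndex] | None = None

    def _index_for(self, reference: dict[str, str]) -> SeedIndex:
        key = id(reference)
        if self._index_cache is None or self._index_cache[0] != key:
            self._index_cache = (key, SeedIndex(reference, self.k))
        return self._index_cache[1]

    def align(
        self, pairs: Iterable[ReadPair], reference: dict[str, str]
    ) -> Iterator[tuple[ReadAlignment, ReadAlignment]]:
        index = self._index_for(reference)
        for pair in pairs:
            yield align_pair(
                index, pair, flm=self.flm, max_edit_frac=self.max_edit_frac
            )


class AlignerContractError(RuntimeError):
    """An aligner violated the read-conservation contract or failed."""


class ExternalAligner:
    """Adapter running an external aligner command emitting SAM.

    ``command_template`` must contain the placeholders ``{reference}``,
    ``{fastq1}``, ``{fastq2}`` and ``{output}``; the command must write
    standard SAM to ``{output}``.  Output records are checked against the
    input read names (conservation) before being yielded.
    """

    deterministic = False

    def __init__(self, command_template: str):
        for ph in ("{reference}", "{fastq1}", "{fastq2}", "{output}"):
            if ph not in command_template:
                raise ValueError(f"command template missing {ph}")
        self.command_template = command_template
        self.name = f"exec:{command_template.split()[0]}"

    def align(
        self, pairs: Iterable[ReadPair], reference: dict[str, str]
    ) -> Iterator[tuple[ReadAlignment, ReadAlignment]]:
        from .reference_builder import write_fasta

        pairs = list(pairs)
        with tempfile.TemporaryDirectory(prefix="targetfirst-ext-") as tmp:
            tmp = Path(tmp)
            ref_fa = tmp / "ref.fa"
            write_fasta(sorted(reference.items()), ref_fa)
            fq1, fq2 = tmp / "r1.fastq", tmp / "r2.fastq"
            write_fastq_pairs(pairs, fq1, fq2)
            out_sam = tmp / "out.sam"
            cmd = self.command_template.format(
                reference=shlex.quote(str(ref_fa)),
                fastq1=shlex.quote(str(fq1)),
                fastq2=shlex.quote(str(fq2)),
                output=shlex.quote(str(out_sam)),
            )
            proc = subprocess.run(
                cmd, shell=True, capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise AlignerContractError(
                    f"external aligner exited {proc.returncode}: "
                    f"{proc.stderr[-2000:]}"
                )
            try:
                records = read_sam(out_sam)
            except Exception as exc:
                raise AlignerContractError(
                    f"external aligner produced unparseable SAM: {exc}"
                ) from exc
        by_key = {(r.read_name, r.mate): r for r in records}
        names = {p.name for p in pairs}
        for r in records:
            if r.read_name not in names:
                raise AlignerContractError(
                    f"external aligner emitted unknown read {r.read_name!r}"
                )
        for p in pairs:
            try:
                yield by_key[(p.name, 1)], by_key[(p.name, 2)]
            except KeyError as exc:
                raise AlignerContractError(
                    f"external aligner lost read {p.name!r}"
                ) from exc


def make_aligner(spec: str, flm: FragmentLengthModel | None = None,
                 k: int = 21) -> AlignerContract:
    """``builtin`` or ``exec:<command template>``."""
    if spec == "builtin":
        return BuiltinAligner(k=k, flm=flm)
    if spec.startswith("exec:"):
        return ExternalAligner(spec[len("exec:"):])
    raise ValueError(f"unknown aligner spec {spec!r}")


# ---------------------------------------------------------------------------
# SAM / FASTQ I/O (via pysam)
# ---------------------------------------------------------------------------

def write_sam(
    alignments: Iterable[ReadAlignment],
    ref_lengths: dict[str, int],
    path: str | Path,
    program_name: str = "targetfirst",
    sort: bool = False,
) -> None:
    """Write alignments as plain SAM with a valid @HD/@SQ header."""
    import pysam

    names = sorted(ref_lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unsorted"},
            "SQ": [{"SN": n, "LN": ref_lengths[n]} for n in names],
            "PG": [{"ID": program_name, "PN": program_name}],
        }
    )
    alignments = list(alignments)
    if sort:
        tid = {n: i for i, n in enumerate(names)}
        alignments.sort(
            key=lambda a: (
                (0, tid[a.seq_name], a.pos) if a.is_mapped else (1, 0, 0),
                a.read_name,
                a.mate,
            )
        )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_name
            seg.query_sequence = a.seq
            seg.query_qualities = pysam.qualitystring_to_array(a.qual)
            seg.flag = a.flag
            if a.is_mapped:
                seg.reference_name = a.seq_name
                seg.reference_start = a.pos
                seg.mapping_quality = a.mapq
                seg.cigarstring = a.cigar
                seg.set_tag("NM", a.nm)
            if a.mate_seq_name is not None:
                seg.next_reference_name = a.mate_seq_name
                seg.next_reference_start = a.mate_pos
            seg.template_length = a.tlen
            out.write(seg)


def read_sam(path: str | Path) -> list[ReadAlignment]:
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            qual = (
                pysam.qualities_to_qualitystring(seg.query_qualities)
                if seg.query_qualities is not None
                else "I" * len(seg.query_sequence or "")
            )
            out.append(
                ReadAlignment(
                    read_name=seg.query_name,
                    mate=2 if seg.is_read2 else 1,
                    seq=seg.query_sequence or "",
                    qual=qual,
                    seq_name=None if seg.is_unmapped else seg.reference_name,
                    pos=None if seg.is_unmapped else seg.reference_start,
                    is_reverse=bool(seg.is_reverse) and not seg.is_unmapped,
                    cigar=None if seg.is_unmapped else seg.cigarstring,
                    mapq=seg.mapping_quality,
                    nm=seg.get_tag("NM") if seg.has_tag("NM") else 0,
                    proper_pair=bool(seg.is_proper_pair),
                    mate_seq_name=(
                        None if seg.mate_is_unmapped or seg.next_reference_id < 0
                        else seg.next_reference_name
                    ),
                    mate_pos=(
                        None if seg.mate_is_unmapped or seg.next_reference_id < 0
                        else seg.next_reference_start
                    ),
                    mate_is_reverse=bool(seg.mate_is_reverse),
                    tlen=seg.template_length,
                )
            )
    return out


def read_fastq_pairs(fq1: str | Path, fq2: str | Path) -> list[ReadPair]:
    """Read mate files (optionally gzipped) into synchronized pairs."""
    import pysam

    pairs = []
    with pysam.FastxFile(str(fq1)) as f1, pysam.FastxFile(str(fq2)) as f2:
        for r1, r2 in zip(f1, f2):
            n1 = r1.name.removesuffix("/1")
            n2 = r2.name.removesuffix("/2")
            if n1 != n2:
                raise ValueError(
                    f"mate files out of sync: {r1.name!r} vs {r2.name!r}"
                )
            pairs.append(
                ReadPair(n1, r1.sequence, r1.quality or "I" * len(r1.sequence),
                         r2.sequence, r2.quality or "I" * len(r2.sequence))
            )
    return pairs


def write_fastq_pairs(
    pairs: Iterable[ReadPair], fq1: str | Path, fq2: str | Path
) -> None:
    with open(fq1, "w") as f1, open(fq2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")
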