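"""Evaluation machinery: concordance, call-set comparison, QC cascade.

Three independent checks of a call set:

* :func:`genotype_concordance` — against a SNP-array-style truth panel.
  A covered truth site with no VCF record is an *implied hom-ref* call;
  a site with zero aligned depth is a *no-call* and leaves the
  concordance denominator.
* :func:`compare_variant_sets` — shared/exclusive variants between two
  call sets (split SNV vs indel) after normalization (left-alignment and
  shared-base trimming), so the same event represented differently still
  matches.
* :func:`classify_discordant` — the QC cascade applied to calls exclusive
  to one set, in fixed precedence: quality-by-depth < 5, then strand bias
  (two-sided Fisher exact on the ref/alt x fwd/rev table), then depth
  < 10, then >= 5 homologous regions elsewhere in the genome; anything
  surviving is ``good``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from scipy import stats as scipy_stats

from .caller import VariantCall
from .reference_builder import GenomicInterval

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# truth genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthGenotype:
    """One array genotype: 0-based position, unordered allele pair."""

    seq_name: str
    pos: int
    ref: str
    alleles: frozenset[str] | tuple[str, str]

    def allele_set(self) -> frozenset[str]:
        return frozenset(self.alleles)


def read_truth_tsv(path: str | Path) -> list[TruthGenotype]:
    """4-column TSV: chrom, 1-based pos, ref base, genotype (e.g. ``AG``)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, pos, ref, gt = f
            if len(gt) != 2 or any(a not in "ACGT" for a in gt):
                raise ValueError(f"{path}:{lineno}: bad genotype {gt!r}")
            out.append(
                TruthGenotype(chrom, int(pos) - 1, ref, (gt[0], gt[1]))
            )
    return out


def read_hapmap_forward(
    path: str | Path, sample: str
) -> list[TruthGenotype]:
    """HapMap forward-strand dialect: whitespace-separated, 11 metadata
    columns (rs#, alleles, chrom, pos, strand, ...) then one genotype
    column per sample; genotypes like ``AG``, missing ``NN``."""
    out = []
    with open(path) as fh:
        header = fh.readline().split()
        try:
            col = header.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in {path}") from None
        for line in fh:
            f = line.split()
            if len(f) <= col:
                continue
            gt = f[col]
            if len(gt) != 2 or any(a not in "ACGT" for a in gt):
                continue  # NN / malformed: skip
            chrom = f[2] if f[2].startswith("chr") else "chr" + f[2]
            ref = f[1].split("/")[0]
            out.append(TruthGenotype(chrom, int(f[3]) - 1, ref, (gt[0], gt[1])))
    return out


# ---------------------------------------------------------------------------
# concordance (Table-1 shaped)
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    n_truth: int
    n_concordant: int
    n_discordant: int
    n_nocall: int
    n_excluded: int = 0
    discordant_sites: list[tuple[str, int]] = field(default_factory=list)

    @property
    def pct_concordance(self) -> float:
        denom = self.n_concordant + self.n_discordant
        return 100.0 * self.n_concordant / denom if denom else 0.0

    def validate(self) -> None:
        if (
            self.n_concordant + self.n_discordant + self.n_nocall
            != self.n_truth
        ):
            raise AssertionError("concordance partition violated")

    def as_text(self) -> str:
        return (
            f"truth sites           {self.n_truth}\n"
            f"concordant            {self.n_concordant}\n"
            f"discordant            {self.n_discordant}\n"
            f"no-call (zero depth)  {self.n_nocall}\n"
            f"excluded (bad ref)    {self.n_excluded}\n"
            f"% concordance         {self.pct_concordance:.2f}\n"
        )


def _called_genotype(call: VariantCall) -> frozenset[str]:
    alleles = [call.ref, call.alt]
    gt = {alleles[int(x)] for x in call.genotype.split("/")}
    return frozenset(gt)


def genotype_concordance(
    calls: Iterable[VariantCall],
    truth: Sequence[TruthGenotype],
    depth_at: Callable[[str, int], int] | dict[tuple[str, int], int] | None
    = None,
    genome: dict[str, str] | None = None,
) -> ConcordanceReport:
    """Compare explicit + implied genotypes against a truth panel.

    ``depth_at`` supplies aligned depth per truth site; sites with zero
    depth become no-calls, covered sites without a call become implied
    hom-ref.  ``None`` treats every site as covered.  When ``genome`` is
    given, truth sites whose stated ref base disagrees with the genome are
    excluded with a warning (and leave ``n_truth``).
    """
    if isinstance(depth_at, dict):
        d = depth_at
        depth_fn = lambda s, p: d.get((s, p), 0)  # noqa: E731
    elif depth_at is None:
        depth_fn = lambda s, p: 1  # noqa: E731
    else:
        depth_fn = depth_at
    by_site: dict[tuple[str, int], VariantCall] = {}
    for c in calls:
        if c.var_type == "SNV":
            by_site[(c.seq_name, c.pos)] = c
    n_conc = n_disc = n_nocall = n_excl = 0
    discordant_sites = []
    for t in truth:
        if genome is not None:
            refbase = genome.get(t.seq_name, "")[t.pos : t.pos + 1]
            if refbase != t.ref:
                logger.warning(
                    "truth site %s:%d ref %r inconsistent with genome %r; "
                    "excluded", t.seq_name, t.pos + 1, t.ref, refbase,
                )
                n_excl += 1
                continue
        call = by_site.get((t.seq_name, t.pos))
        if call is None:
            if depth_fn(t.seq_name, t.pos) <= 0:
                n_nocall += 1
                continue
            called = frozenset({t.ref})  # implied hom-ref
        else:
            called = _called_genotype(call)
        if called == t.allele_set():
            n_conc += 1
        else:
            n_disc += 1
            discordant_sites.append((t.seq_name, t.pos))
    report = ConcordanceReport(
        n_truth=len(truth) - n_excl,
        n_concordant=n_conc,
        n_discordant=n_disc,
        n_nocall=n_nocall,
        n_excluded=n_excl,
        discordant_sites=discordant_sites,
    )
    report.validate()
    return report


# ---------------------------------------------------------------------------
# variant-set comparison (Table-2 shaped)
# ---------------------------------------------------------------------------

def normalize_variant(
    seq_name: str, pos: int, ref: str, alt: str, genome: dict[str, str]
) -> tuple[str, int, str, str]:
    """Left-align and trim a variant to canonical form.

    Shared trailing then leading bases are trimmed (keeping one base of
    each allele for indels), then indels are shifted left while the base
    preceding the event equals the last base of the longer allele.
    """
    seq = genome[seq_name].upper()
    ref, alt = ref.upper(), alt.upper()
    # left-align: trim a shared trailing base; when an allele empties,
    # extend both left from the reference and shift the position
    while True:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if (not ref or not alt) and pos > 0:
            pos -= 1
            ref, alt = seq[pos] + ref, seq[pos] + alt
            changed = True
        if not changed:
            break
    # trim shared leading bases
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return seq_name, pos, ref, alt


@dataclass
class TypeComparison:
    n_shared: int = 0
    n_exclusive_a: int = 0
    n_exclusive_b: int = 0
    exclusive_a: list[VariantCall] = field(default_factory=list)
    exclusive_b: list[VariantCall] = field(default_factory=list)


@dataclass
class VariantSetComparison:
    snv: TypeComparison = field(default_factory=TypeComparison)
    indel: TypeComparison = field(default_factory=TypeComparison)

    def of(self, var_type: str) -> TypeComparison:
        return self.snv if var_type == "SNV" else self.indel

    def as_text(self, label_a: str = "A", label_b: str = "B") -> str:
        rows = []
        for vt in ("SNV", "INDEL"):
            c = self.of(vt)
            rows.append(f"{label_a}\t{vt}s\tShared\t{c.n_shared}")
            rows.append(f"{label_b}\t{vt}s\tShared\t{c.n_shared}")
            rows.append(f"{label_a}\t{vt}s\tExclusive\t{c.n_exclusive_a}")
            rows.append(f"{label_b}\t{vt}s\tExclusive\t{c.n_exclusive_b}")
        return "Workflow\tVariant\tType\tCount\n" + "\n".join(rows) + "\n"


def compare_variant_sets(
    a: Sequence[VariantCall],
    b: Sequence[VariantCall],
    genome: dict[str, str],
    regions: Sequence[GenomicInterval] | None = None,
) -> VariantSetComparison:
    """Shared/exclusive variants by exact key after normalization."""
    from .pipeline import restrict_calls

    if regions is not None:
        a = restrict_calls(a, regions)
        b = restrict_calls(b, regions)

    def norm_map(calls: Sequence[VariantCall]):
        out = {}
        for c in calls:
            key = normalize_variant(c.seq_name, c.pos, c.ref, c.alt, genome)
            out.setdefault(key, c)  # shared counted once
        return out

    ka, kb = norm_map(a), norm_map(b)
    cmp = VariantSetComparison()
    for key, call in ka.items():
        tc = cmp.of("SNV" if len(key[2]) == len(key[3]) == 1 else "INDEL")
        if key in kb:
            tc.n_shared += 1
        else:
            tc.n_exclusive_a += 1
            tc.exclusive_a.append(call)
    for key, call in kb.items():
        if key not in ka:
            tc = cmp.of("SNV" if len(key[2]) == len(key[3]) == 1 else "INDEL")
            tc.n_exclusive_b += 1
            tc.exclusive_b.append(call)
    return cmp


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

def strand_bias_test(
    ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int
) -> float:
    """Two-sided Fisher exact p-value on the ref/alt x fwd/rev table."""
    if min(ref_fwd, ref_rev, alt_fwd, alt_rev) < 0:
        raise ValueError("strand counts must be >= 0")
    if ref_fwd + ref_rev + alt_fwd + alt_rev == 0:
        return 1.0
    _, p = scipy_stats.fisher_exact(
        [[ref_fwd, ref_rev], [alt_fwd, alt_rev]], alternative="two-sided"
    )
    return float(p)


def homology_count(
    genome: dict[str, str],
    seq_name: str,
    pos: int,
    flank: int = 50,
    max_mismatch_frac: float = 0.05,
) -> int:
    """Number of other genomic loci (both strands) matching the window
    around ``pos`` with at most ``max_mismatch_frac`` mismatches.

    The window is ``[pos - flank, pos + flank + 1)``, truncated (with a
    warning) at sequence ends.  Matching is ungapped; candidate loci are
    found by exact seeding with pigeonhole chunks and verified by Hamming
    distance.  The query locus itself (same sequence, same start, forward
    strand) is excluded.
    """
    from .aligner import revcomp

    seq = genome[seq_name]
    start = pos - flank
    end = pos + flank + 1
    if start < 0 or end > len(seq):
        logger.warning(
            "homology window at %s:%d truncated at sequence end",
            seq_name, pos + 1,
        )
        start, end = max(0, start), min(len(seq), end)
    window = seq[start:end].upper()
    w = len(window)
    if w == 0:
        return 0
    max_mm = int(max_mismatch_frac * w)
    # pigeonhole: any match with <= max_mm mismatches shares one exact chunk
    n_chunks = max_mm + 1
    bounds = [round(i * w / n_chunks) for i in range(n_chunks + 1)]
    count = 0
    for name in sorted(genome):
        target = genome[name].upper()
        for strand in (0, 1):
            probe = window if strand == 0 else revcomp(window)
            cand_starts: set[int] = set()
            for i in range(n_chunks):
                lo, hi = bounds[i], bounds[i + 1]
                chunk = probe[lo:hi]
                if not chunk:
                    continue
                at = target.find(chunk)
                while at != -1:
                    cand_starts.add(at - lo)
                    at = target.find(chunk, at + 1)
            for s in sorted(cand_starts):
                if s < 0 or s + w > len(target):
                    continue
                if strand == 0 and name == seq_name and s == start:
                    continue  # the query locus itself
                mm = sum(
                    1 for x, y in zip(probe, target[s : s + w]) if x != y
                )
                if mm <= max_mm:
                    count += 1
    return count


@dataclass
class QCClassification:
    category: str  # low_qd | strand_bias | low_depth | homologous | good
    qd: float
    sb_p: float
    depth: int
    homolog_count: int | None = None


def classify_discordant(
    v: VariantCall,
    genome: dict[str, str] | None = None,
    min_qd: float = 5.0,
    sb_alpha: float = 0.01,
    min_depth: int = 10,
    homolog_threshold: int = 5,
    flank: int = 50,
) -> QCClassification:
    """QC cascade with fixed precedence: low QD, strand bias, low depth,
    homologous region, else good.  The homology scan runs only when the
    first three filters pass and ``genome`` is supplied."""
    p = strand_bias_test(v.ref_fwd, v.ref_rev, v.alt_fwd, v.alt_rev)
    if v.qd < min_qd:
        return QCClassification("low_qd", v.qd, p, v.depth)
    if p < sb_alpha:
        return QCClassification("strand_bias", v.qd, p, v.depth)
    if v.depth < min_depth:
        return QCClassification("low_depth", v.qd, p, v.depth)
    n_hom = None
    if genome is not None:
        n_hom = homology_count(genome, v.seq_name, v.pos, flank=flank)
        if n_hom >= homolog_threshold:
            return QCClassification("homologous", v.qd, p, v.depth, n_hom)
    return QCClassification("good", v.qd, p, v.depth, n_hom)
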