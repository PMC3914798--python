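"""Built-in aligner: seeding, extension, pairing, contracts, SAM I/O."""

import sys

import numpy as np
import pytest

import targetfirst as tf
from targetfirst.aligner import (
    SeedIndex,
    align_read,
    revcomp,
    write_fastq_pairs,
)


def random_genome(seed, length, name="ref1"):
    rng = np.random.default_rng(seed)
    return {name: "".join(rng.choice(list("ACGT"), length))}


def semiglobal_scan(read, reference):
    """Independent oracle: full-reference semiglobal edit-distance scan
    (both strands, no seeding).  Returns (dist, seq_name, pos, is_reverse)
    of the best locus with the aligner's tie order."""
    import edlib

    best = None
    for name in sorted(reference):
        ref = reference[name]
        for is_reverse in (False, True):
            q = revcomp(read) if is_reverse else read
            res = edlib.align(q, ref, mode="HW", task="locations")
            d = res["editDistance"]
            for start, _ in res["locations"]:
                cand = (d, name, start, is_reverse)
                if best is None or cand < best:
                    best = cand
    return best


def dp_semiglobal(read, ref):
    """Tiny pure-numpy semiglobal DP, cross-checking edlib itself."""
    m, n = len(read), len(ref)
    prev = np.zeros(n + 1, dtype=int)
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=int)
        cur[0] = i
        for j in range(1, n + 1):
            cost = read[i - 1] != ref[j - 1]
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev.min())


class TestSeedIndex:
    def test_kmer_count_and_content(self):
        genome = random_genome(1, 60)
        idx = SeedIndex(genome, k=11)
        n_pos = sum(len(v) for v in idx.index.values())
        assert n_pos == 60 - 11 + 1
        for kmer, hits in idx.index.items():
            for name, pos in hits:
                assert genome[name][pos : pos + 11] == kmer

    def test_kmers_overlapping_n_excluded(self):
        genome = {"r": "ACGTACGTACG" + "N" + "ACGTACGTACG"}
        idx = SeedIndex(genome, k=11)
        assert all("N" not in kmer for kmer in idx.index)
        assert sum(len(v) for v in idx.index.values()) == 2

    def test_reference_shorter_than_k_warns_empty(self, caplog):
        idx = SeedIndex({"r": "ACGT"}, k=11)
        assert idx.index == {}

    @pytest.mark.parametrize("k", [10, 9, 33])
    def test_k_validation(self, k):
        with pytest.raises(ValueError):
            SeedIndex({"r": "A" * 50}, k=k)


class TestAlignRead:
    def test_exact_unique_substring(self):
        genome = random_genome(2, 2000)
        idx = SeedIndex(genome)
        read = genome["ref1"][500:600]
        a = align_read(idx, "r1", read, "I" * 100)
        assert (a.seq_name, a.pos, a.nm, a.mapq) == ("ref1", 500, 0, 60)
        assert a.cigar == "100M"

    def test_two_locus_tie_lowest_position_mapq0(self):
        core = random_genome(3, 300)["ref1"]
        dup = core[100:200]
        genome = {"ref1": core + dup + core[200:]}
        idx = SeedIndex(genome)
        a = align_read(idx, "r1", dup, "I" * 100)
        assert (a.pos, a.mapq) == (100, 0)

    def test_reverse_complement_read(self):
        genome = random_genome(4, 2000)
        idx = SeedIndex(genome)
        read = revcomp(genome["ref1"][700:800])
        a = align_read(idx, "r1", read, "I" * 100)
        assert (a.seq_name, a.pos, a.is_reverse) == ("ref1", 700, True)
        assert a.seq == genome["ref1"][700:800]  # stored ref-oriented

    def test_no_candidate_gives_unmapped(self):
        idx = SeedIndex(random_genome(5, 1000))
        a = align_read(idx, "r1", "A" * 100, "I" * 100)
        assert not a.is_mapped and a.pos is None and a.cigar is None

    @pytest.mark.parametrize("n_subs", [1, 2, 4])
    def test_substituted_reads_match_full_scan_oracle(self, n_subs):
        genome = random_genome(6, 20_000)
        idx = SeedIndex(genome)
        rng = np.random.default_rng(6)
        for _ in range(15):
            start = int(rng.integers(0, 20_000 - 100))
            read = list(genome["ref1"][start : start + 100])
            for p in rng.choice(100, size=n_subs, replace=False):
                read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
            read = "".join(read)
            a = align_read(idx, "r", read, "I" * 100)
            d, name, pos, is_rev = semiglobal_scan(read, genome)
            assert a.is_mapped
            assert (a.nm, a.seq_name, a.pos, a.is_reverse) == (
                d, name, pos, is_rev
            )

    def test_edlib_oracle_agrees_with_dp_on_tiny_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            ref = "".join(rng.choice(list("ACGT"), 60))
            read = "".join(rng.choice(list("ACGT"), 15))
            d, _, _, is_rev = semiglobal_scan(read, {"r": ref})
            probe = revcomp(read) if is_rev else read
            dp_best = min(dp_semiglobal(read, ref),
                          dp_semiglobal(revcomp(read), ref))
            assert dp_semiglobal(probe, ref) == d == dp_best

    def test_indel_read_aligns_gapped(self):
        genome = random_genome(7, 5000)
        idx = SeedIndex(genome)
        src = genome["ref1"][1000:1103]
        read = src[:50] + src[53:]  # 3 bp deletion
        a = align_read(idx, "r", read, "I" * 100)
        assert a.is_mapped and a.pos == 1000 and a.nm == 3
        assert "D" in a.cigar


class TestAlignPairs:
    def test_concordant_unique_pair_is_proper(self):
        genome = random_genome(9, 5000)
        idx = SeedIndex(genome)
        frag = genome["ref1"][2000:2400]
        pair = tf.ReadPair("p", frag[:100], "I" * 100,
                           revcomp(frag[-100:]), "I" * 100)
        flm = tf.FragmentLengthModel.normal(400, 50, 250, 700)
        a1, a2 = tf.align_pair(idx, pair, flm=flm)
        assert a1.proper_pair and a2.proper_pair
        assert (a1.pos, a2.pos) == (2000, 2300)
        assert a1.tlen == 400 and a2.tlen == -400

    def test_multimapping_mate_rescued_by_concordance(self):
        # mate-2 sequence occurs twice; only one copy is concordant
        core = random_genome(10, 6000)["ref1"]
        dup = core[2300:2400]
        genome = {"ref1": core + dup + core[2400:]}
        idx = SeedIndex(genome)
        pair = tf.ReadPair(
            "p", genome["ref1"][2000:2100], "I" * 100,
            revcomp(dup), "I" * 100,
        )
        flm = tf.FragmentLengthModel.normal(400, 50, 250, 700)
        a1, a2 = tf.align_pair(idx, pair, flm=flm)
        assert a2.pos == 2300 and a2.proper_pair
        assert a2.mapq > 0  # pairing disambiguated the tie

    def test_simulated_error_free_pairs_recover_true_loci(self, small_world):
        cfg = tf.SimConfig(
            genome_length=20_000, n_genes=2, coverage=10,
            error_rate=0.0, snv_density=0.0, indel_density=0.0, seed=3,
        )
        sim = tf.simulate_genome(cfg)
        haps = tf.inject_variants(sim.genome, cfg)
        pairs = tf.simulate_reads(haps, cfg, n_pairs=1000)
        aligner = tf.BuiltinAligner(flm=cfg.flm)
        ok = total = 0
        for a1, a2 in aligner.align(pairs, sim.genome):
            chrom, start, end, _ = tf.decode_read_name(a1.read_name)
            for a in (a1, a2):
                total += 1
                truth_pos = start if not a.is_reverse else end - 100
                if a.is_mapped and a.seq_name == chrom and \
                        a.pos == truth_pos:
                    ok += 1
        assert ok / total >= 0.999


class TestContracts:
    def test_read_conservation_and_determinism(self, small_world, tmp_path):
        pairs = small_world.pairs[:300]
        sams = []
        for run in (1, 2):
            aligner = tf.BuiltinAligner(flm=small_world.cfg.flm)
            out = []
            for a1, a2 in aligner.align(pairs, small_world.genome):
                out.extend((a1, a2))
            assert len(out) == 2 * len(pairs)
            assert {(a.read_name, a.mate) for a in out} == {
                (p.name, m) for p in pairs for m in (1, 2)
            }
            p = tmp_path / f"run{run}.sam"
            tf.aligner.write_sam(
                out,
                {c: len(s) for c, s in small_world.genome.items()},
                p,
            )
            sams.append(p.read_bytes())
        assert sams[0] == sams[1]

    def test_sam_round_trip(self, small_world, tmp_path):
        aligner = tf.BuiltinAligner(flm=small_world.cfg.flm)
        out = []
        for a1, a2 in aligner.align(small_world.pairs[:100],
                                    small_world.genome):
            out.extend((a1, a2))
        p = tmp_path / "rt.sam"
        glens = {c: len(s) for c, s in small_world.genome.items()}
        tf.aligner.write_sam(out, glens, p)
        back = tf.aligner.read_sam(p)
        assert len(back) == len(out)
        for a, b in zip(out, back):
            assert (a.read_name, a.mate, a.seq_name, a.pos, a.cigar,
                    a.is_reverse, a.mapq, a.nm, a.seq, a.qual) == \
                   (b.read_name, b.mate, b.seq_name, b.pos, b.cigar,
                    b.is_reverse, b.mapq, b.nm, b.seq, b.qual)

    def test_mapped_cigar_consumes_read_length(self, small_iterative):
        for a in small_iterative.step2.retained[:500]:
            if a.is_mapped:
                assert tf.aligner.cigar_query_length(a.cigar) == len(a.seq)


STUB_PASSTHROUGH = """\
import sys, shutil
# args: reference fastq1 fastq2 output golden
shutil.copy(sys.argv[5], sys.argv[4])
"""

STUB_FAIL = "import sys; sys.exit(1)\n"


class TestExternalAdapter:
    def _golden(self, tmp_path, pairs, reference):
        aligner = tf.BuiltinAligner()
        out = []
        for a1, a2 in aligner.align(pairs, reference):
            out.extend((a1, a2))
        golden = tmp_path / "golden.sam"
        tf.aligner.write_sam(
            out, {c: len(s) for c, s in reference.items()}, golden
        )
        return golden, out

    def _pairs(self, reference):
        seq = reference["ref1"]
        return [
            tf.ReadPair(f"p{i}", seq[i * 40 : i * 40 + 100], "I" * 100,
                        revcomp(seq[i * 40 + 200 : i * 40 + 300]), "I" * 100)
            for i in range(3)
        ]

    def test_stub_passthrough_yields_golden_records(self, tmp_path):
        reference = random_genome(12, 2000)
        pairs = self._pairs(reference)
        golden, records = self._golden(tmp_path, pairs, reference)
        stub = tmp_path / "stub.py"
        stub.write_text(STUB_PASSTHROUGH)
        ext = tf.ExternalAligner(
            f"{sys.executable} {stub} {{reference}} {{fastq1}} {{fastq2}} "
            f"{{output}} {golden}"
        )
        got = [a for pair in ext.align(pairs, reference) for a in pair]
        assert [(a.read_name, a.mate, a.pos) for a in got] == [
            (a.read_name, a.mate, a.pos) for a in records
        ]

    def test_stub_failure_raises(self, tmp_path):
        stub = tmp_path / "stub.py"
        stub.write_text(STUB_FAIL)
        ext = tf.ExternalAligner(
            f"{sys.executable} {stub} {{reference}} {{fastq1}} {{fastq2}} "
            f"{{output}}"
        )
        reference = random_genome(13, 1000)
        with pytest.raises(tf.AlignerContractError, match="exited 1"):
            list(ext.align(self._pairs(reference), reference))

    def test_stub_emitting_foreign_read_violates_contract(self, tmp_path):
        reference = random_genome(14, 2000)
        pairs = self._pairs(reference)
        golden, _ = self._golden(
            tmp_path,
            pairs + [tf.ReadPair("ghost", "A" * 100, "I" * 100,
                                 "C" * 100, "I" * 100)],
            reference,
        )
        stub = tmp_path / "stub.py"
        stub.write_text(STUB_PASSTHROUGH)
        ext = tf.ExternalAligner(
            f"{sys.executable} {stub} {{reference}} {{fastq1}} {{fastq2}} "
            f"{{output}} {golden}"
        )
        with pytest.raises(tf.AlignerContractError, match="unknown read"):
            list(ext.align(pairs, reference))

    def test_template_placeholder_validation(self):
        with pytest.raises(ValueError, match="output"):
            tf.ExternalAligner("aln {reference} {fastq1} {fastq2}")
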