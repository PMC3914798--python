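"""Evaluation: concordance partition, set comparison with normalization,
Fisher strand bias, homology counting, QC cascade precedence."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import targetfirst as tf
from targetfirst.evaluation import TruthGenotype, normalize_variant


def call(seq, pos, ref, alt, gt="0/1", qual=50.0, depth=30,
         sb=(8, 7, 8, 7)):
    return tf.VariantCall(seq, pos, ref, alt, gt, qual, depth, *sb)


class TestGenotypeConcordance:
    def test_four_of_five_match(self):
        truth = [
            TruthGenotype("chr1", p, "A", ("A", "G")) for p in range(5)
        ]
        calls = [call("chr1", p, "A", "G") for p in range(4)]
        calls.append(call("chr1", 4, "A", "G", gt="1/1"))
        rep = tf.genotype_concordance(calls, truth)
        assert (rep.n_concordant, rep.n_discordant) == (4, 1)
        assert rep.pct_concordance == pytest.approx(80.0)

    def test_covered_absent_site_is_implied_hom_ref(self):
        truth = [TruthGenotype("chr1", 10, "C", ("C", "C"))]
        rep = tf.genotype_concordance(
            [], truth, depth_at={("chr1", 10): 25}
        )
        assert rep.n_concordant == 1

    def test_zero_depth_site_is_nocall(self):
        truth = [TruthGenotype("chr1", 10, "C", ("C", "T"))]
        rep = tf.genotype_concordance([], truth, depth_at={})
        assert (rep.n_nocall, rep.n_concordant, rep.n_discordant) == \
            (1, 0, 0)

    def test_truth_ref_inconsistent_with_genome_excluded(self, caplog):
        genome = {"chr1": "AAAA"}
        truth = [
            TruthGenotype("chr1", 1, "C", ("C", "T")),  # genome says A
            TruthGenotype("chr1", 2, "A", ("A", "A")),
        ]
        rep = tf.genotype_concordance([], truth, genome=genome)
        assert rep.n_excluded == 1 and rep.n_truth == 1
        assert rep.n_concordant == 1

    def test_unordered_allele_match(self):
        truth = [TruthGenotype("chr1", 5, "A", ("G", "A"))]
        rep = tf.genotype_concordance([call("chr1", 5, "A", "G")], truth)
        assert rep.n_concordant == 1

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 60),          # truth site position
                st.sampled_from(["AA", "AG", "GG"]),  # truth genotype
                st.integers(0, 2),           # 0 no call, 1 het, 2 hom call
                st.booleans(),               # covered?
            ),
            min_size=0,
            max_size=30,
            unique_by=lambda t: t[0],
        )
    )
    def test_partition_invariant(self, spec):
        truth = [
            TruthGenotype("chr1", p, "A", (gt[0], gt[1]))
            for p, gt, _, _ in spec
        ]
        calls = []
        depth = {}
        for p, _, kind, covered in spec:
            depth[("chr1", p)] = 20 if covered else 0
            if kind == 1:
                calls.append(call("chr1", p, "A", "G"))
            elif kind == 2:
                calls.append(call("chr1", p, "A", "G", gt="1/1"))
        rep = tf.genotype_concordance(calls, truth, depth_at=depth)
        assert (
            rep.n_concordant + rep.n_discordant + rep.n_nocall
            == rep.n_truth == len(truth)
        )

    def test_against_brute_force_on_simulation(
            self, small_world, small_iterative):
        sites = tf.make_array_sites(
            small_world.haps, small_world.genome, small_world.regions,
            200, seed=99,
        )
        truth = [
            TruthGenotype(c, p, ref, (gt[0], gt[1]))
            for c, p, ref, gt in sites
        ]
        depth = tf.depth_at_sites(
            small_iterative.step2.retained,
            [(t.seq_name, t.pos) for t in truth],
        )
        rep = tf.genotype_concordance(
            small_iterative.early_calls, truth, depth_at=depth
        )
        # independent per-site brute force
        by_site = {
            (c.seq_name, c.pos): c
            for c in small_iterative.early_calls
            if len(c.ref) == len(c.alt) == 1
        }
        n_conc = n_disc = n_nc = 0
        for t in truth:
            c = by_site.get((t.seq_name, t.pos))
            if c is None and depth.get((t.seq_name, t.pos), 0) == 0:
                n_nc += 1
                continue
            if c is None:
                got = {t.ref}
            else:
                alleles = [c.ref, c.alt]
                got = {alleles[int(i)] for i in c.genotype.split("/")}
            if got == set(t.alleles):
                n_conc += 1
            else:
                n_disc += 1
        assert (rep.n_concordant, rep.n_discordant, rep.n_nocall) == \
            (n_conc, n_disc, n_nc)


class TestCompareVariantSets:
    GENOME = {"chr1": "ACGTACGTACAAACGTACGT"}

    def test_identical_sets_all_shared(self):
        a = [call("chr1", 3, "T", "C"), call("chr1", 8, "A", "AT")]
        cmp = tf.compare_variant_sets(a, list(a), self.GENOME)
        assert cmp.snv.n_shared == 1 and cmp.indel.n_shared == 1
        assert cmp.snv.n_exclusive_a == cmp.indel.n_exclusive_b == 0

    def test_extra_indel_exclusive(self):
        a = [call("chr1", 3, "T", "C"), call("chr1", 8, "A", "AT")]
        b = [call("chr1", 3, "T", "C")]
        cmp = tf.compare_variant_sets(a, b, self.GENOME)
        assert cmp.indel.n_exclusive_a == 1
        assert cmp.indel.exclusive_a[0].pos == 8

    def test_symmetry(self):
        a = [call("chr1", 3, "T", "C"), call("chr1", 8, "A", "AT")]
        b = [call("chr1", 3, "T", "C"), call("chr1", 14, "G", "C")]
        ab = tf.compare_variant_sets(a, b, self.GENOME)
        ba = tf.compare_variant_sets(b, a, self.GENOME)
        for vt in ("SNV", "INDEL"):
            assert ab.of(vt).n_shared == ba.of(vt).n_shared
            assert ab.of(vt).n_exclusive_a == ba.of(vt).n_exclusive_b
            assert ab.of(vt).n_exclusive_b == ba.of(vt).n_exclusive_a

    def test_differently_padded_deletion_shared_after_normalization(self):
        # genome ...ACAAAC...: deleting one A of the homopolymer can be
        # written at several positions/paddings
        a = [call("chr1", 9, "CA", "C")]
        b = [call("chr1", 10, "AAA", "AA")]
        cmp = tf.compare_variant_sets(a, b, self.GENOME)
        assert cmp.indel.n_shared == 1
        assert cmp.indel.n_exclusive_a == cmp.indel.n_exclusive_b == 0

    def test_normalization_haplotype_oracle(self):
        """Two representations are normalized to the same key iff applying
        them to the reference yields the same sequence."""
        genome = {"c": "TTACACACAGGA"}
        reps = [
            ("c", 1, "TAC", "T"),
            ("c", 3, "CAC", "C"),
            ("c", 5, "CAC", "C"),
            ("c", 3, "C", "T"),
        ]

        def apply(pos, ref, alt):
            s = genome["c"]
            assert s[pos : pos + len(ref)] == ref
            return s[:pos] + alt + s[pos + len(ref):]

        keys = [normalize_variant(c, p, r, a, genome)
                for c, p, r, a in reps]
        haps = [apply(p, r, a) for _, p, r, a in reps]
        for i in range(len(reps)):
            for j in range(len(reps)):
                assert (keys[i] == keys[j]) == (haps[i] == haps[j])


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)

    def pmf(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    pobs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(
        pmf(x) for x in range(lo, hi + 1) if pmf(x) <= pobs * (1 + 1e-7)
    )


class TestStrandBias:
    def test_symmetric_table_p1(self):
        assert tf.strand_bias_test(10, 10, 10, 10) == 1.0

    def test_all_zero_table_p1(self):
        assert tf.strand_bias_test(0, 0, 0, 0) == 1.0

    def test_clear_bias_matches_enumeration(self):
        p = tf.strand_bias_test(20, 20, 15, 0)
        assert p == pytest.approx(fisher_oracle(20, 20, 15, 0), abs=1e-10)
        assert p < 0.01

    def test_tiny_opposite_singletons(self):
        p = tf.strand_bias_test(1, 0, 0, 1)
        assert p == pytest.approx(fisher_oracle(1, 0, 0, 1), abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            tf.strand_bias_test(-1, 0, 0, 0)

    @settings(max_examples=200, deadline=None)
    @given(*(st.integers(0, 25) for _ in range(4)))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        assert tf.strand_bias_test(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-10
        )


def hamming_scan_oracle(genome, seq_name, pos, flank, max_frac):
    """Exhaustive sliding-window Hamming scan over both strands."""
    from targetfirst.aligner import revcomp

    seq = genome[seq_name]
    start = max(0, pos - flank)
    end = min(len(seq), pos + flank + 1)
    window = seq[start:end]
    w = len(window)
    max_mm = int(max_frac * w)
    count = 0
    for name in sorted(genome):
        t = genome[name]
        arr = np.frombuffer(t.encode(), dtype=np.uint8)
        for strand, probe in ((0, window), (1, revcomp(window))):
            parr = np.frombuffer(probe.encode(), dtype=np.uint8)
            if len(arr) < w:
                continue
            sw = np.lib.stride_tricks.sliding_window_view(arr, w)
            mism = (sw != parr).sum(axis=1)
            for s in np.nonzero(mism <= max_mm)[0]:
                if strand == 0 and name == seq_name and int(s) == start:
                    continue
                count += 1
    return count


class TestHomologyCount:
    def test_unique_locus_zero(self):
        rng = np.random.default_rng(21)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 5000))}
        assert tf.homology_count(genome, "chr1", 2500) == 0

    def test_planted_five_copies_detected(self):
        rng = np.random.default_rng(22)
        unit = "".join(rng.choice(list("ACGT"), 200))
        spacer = lambda: "".join(rng.choice(list("ACGT"), 300))  # noqa: E731
        genome = {"chr1": spacer() + (unit + spacer()) * 6}
        pos = 300 + 100  # middle of the first copy
        assert tf.homology_count(genome, "chr1", pos) >= 5

    def test_reverse_strand_copy_counted(self):
        from targetfirst.aligner import revcomp

        rng = np.random.default_rng(23)
        unit = "".join(rng.choice(list("ACGT"), 150))
        pad = "".join(rng.choice(list("ACGT"), 400))
        genome = {"chr1": pad + unit + pad[::-1] + revcomp(unit) + pad}
        assert tf.homology_count(genome, "chr1", 400 + 75) >= 1

    def test_window_truncated_at_sequence_end(self, caplog):
        rng = np.random.default_rng(24)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 300))}
        tf.homology_count(genome, "chr1", 3)  # no raise

    @pytest.mark.parametrize("seed", [31, 32])
    def test_matches_exhaustive_hamming_scan(self, seed):
        rng = np.random.default_rng(seed)
        core = "".join(rng.choice(list("ACGT"), 6000))
        # plant a family of diverged copies of one segment
        unit = core[1000:1101]
        g = list(core)
        for at in (2000, 3000, 4000):
            mutated = list(unit)
            for p in rng.choice(101, size=3, replace=False):
                mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[
                    mutated[p]
                ]
            g[at : at + 101] = mutated
        genome = {"chr1": "".join(g)}
        for pos in (1050, 2050, 2500):
            assert tf.homology_count(genome, "chr1", pos) == \
                hamming_scan_oracle(genome, "chr1", pos, 50, 0.05)


class TestClassifyDiscordant:
    def test_low_qd_first(self):
        v = call("chr1", 5, "A", "G", qual=150.0, depth=50,
                 sb=(20, 20, 10, 0))
        v.qual = 3 * 50  # qd = 3
        v = tf.VariantCall("chr1", 5, "A", "G", "0/1", 150.0, 50,
                           20, 20, 10, 0)
        assert v.qd == pytest.approx(3.0)
        assert tf.classify_discordant(v).category == "low_qd"

    def test_strand_bias_second(self):
        v = tf.VariantCall("chr1", 5, "A", "G", "0/1", 400.0, 50,
                           20, 20, 15, 0)
        assert v.qd == 8.0
        assert tf.classify_discordant(v).category == "strand_bias"

    def test_low_depth_third(self):
        v = tf.VariantCall("chr1", 5, "A", "G", "0/1", 64.0, 8,
                           2, 2, 2, 2)
        assert tf.classify_discordant(v).category == "low_depth"

    def test_homologous_fourth(self):
        rng = np.random.default_rng(25)
        unit = "".join(rng.choice(list("ACGT"), 200))
        spacer = "".join(rng.choice(list("ACGT"), 300))
        genome = {"chr1": spacer + (unit + spacer) * 6}
        v = tf.VariantCall("chr1", 400, "A", "G", "0/1", 240.0, 30,
                           8, 7, 8, 7)
        got = tf.classify_discordant(v, genome=genome)
        assert got.category == "homologous"
        assert got.homolog_count >= 5

    def test_good_when_all_pass(self):
        rng = np.random.default_rng(26)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 3000))}
        v = tf.VariantCall("chr1", 1500, "A", "G", "0/1", 240.0, 30,
                           8, 7, 8, 7)
        assert tf.classify_discordant(v, genome=genome).category == "good"


class TestTruthReaders:
    def test_truth_tsv_round_trip(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chr1\t100\tA\tAG\nchr2\t5\tC\tCC\n")
        got = tf.read_truth_tsv(p)
        assert got[0] == TruthGenotype("chr1", 99, "A", ("A", "G"))
        assert got[1].pos == 4 and set(got[1].alleles) == {"C"}

    def test_truth_tsv_bad_genotype_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chr1\t100\tA\tAX\n")
        with pytest.raises(ValueError, match="genotype"):
            tf.read_truth_tsv(p)

    def test_hapmap_forward_dialect(self, tmp_path):
        from targetfirst.evaluation import read_hapmap_forward

        header = (
            "rs# alleles chrom pos strand assembly# center protLSID "
            "assayLSID panelLSID QCcode NA001 NA002"
        )
        rows = [
            "rs1 A/G chr1 100 + b37 x p a p Q AG GG",
            "rs2 C/T 2 200 + b37 x p a p Q NN CT",
            "rs3 C/T chr3 300 + b37 x p a p Q CC TT",
        ]
        p = tmp_path / "hapmap.txt"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        got = read_hapmap_forward(p, "NA001")
        assert len(got) == 2  # NN skipped
        assert got[0] == TruthGenotype("chr1", 99, "A", ("A", "G"))
        assert got[1].seq_name == "chr3"
        got2 = read_hapmap_forward(p, "NA002")
        assert [g.seq_name for g in got2] == ["chr1", "chr2", "chr3"]
        with pytest.raises(KeyError):
            read_hapmap_forward(p, "NA999")
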