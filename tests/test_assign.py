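"""SNP calling, pseudo-genome construction, read assignment, counting."""

import collections

import numpy as np
import pandas as pd
import pytest

import asedivergence as ad
from asedivergence import seqio
from asedivergence.assign import ReadPair


class TestCallSnps:
    def _pileup(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "A", "C", "G", "T"])

    def test_threshold_arithmetic(self):
        ref = {"c1": "G" * 200}
        pileups = {"O": self._pileup([
            ("c1", 10, 10, 0, 0, 0),    # clean A substitution -> called
            ("c1", 20, 1, 0, 0, 0),     # depth 1 < 2 -> not called
            ("c1", 30, 97, 0, 3, 0),    # freq 0.97 < 0.98 -> not called
            ("c1", 40, 0, 0, 50, 0),    # majority == reference -> not called
            ("c1", 50, 98, 0, 2, 0),    # freq exactly 0.98 -> called
        ])}
        snps = ad.call_snps(pileups, ref)
        assert list(snps.table["pos"]) == [10, 50]
        assert list(snps.table["alt"]) == ["A", "A"]

    def test_malformed_row_reports_position(self):
        ref = {"c1": "G" * 10}
        pileups = {"O": self._pileup([("c1", 5, -1, 0, 0, 0)])}
        with pytest.raises(ValueError, match="row 0"):
            ad.call_snps(pileups, ref)


class TestBuildGenomes:
    def test_empty_snpset_reproduces_reference(self):
        ref = {"c1": "ACGTACGT"}
        empty = ad.SnpSet(pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "parent"]))
        genomes = ad.build_parental_genomes(ref, empty)
        assert genomes.o == ref and genomes.s == ref

    def test_single_substitution_touches_one_site(self):
        ref = {"c1": "AAAAAAAAAA"}
        snps = ad.SnpSet(pd.DataFrame(
            [("c1", 5, "A", "T", "O")],
            columns=["chrom", "pos", "ref", "alt", "parent"]))
        genomes = ad.build_parental_genomes(ref, snps)
        assert genomes.o["c1"] == "AAAATAAAAA"
        assert genomes.s["c1"] == ref["c1"]

    def test_reference_mismatch_names_site(self):
        ref = {"c1": "AAAA"}
        snps = ad.SnpSet(pd.DataFrame(
            [("c1", 2, "G", "T", "O")],
            columns=["chrom", "pos", "ref", "alt", "parent"]))
        with pytest.raises(ValueError, match="c1:2"):
            ad.build_parental_genomes(ref, snps)

    def test_hamming_distance_equals_differing_positions(self):
        rng = np.random.default_rng(5)
        ref = {"c1": "".join(rng.choice(list("ACGT"), size=5000))}
        pos = rng.choice(5000, size=1000, replace=False) + 1
        rows = []
        for i, p in enumerate(sorted(pos)):
            base = ref["c1"][p - 1]
            alt = rng.choice([b for b in "ACGT" if b != base])
            rows.append(("c1", int(p), base, alt, "O" if i % 2 else "S"))
        snps = ad.SnpSet(pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "parent"]))
        genomes = ad.build_parental_genomes(ref, snps)
        hamming = sum(a != b for a, b in zip(genomes.o["c1"], genomes.s["c1"]))
        # parents differ exactly where either one deviates from the other
        expected = sum(1 for _, r in snps.table.iterrows())
        assert hamming == expected


class TestAssignReadPair:
    def _pair(self, genome, chrom, s1, s2, n=30, name="p"):
        seq = genome[chrom]
        return ReadPair(name=name, chrom=chrom, start1=s1,
                        seq1=seq[s1:s1 + n], start2=s2, seq2=seq[s2:s2 + n])

    def test_snp_overlapping_pair_assigned(self, tiny_genome_setup):
        _, _, _, genomes = tiny_genome_setup
        pair = self._pair(genomes.o, "c1", 290, 320)  # covers O SNP at 301
        assert ad.assign_read_pair(pair, genomes) == "O"
        pair_s = self._pair(genomes.s, "c1", 290, 320)
        assert ad.assign_read_pair(pair_s, genomes) == "S"

    def test_no_snp_pair_is_ambiguous(self, tiny_genome_setup):
        _, _, _, genomes = tiny_genome_setup
        pair = self._pair(genomes.o, "c1", 400, 440)
        assert ad.assign_read_pair(pair, genomes) == "ambiguous"

    def test_conflicting_snps_tie_to_ambiguous(self):
        ref = {"c1": "A" * 100}
        snps = ad.SnpSet(pd.DataFrame(
            [("c1", 10, "A", "T", "O"), ("c1", 20, "A", "G", "S")],
            columns=["chrom", "pos", "ref", "alt", "parent"]))
        genomes = ad.build_parental_genomes(ref, snps)
        # read carries the O variant at 10 and the S variant at 20
        seq = list("A" * 30)
        seq[9] = "T"
        seq[19] = "G"
        pair = ReadPair(name="x", chrom="c1", start1=0, seq1="".join(seq),
                        start2=40, seq2="A" * 30)
        assert ad.assign_read_pair(pair, genomes) == "ambiguous"

    def test_off_genome_or_garbage_pair_unmapped(self, tiny_genome_setup):
        _, _, _, genomes = tiny_genome_setup
        pair = ReadPair(name="x", chrom="c9", start1=0, seq1="ACGT",
                        start2=10, seq2="ACGT")
        assert ad.assign_read_pair(pair, genomes) == "unmapped"
        junk = ReadPair(name="y", chrom="c1", start1=0, seq1="N" * 50,
                        start2=60, seq2="N" * 50)
        assert ad.assign_read_pair(junk, genomes) == "unmapped"

    def test_zero_length_mate_rejected(self, tiny_genome_setup):
        _, _, _, genomes = tiny_genome_setup
        pair = ReadPair(name="x", chrom="c1", start1=0, seq1="",
                        start2=10, seq2="ACGT")
        with pytest.raises(ValueError):
            ad.assign_read_pair(pair, genomes)

    def test_label_symmetry_under_genome_swap(self, tiny_genome_setup):
        _, _, _, genomes = tiny_genome_setup
        swapped = genomes.swapped()
        rng = np.random.default_rng(2)
        flip = {"O": "S", "S": "O", "ambiguous": "ambiguous",
                "unmapped": "unmapped"}
        for _ in range(100):
            s1 = int(rng.integers(0, 2800))
            hap = genomes.o if rng.random() < 0.5 else genomes.s
            pair = self._pair(hap, "c1", s1, s1 + 45)
            assert ad.assign_read_pair(pair, swapped) == \
                flip[ad.assign_read_pair(pair, genomes)]

    def test_conservation_of_pair_labels(self):
        cfg = ad.SimConfig(n_genes=20, seed=3)
        genomes, _, pairs, _ = ad.simulate_reads(cfg, snp_rate=0.01,
                                                 error_rate=0.002,
                                                 n_pairs=2000)
        labels = collections.Counter(
            ad.assign_read_pair(p, genomes) for p in pairs)
        assert sum(labels.values()) == len(pairs)
        assert set(labels) <= {"O", "S", "ambiguous", "unmapped"}


class TestCountReads:
    def _assigned(self, genomes, chrom, s1, s2, n=30, label="O"):
        seq = genomes.o[chrom]
        pair = ReadPair(name="p", chrom=chrom, start1=s1,
                        seq1=seq[s1:s1 + n], start2=s2, seq2=seq[s2:s2 + n])
        return (pair, label)

    def test_fully_inside_pair_counted(self, tiny_genome_setup):
        _, ann, _, genomes = tiny_genome_setup
        counts = ad.count_reads(
            [self._assigned(genomes, "c1", 2100, 2200, label="O")], ann)
        assert counts.loc["gC", "O"] == 1
        assert counts.to_numpy().sum() == 1

    def test_mate_past_gene_end_not_counted(self, tiny_genome_setup):
        _, ann, _, genomes = tiny_genome_setup
        # gC spans 2000-2900; mate 2 extends past the end
        counts = ad.count_reads(
            [self._assigned(genomes, "c1", 2800, 2880, label="O")], ann)
        assert counts.to_numpy().sum() == 0

    def test_overlap_region_not_counted(self, tiny_genome_setup):
        _, ann, _, genomes = tiny_genome_setup
        # 900-1100 is shared by gA and gB
        counts = ad.count_reads(
            [self._assigned(genomes, "c1", 910, 1000, label="S")], ann)
        assert counts.to_numpy().sum() == 0

    def test_three_prime_restriction_is_strand_aware(self, tiny_genome_setup):
        _, ann, _, genomes = tiny_genome_setup
        # gC is on '-': its 3' end is the interval start (2000..2500)
        inside = self._assigned(genomes, "c1", 2050, 2150, label="O")
        outside = self._assigned(genomes, "c1", 2700, 2800, label="O")
        counts = ad.count_reads([inside, outside], ann, three_prime_only=500)
        assert counts.loc["gC", "O"] == 1

    def test_unknown_chromosome_skipped(self, tiny_genome_setup, caplog):
        _, ann, _, _ = tiny_genome_setup
        pair = ReadPair(name="p", chrom="cX", start1=0, seq1="ACGT",
                        start2=10, seq2="ACGT")
        counts = ad.count_reads([(pair, "O")], ann)
        assert counts.to_numpy().sum() == 0


class TestBiasScreen:
    def test_symmetric_genes_pass_and_snpless_uninformative(
            self, tiny_genome_setup):
        _, ann, _, genomes = tiny_genome_setup
        res = ad.mapping_bias_screen(genomes, ann, n_pairs=200, seed=0)
        assert res.biased == []
        # gB's only non-masked SNP is at 1501; still informative
        assert "gB" not in res.uninformative

    def test_snpless_gene_flagged_uninformative(self):
        rng = np.random.default_rng(4)
        ref = {"c1": "".join(rng.choice(list("ACGT"), size=1500))}
        genes = pd.DataFrame([("g1", "c1", 100, 1400, "+")],
                             columns=["gene_id", "chrom", "start", "end",
                                      "strand"])
        ann = ad.GeneAnnotation(genes=genes)
        empty = ad.SnpSet(pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "parent"]))
        genomes = ad.build_parental_genomes(ref, empty)
        res = ad.mapping_bias_screen(genomes, ann, n_pairs=50, seed=0)
        assert res.uninformative == ["g1"]
        assert res.biased == []

    def test_asymmetric_assigner_is_flagged(self, tiny_genome_setup):
        # emulate an aligner mappability hole: S-haplotype fragments over a
        # window of gA cannot be placed, so gA's counts skew towards O
        _, ann, _, genomes = tiny_genome_setup
        hole = (250, 450)

        def holey(pair, g):
            lo, hi = pair.span
            label = ad.assign_read_pair(pair, g)
            if lo < hole[1] and hi > hole[0] and pair.true_hap == "S":
                return "unmapped" if label in ("S", "ambiguous") else label
            return label

        res = ad.mapping_bias_screen(genomes, ann, n_pairs=300, seed=5,
                                     assign_fn=holey)
        assert "gA" in res.biased
        assert "gC" not in res.biased


class TestGffAndFastqRoundTrips:
    def test_gff_round_trip_preserves_coordinates(self, tmp_path,
                                                  tiny_genome_setup):
        _, ann, _, _ = tiny_genome_setup
        path = tmp_path / "genes.gff3"
        ann.to_gff(path)
        back = ad.GeneAnnotation.from_gff(path)
        pd.testing.assert_frame_equal(
            back.genes.reset_index(drop=True),
            ann.genes.reset_index(drop=True))

    def test_fastq_round_trip_preserves_assignability(self, tmp_path):
        cfg = ad.SimConfig(n_genes=5, seed=3)
        genomes, _, pairs, _ = ad.simulate_reads(cfg, snp_rate=0.01,
                                                 n_pairs=200)
        p1 = tmp_path / "r1.fastq.gz"
        p2 = tmp_path / "r2.fastq.gz"
        seqio.write_fastq_pairs(pairs, p1, p2)
        back = seqio.read_fastq_pairs(p1, p2)
        assert len(back) == len(pairs)
        for a, b in zip(pairs, back):
            assert (a.seq1, a.seq2, a.start1, a.start2, a.true_hap) == \
                (b.seq1, b.seq2, b.start1, b.start2, b.true_hap)

    def test_fasta_round_trip(self, tmp_path, tiny_genome_setup):
        _, _, _, genomes = tiny_genome_setup
        path = tmp_path / "o.fa"
        seqio.write_fasta(genomes.o, path)
        assert seqio.read_fasta(path) == genomes.o
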