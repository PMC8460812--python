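"""Paired-end read simulation, truth alignments, SAM/FASTQ interchange."""

import numpy as np
import pytest
from scipy import stats

from normcov import (
    AlignmentRecord,
    AlignmentSet,
    GenomeModel,
    PopulationModel,
    ReadPairSpec,
    random_replicon,
    read_sam,
    sample_founder,
    simulate_reads,
    write_fastq,
    write_sam,
)


@pytest.fixture
def two_replicon_model():
    a = random_replicon("chrA", 2000, 0.5, seed=21, role="chromosome")
    b = random_replicon("pB", 2000, 0.5, seed=22, role="plasmid")
    genome = GenomeModel([a, b])
    return PopulationModel(genome=genome, plasmid_copy={"pB": 2.0})


class TestSpecValidation:
    def test_read_longer_than_fragment_rejected(self):
        with pytest.raises(ValueError):
            ReadPairSpec(n_pairs=10, read_length=200, fragment_mean=150)

    def test_substitution_rate_bounded(self):
        with pytest.raises(ValueError):
            ReadPairSpec(n_pairs=10, substitution_rate=0.5)

    def test_at_least_one_pair(self):
        with pytest.raises(ValueError):
            ReadPairSpec(n_pairs=0)


class TestSimulateReads:
    def test_read_share_proportional_to_copies_times_length(self, two_replicon_model):
        """Equal lengths, copies 1 vs 2 -> expected share 1/3 vs 2/3."""
        spec = ReadPairSpec(n_pairs=50_000, seed=1, fragment_mean=300, fragment_sd=30)
        aln = simulate_reads(two_replicon_model, spec)
        pairs = {"chrA": 0, "pB": 0}
        for rec in aln.records:
            if rec.mate == 1:
                pairs[rec.replicon] += 1
        chi = stats.chisquare(
            [pairs["chrA"], pairs["pB"]], [50_000 / 3, 2 * 50_000 / 3]
        )
        assert chi.pvalue > 0.001

    def test_ploidy_weight_closed_form(self, small_genome):
        """Plasmid share = L_p / (P * L_chr + L_p) at ploidy P, CN 1."""
        model = PopulationModel(genome=small_genome, ploidy=2.0)
        spec = ReadPairSpec(n_pairs=50_000, seed=2, fragment_mean=300, fragment_sd=30)
        aln = simulate_reads(model, spec)
        share = 1000 / (2 * 5000 + 1000)
        n_plasmid = sum(1 for r in aln.records if r.replicon == "pA" and r.mate == 1)
        chi = stats.chisquare(
            [50_000 - n_plasmid, n_plasmid],
            [50_000 * (1 - share), 50_000 * share],
        )
        assert chi.pvalue > 0.001

    def test_error_free_reads_match_reference(self, small_model, small_genome):
        spec = ReadPairSpec(n_pairs=300, seed=3, fragment_mean=300, fragment_sd=30)
        aln = simulate_reads(small_model, spec)
        for rec in aln.records:
            ref = small_genome[rec.replicon].sequence
            assert rec.sequence == ref[rec.start : rec.start + 151]

    def test_substitutions_change_some_bases(self, small_model, small_genome):
        spec = ReadPairSpec(
            n_pairs=300, seed=3, fragment_mean=300, fragment_sd=30,
            substitution_rate=0.01,
        )
        aln = simulate_reads(small_model, spec)
        mismatches = sum(
            a != b
            for rec in aln.records
            for a, b in zip(
                rec.sequence,
                small_genome[rec.replicon].sequence[rec.start : rec.start + 151],
            )
        )
        total = len(aln.records) * 151
        # binomial(total, 0.01) within 4 sigma
        assert abs(mismatches - 0.01 * total) < 4 * np.sqrt(total * 0.01 * 0.99)

    def test_founder_without_plasmid_gets_no_plasmid_reads(self, small_genome):
        model = PopulationModel(genome=small_genome, carriage={"pA": 0.0})
        founder = sample_founder(model, seed=1)
        assert not founder.presence["pA"]
        spec = ReadPairSpec(n_pairs=500, seed=4, fragment_mean=300, fragment_sd=30)
        aln = simulate_reads(model, spec, founder=founder)
        assert all(rec.replicon == "chr" for rec in aln.records)

    def test_short_replicon_excluded_with_warning(self):
        chrom = random_replicon("chr", 3000, 0.5, seed=31, role="chromosome")
        tiny = random_replicon("tiny", 100, 0.5, seed=32, role="plasmid")
        model = PopulationModel(genome=GenomeModel([chrom, tiny]))
        spec = ReadPairSpec(n_pairs=100, seed=5, fragment_mean=300, fragment_sd=30)
        with pytest.warns(UserWarning, match="tiny"):
            aln = simulate_reads(model, spec)
        assert all(rec.replicon == "chr" for rec in aln.records)

    def test_all_replicons_excluded_is_error(self):
        tiny = random_replicon("t", 100, 0.5, seed=33, role="chromosome")
        model = PopulationModel(genome=GenomeModel([tiny]))
        spec = ReadPairSpec(n_pairs=10, fragment_mean=300, fragment_sd=30)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no replicon"):
                simulate_reads(model, spec)

    def test_mates_stay_within_bounds_and_pair_structure(self, small_model):
        spec = ReadPairSpec(n_pairs=400, seed=6, fragment_mean=300, fragment_sd=30)
        aln = simulate_reads(small_model, spec)
        assert len(aln.records) == 800
        for r1, r2 in zip(aln.records[::2], aln.records[1::2]):
            assert r1.read_id == r2.read_id
            assert (r1.mate, r2.mate) == (1, 2)
            assert {r1.strand, r2.strand} == {"+", "-"}
            for rec in (r1, r2):
                assert 0 <= rec.start
                assert rec.start + 151 <= aln.header[rec.replicon]


class TestSamInterchange:
    def test_empty_alignment_set_gives_header_only_sam(self, tmp_path):
        aln = AlignmentSet(header={"chr": 1000})
        path = tmp_path / "empty.sam"
        write_sam(aln, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("@HD")
        assert lines[1] == "@SQ\tSN:chr\tLN:1000"
        assert len(lines) == 2

    def test_zero_based_start_becomes_pos_one(self, tmp_path):
        rec = AlignmentRecord("r1", "chr", 0, "+", "ACGT", "4M", 1)
        aln = AlignmentSet(header={"chr": 1000}, records=[rec])
        path = tmp_path / "one.sam"
        write_sam(aln, path)
        row = path.read_text().splitlines()[-1].split("\t")
        assert row[3] == "1"

    def test_sam_round_trip(self, small_model, tmp_path):
        spec = ReadPairSpec(n_pairs=150, seed=7, fragment_mean=300, fragment_sd=30)
        aln = simulate_reads(small_model, spec)
        path = tmp_path / "rt.sam"
        write_sam(aln, path)
        back = read_sam(path)
        assert back.header == aln.header
        assert sorted(back.records) == sorted(aln.records)

    def test_fixed_seed_byte_identical_outputs(self, small_model, tmp_path):
        spec = ReadPairSpec(n_pairs=100, seed=8, fragment_mean=300, fragment_sd=30)
        for run in ("a", "b"):
            aln = simulate_reads(small_model, spec)
            write_sam(aln, tmp_path / f"{run}.sam")
            write_fastq(aln, tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq")
        for suffix in (".sam", "_1.fq", "_2.fq"):
            assert (tmp_path / f"a{suffix}").read_bytes() == (
                tmp_path / f"b{suffix}"
            ).read_bytes()

    def test_fastq_reverse_strand_is_reverse_complemented(
        self, small_model, tmp_path
    ):
        spec = ReadPairSpec(n_pairs=5, seed=9, fragment_mean=300, fragment_sd=30)
        aln = simulate_reads(small_model, spec)
        write_fastq(aln, tmp_path / "r1.fq", tmp_path / "r2.fq")
        fq = {}
        for mate, fname in ((1, "r1.fq"), (2, "r2.fq")):
            lines = (tmp_path / fname).read_text().splitlines()
            for i in range(0, len(lines), 4):
                fq[(lines[i][1:].split("/")[0], mate)] = lines[i + 1]
        from normcov.replicons import revcomp

        for rec in aln.records:
            expected = revcomp(rec.sequence) if rec.strand == "-" else rec.sequence
            assert fq[(rec.read_id, rec.mate)] == expected

    def test_out_of_bounds_record_rejected(self):
        rec = AlignmentRecord("r1", "chr", 990, "+", "A" * 20, "20M", 1)
        with pytest.raises(ValueError, match="bounds"):
            AlignmentSet(header={"chr": 1000}, records=[rec])
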