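"""Pileup counting, the 35% consensus screen and two-sample comparison."""

import numpy as np
import pytest

from normcov import (
    AlignmentRecord,
    AlignmentSet,
    GenomeModel,
    PileupColumn,
    PopulationModel,
    ReadPairSpec,
    Replicon,
    build_pileup,
    call_variants,
    compare_samples,
    random_replicon,
    simulate_mixture,
    simulate_reads,
    write_vcf,
)


def _column(ref="A", alt="C", ref_n=6, alt_n=4, pos=10, depth=None):
    counts = {b: 0 for b in "ACGT"}
    counts[ref] = ref_n
    counts[alt] = alt_n
    return PileupColumn(
        replicon="chr",
        pos=pos,
        ref_base=ref,
        counts=counts,
        depth=depth if depth is not None else ref_n + alt_n,
    )


def _single_base_reads(bases, pos=10, length=100):
    """One 1 bp read per base, all stacked at one position."""
    records = [
        AlignmentRecord(f"r{i}", "chr", pos, "+", b, "1M", 1)
        for i, b in enumerate(bases)
    ]
    return AlignmentSet(header={"chr": length}, records=records)


@pytest.fixture
def ref_genome():
    seq = "A" * 100
    return GenomeModel([Replicon.from_sequence("chr", seq, role="chromosome")])


class TestBuildPileup:
    def test_direct_count_of_mixed_column(self, ref_genome):
        aln = _single_base_reads("A" * 6 + "C" * 4)
        cols = list(build_pileup(aln, ref_genome))
        assert len(cols) == 1
        col = cols[0]
        assert col.pos == 10
        assert col.counts == {"A": 6, "C": 4, "G": 0, "T": 0}
        assert col.depth == 10

    def test_uncovered_positions_absent(self, ref_genome):
        aln = _single_base_reads("AAAA", pos=50)
        cols = list(build_pileup(aln, ref_genome))
        assert [c.pos for c in cols] == [50]

    def test_n_bases_skipped(self, ref_genome):
        aln = _single_base_reads("AANN")
        col = next(build_pileup(aln, ref_genome))
        assert col.depth == 2

    def test_brute_force_tally_oracle(self, small_genome, small_model):
        """Pileup counts equal a per-position dictionary tally of every read."""
        spec = ReadPairSpec(n_pairs=300, seed=23, fragment_mean=300, fragment_sd=30)
        aln = simulate_reads(small_model, spec)
        naive: dict = {}
        for rec in aln.records:
            for offset, base in enumerate(rec.sequence):
                if base == "N":
                    continue
                key = (rec.replicon, rec.start + offset)
                naive.setdefault(key, {b: 0 for b in "ACGT"})[base] += 1
        cols = {
            (c.replicon, c.pos): c.counts for c in build_pileup(aln, small_genome)
        }
        assert cols == naive

    def test_cigar_sequence_mismatch_rejected(self, ref_genome):
        rec = AlignmentRecord("r", "chr", 0, "+", "ACGT", "5M", 1)
        aln = AlignmentSet.__new__(AlignmentSet)
        aln.header = {"chr": 100}
        aln.records = [rec]
        with pytest.raises(ValueError, match="inconsistent"):
            list(build_pileup(aln, ref_genome))

    def test_indels_tallied_but_bases_counted_from_match_segments(self, ref_genome):
        rec = AlignmentRecord("r", "chr", 0, "+", "CCCCC", "2M1I2M", 1)
        aln = AlignmentSet(header={"chr": 100}, records=[rec])
        cols = list(build_pileup(aln, ref_genome))
        assert [c.pos for c in cols] == [0, 1, 2, 3]
        assert cols[2].indels == 1  # insertion opens at reference position 2


class TestCallVariants:
    def test_forty_percent_called(self):
        calls = call_variants([_column(ref_n=6, alt_n=4)])
        assert len(calls) == 1
        assert calls[0].alt_base == "C"
        assert calls[0].alt_fraction == pytest.approx(0.4)

    def test_thirty_percent_not_called(self):
        assert call_variants([_column(ref_n=7, alt_n=3)]) == []

    def test_exact_boundary_inclusive(self):
        """A site at exactly 35% alternate fraction is called."""
        calls = call_variants([_column(ref_n=13, alt_n=7)])
        assert len(calls) == 1
        assert calls[0].alt_fraction == pytest.approx(0.35)

    def test_min_depth_filter(self):
        assert call_variants([_column(ref_n=3, alt_n=2)], min_depth=10) == []

    def test_two_alternate_alleles_called_independently(self):
        counts = {"A": 4, "C": 3, "G": 3, "T": 0}
        col = PileupColumn("chr", 5, "A", counts, 10)
        calls = call_variants([col], threshold=0.3)
        assert {c.alt_base for c in calls} == {"C", "G"}

    def test_threshold_monotonicity_on_simulated_mixture(self):
        rep = random_replicon("chr", 4000, 0.6, seed=51, role="chromosome")
        sites = {
            int(p): ("A" if rep.sequence[int(p)] != "A" else "C")
            for p in np.linspace(100, 3900, 20)
        }
        spec = ReadPairSpec(n_pairs=8000, seed=52, fragment_mean=300, fragment_sd=30)
        aln = simulate_mixture(rep, sites, 0.4, spec)
        genome = GenomeModel([rep])
        loose = {
            (c.pos, c.alt_base)
            for c in call_variants(build_pileup(aln, genome), threshold=0.35)
        }
        strict = {
            (c.pos, c.alt_base)
            for c in call_variants(build_pileup(aln, genome), threshold=0.5)
        }
        assert strict <= loose


class TestMixtureRecovery:
    def test_sixty_forty_mixture_all_sites_recovered(self):
        """30 engineered SNVs at 60/40 mixture, deep coverage: all called at
        the 35% cutoff, no false calls in error-free reads."""
        rep = random_replicon("chr", 5000, 0.6, seed=61, role="chromosome")
        sites = {
            int(p): ("A" if rep.sequence[int(p)] != "A" else "C")
            for p in np.linspace(200, 4800, 30).astype(int)
        }
        spec = ReadPairSpec(n_pairs=33_000, seed=62, fragment_mean=300, fragment_sd=30)
        aln = simulate_mixture(rep, sites, 0.4, spec)
        genome = GenomeModel([rep])
        cols = list(build_pileup(aln, genome))
        assert min(c.depth for c in cols if c.pos in sites) >= 50
        calls = call_variants(cols, threshold=0.35, min_depth=10)
        called = {(c.pos, c.alt_base) for c in calls}
        assert called == set(sites.items())


class TestCompareSamples:
    def _setup(self, fa, fb, depth=100):
        alt_a = round(fa * depth)
        alt_b = round(fb * depth)
        col_a = _column(ref_n=depth - alt_a, alt_n=alt_a)
        col_b = _column(ref_n=depth - alt_b, alt_n=alt_b)
        calls_a = call_variants([col_a], sample="a")
        calls_b = call_variants([col_b], sample="b")
        return compare_samples(calls_a, calls_b, [col_a], [col_b])

    def test_fixed_difference(self):
        df = self._setup(1.0, 0.0)
        assert list(df["class"]) == ["fixed_difference"]

    def test_shared_heterogeneity(self):
        df = self._setup(0.40, 0.45)
        assert list(df["class"]) == ["shared_heterogeneity"]

    def test_private_heterogeneity(self):
        df = self._setup(0.40, 0.0)
        assert list(df["class"]) == ["private_heterogeneity"]

    def test_ambiguous_intermediate_fraction(self):
        df = self._setup(0.40, 0.20)
        assert list(df["class"]) == ["ambiguous"]

    def test_site_absent_from_other_pileup_has_zero_fraction(self):
        col_a = _column(ref_n=0, alt_n=100)
        calls_a = call_variants([col_a], sample="a")
        df = compare_samples(calls_a, [], [col_a], [])
        assert list(df["class"]) == ["fixed_difference"]
        assert df.loc[0, "alt_fraction_b"] == 0.0


def test_vcf_output_is_one_based(tmp_path, ref_genome):
    calls = call_variants([_column(ref_n=6, alt_n=4, pos=10)])
    path = tmp_path / "calls.vcf"
    write_vcf(calls, ref_genome, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "##fileformat=VCFv4.2"
    body = [l for l in lines if not l.startswith("#")]
    chrom, pos, _, ref, alt, _, _, info = body[0].split("\t")
    assert (chrom, pos, ref, alt) == ("chr", "11", "A", "C")
    assert "AF=0.4000" in info and "DP=10" in info
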