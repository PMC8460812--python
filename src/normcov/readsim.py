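"""Paired-end read simulation with truth alignments.

Emulates an Illumina library (2 × 151 bp by default) drawn from a cell
population: each fragment picks a replicon with probability proportional to
``effective copies × length``, a start uniform along the replicon, and a
normally distributed fragment length truncated to [read length, replicon
length].  Fragments never wrap the circular origin — a simplification that
biases coverage only in the terminal window at desk scale.

The simulator records the true placement of every mate (an
:class:`AlignmentSet`), standing in for an external mapping step; the pipeline
downstream consumes these truth alignments, or any externally produced SAM in
the minimal dialect (M/=/X CIGAR operations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
import pysam

from .population import ColonyFounder, PopulationModel
from .replicons import GenomeModel, Replicon, revcomp

__all__ = [
    "ReadPairSpec",
    "AlignmentRecord",
    "AlignmentSet",
    "simulate_reads",
    "simulate_mixture",
    "write_sam",
    "read_sam",
    "write_fastq",
]


@dataclass(frozen=True)
class ReadPairSpec:
    """Parameters of a simulated paired-end library."""

    n_pairs: int
    read_length: int = 151
    fragment_mean: int = 400
    fragment_sd: int = 40
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        if not 0.0 <= self.substitution_rate <= 0.1:
            raise ValueError("substitution_rate must be in [0, 0.1]")


class AlignmentRecord(NamedTuple):
    """One aligned mate with its true reference placement.

    ``start`` is 0-based; ``sequence`` is reference-oriented (as stored in
    SAM), so a reverse-strand mate's FASTQ sequence is its reverse complement.
    """

    read_id: str
    replicon: str
    start: int
    strand: str  # '+' or '-'
    sequence: str
    cigar: str
    mate: int  # 1 or 2


@dataclass
class AlignmentSet:
    """Read placements on replicons: the substrate for coverage and pileup."""

    header: dict[str, int]  # replicon name -> length
    records: list[AlignmentRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            self._check(rec)

    def _check(self, rec: AlignmentRecord) -> None:
        if rec.replicon not in self.header:
            raise ValueError(f"record on unknown replicon {rec.replicon!r}")
        if rec.start < 0 or rec.start + len(rec.sequence) > self.header[rec.replicon]:
            raise ValueError(
                f"record {rec.read_id}/{rec.mate} outside replicon bounds"
            )

    def __len__(self) -> int:
        return len(self.records)

    def by_replicon(self) -> dict[str, list[AlignmentRecord]]:
        out: dict[str, list[AlignmentRecord]] = {name: [] for name in self.header}
        for rec in self.records:
            out[rec.replicon].append(rec)
        return out


_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def _effective_copies(
    model: PopulationModel, founder: Optional[ColonyFounder], name: str
) -> float:
    rep = model.genome[name]
    if rep.role == "chromosome":
        return model.ploidy
    if founder is not None:
        return (1.0 if founder.presence[name] else 0.0) * model.plasmid_copy[name]
    return model.carriage[name] * model.plasmid_copy[name]


def simulate_reads(
    model: PopulationModel,
    spec: ReadPairSpec,
    founder: Optional[ColonyFounder] = None,
) -> AlignmentSet:
    """Simulate ``spec.n_pairs`` read pairs from a population (or one founder).

    Replicon r is drawn per fragment (i.i.d.) with probability proportional to
    ``effective_copies(r) × length(r)``, where effective copies are the ploidy
    for the chromosome and carriage × copy number for plasmids (presence ×
    copy number when a colony founder is supplied).  Substitution errors are
    applied after placement, so the recorded coordinates stay the truth.

    Returns an :class:`AlignmentSet`; use :func:`write_fastq` /
    :func:`write_sam` to materialize files.  Fixed spec (including seed) gives
    byte-identical outputs.
    """
    genome = model.genome
    rng = np.random.default_rng(spec.seed)

    eligible: list[Replicon] = []
    weights: list[float] = []
    for rep in genome:
        w = _effective_copies(model, founder, rep.name) * rep.length_bp
        if w <= 0:
            continue
        if not rep.has_sequence:
            raise ValueError(f"replicon {rep.name} has no sequence")
        if rep.length_bp < spec.read_length:
            warnings.warn(
                f"replicon {rep.name} ({rep.length_bp} bp) shorter than the "
                f"read length; excluded from simulation"
            )
            continue
        eligible.append(rep)
        weights.append(w)
    if not eligible:
        raise ValueError("no replicon is eligible for read simulation")

    probs = np.asarray(weights) / float(np.sum(weights))
    lengths = np.array([r.length_bp for r in eligible], dtype=np.int64)

    idx = rng.choice(len(eligible), size=spec.n_pairs, p=probs)
    frag = np.rint(rng.normal(spec.fragment_mean, spec.fragment_sd, spec.n_pairs))
    frag = np.clip(frag, spec.read_length, lengths[idx]).astype(np.int64)
    starts = np.floor(rng.random(spec.n_pairs) * (lengths[idx] - frag + 1)).astype(
        np.int64
    )
    # orientation of the pair: which mate is the leftmost, forward read
    r1_forward = rng.random(spec.n_pairs) < 0.5

    rl = spec.read_length
    records: list[AlignmentRecord] = []
    seqs = [r.sequence for r in eligible]
    names = [r.name for r in eligible]
    for i in range(spec.n_pairs):
        j = int(idx[i])
        s = int(starts[i])
        f = int(frag[i])
        left = seqs[j][s : s + rl]
        right = seqs[j][s + f - rl : s + f]
        if spec.substitution_rate > 0:
            left = _mutate(left, spec.substitution_rate, rng)
            right = _mutate(right, spec.substitution_rate, rng)
        rid = f"sim{i:07d}"
        rec_left = AlignmentRecord(rid, names[j], s, "+", left, f"{rl}M", 0)
        rec_right = AlignmentRecord(rid, names[j], s + f - rl, "-", right, f"{rl}M", 0)
        if r1_forward[i]:
            records.append(rec_left._replace(mate=1))
            records.append(rec_right._replace(mate=2))
        else:
            records.append(rec_right._replace(mate=1))
            records.append(rec_left._replace(mate=2))

    aln = AlignmentSet.__new__(AlignmentSet)  # skip per-record re-validation
    aln.header = {r.name: r.length_bp for r in genome}
    aln.records = records
    return aln


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    for pos in hits:
        choices = _ALPHABET[_ALPHABET != arr[pos]]
        arr[pos] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode("ascii")


def simulate_mixture(
    replicon: Replicon,
    alt_sites: dict[int, str],
    alt_fraction: float,
    spec: ReadPairSpec,
) -> AlignmentSet:
    """Simulate reads from a two-haplotype mixture on one replicon.

    A variant haplotype carrying ``alt_sites`` (0-based position → alternate
    base) contributes ``alt_fraction`` of the cells; the reference haplotype
    the rest.  Both haplotypes share coordinates, so truth alignments of
    variant reads are valid against the reference — the generative model for
    within-culture heterogeneity at engineered SNV sites.
    """
    if not 0.0 <= alt_fraction <= 1.0:
        raise ValueError("alt_fraction must be in [0, 1]")
    var_seq = list(replicon.sequence)
    for pos, alt in alt_sites.items():
        if var_seq[pos] == alt:
            raise ValueError(f"alt base equals reference at position {pos}")
        var_seq[pos] = alt
    variant = Replicon.from_sequence(replicon.name, "".join(var_seq), role="chromosome")
    reference = Replicon.from_sequence(replicon.name, replicon.sequence, role="chromosome")

    rng = np.random.default_rng(spec.seed)
    n_alt = int(rng.binomial(spec.n_pairs, alt_fraction))
    records: list[AlignmentRecord] = []
    for tag, rep, n in (("ref", reference, spec.n_pairs - n_alt), ("alt", variant, n_alt)):
        if n == 0:
            continue
        model = PopulationModel(genome=GenomeModel([rep]))
        sub = replace(spec, n_pairs=n, seed=int(rng.integers(2**31 - 1)))
        part = simulate_reads(model, sub)
        records.extend(
            rec._replace(read_id=f"{tag}:{rec.read_id}") for rec in part.records
        )
    return AlignmentSet(header={replicon.name: replicon.length_bp}, records=records)


# ---------------------------------------------------------------------------
# SAM / FASTQ interchange
# ---------------------------------------------------------------------------

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80


def write_sam(alignments: AlignmentSet, path) -> None:
    """Write a minimal SAM v1.6 file: @HD, @SQ per replicon, <n>M records.

    POS is 1-based per SAM convention; SEQ is reference-oriented; qualities are
    constant 'I' (Q40) since the pipeline does not use them.
    """
    pairs: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    for rec in alignments.records:
        if rec.read_id not in pairs:
            order.append(rec.read_id)
            pairs[rec.read_id] = []
        pairs[rec.read_id].append(rec)

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in alignments.header.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rid in order:
            group = sorted(pairs[rid], key=lambda r: r.mate)
            for rec in group:
                mate = next((m for m in group if m is not rec), None)
                flag = 0
                pnext, tlen = 0, 0
                rnext = "*"
                if mate is not None:
                    flag |= _FLAG_PAIRED | _FLAG_PROPER
                    flag |= _FLAG_READ1 if rec.mate == 1 else _FLAG_READ2
                    if mate.strand == "-":
                        flag |= _FLAG_MATE_REVERSE
                    rnext = "="
                    pnext = mate.start + 1
                    lo = min(rec.start, mate.start)
                    hi = max(rec.start + len(rec.sequence), mate.start + len(mate.sequence))
                    tlen = (hi - lo) if rec.start <= mate.start else -(hi - lo)
                if rec.strand == "-":
                    flag |= _FLAG_REVERSE
                fh.write(
                    "\t".join(
                        [
                            rec.read_id,
                            str(flag),
                            rec.replicon,
                            str(rec.start + 1),
                            "60",
                            rec.cigar,
                            rnext,
                            str(pnext),
                            str(tlen),
                            rec.sequence,
                            "I" * len(rec.sequence),
                        ]
                    )
                    + "\n"
                )


def read_sam(path) -> AlignmentSet:
    """Read a SAM file (any dialect pysam accepts) into an AlignmentSet.

    Unmapped records are skipped; the caller sees reference-oriented sequences
    and 0-based starts, mirroring :func:`write_sam`.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        header = {
            name: length
            for name, length in zip(sam.references, sam.lengths)
        }
        for seg in sam.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            mate = 2 if seg.is_read2 else 1
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    replicon=seg.reference_name,
                    start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    sequence=seg.query_sequence,
                    cigar=seg.cigarstring,
                    mate=mate,
                )
            )
    return AlignmentSet(header=header, records=records)


def write_fastq(alignments: AlignmentSet, path_r1, path_r2) -> None:
    """Write paired FASTQ files (/1 and /2 read-name suffixes).

    Reverse-strand mates are reverse-complemented back to sequencing
    orientation.
    """
    with open(path_r1, "w") as fh1, open(path_r2, "w") as fh2:
        for rec in alignments.records:
            seq = revcomp(rec.sequence) if rec.strand == "-" else rec.sequence
            fh = fh1 if rec.mate == 1 else fh2
            fh.write(f"@{rec.read_id}/{rec.mate}\n{seq}\n+\n{'I' * len(seq)}\n")
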