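"""Multi-replicon genome model, GC/GC-skew tracks and the MSH1 replicon registry.

A *replicon* is an independently replicating DNA element — the chromosome or a
plasmid.  Genomes here are ordered collections of replicons with exactly one
chromosome.  Coordinates are 0-based, half-open throughout the package; circular
topology is recorded but windows never wrap the origin, matching the window
semantics of standard depth tools (``samtools``/``bedtools``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Replicon",
    "GenomeModel",
    "GCSkewTrack",
    "load_fasta",
    "write_fasta",
    "msh1_registry",
    "random_replicon",
    "gc_skew_track",
    "gc_fraction",
    "validate_registry",
    "revcomp",
]

_VALID = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _base_counts(seq: str) -> np.ndarray:
    """Counts of A,C,G,T,N (in that order) from an ASCII DNA string."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    counts = np.bincount(arr, minlength=256)
    return np.array(
        [counts[ord(b)] for b in "ACGTN"], dtype=np.int64
    )


def gc_fraction(seq: str) -> float:
    """GC fraction of a sequence; N bases excluded from numerator and denominator.

    Returns 0.0 for a sequence with no A/C/G/T bases.
    """
    a, c, g, t, _n = _base_counts(seq)
    denom = a + c + g + t
    return float((g + c) / denom) if denom else 0.0


@dataclass
class Replicon:
    """A named circular (or linear) DNA sequence with a role in the genome.

    Registry entries may be sequence-free (``sequence=None``); they still carry
    the printed length and GC so that analyses that only need sizes (e.g.
    expected read shares) can run without the actual accession FASTA.
    """

    name: str
    role: str  # "chromosome" | "plasmid"
    length_bp: int
    sequence: Optional[str] = None
    gc_percent: Optional[float] = None
    topology: str = "circular"

    def __post_init__(self) -> None:
        if self.role not in ("chromosome", "plasmid"):
            raise ValueError(f"unknown replicon role {self.role!r}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.length_bp < 1:
            raise ValueError("length_bp must be positive")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - _VALID
            if bad:
                raise ValueError(
                    f"replicon {self.name}: invalid characters {sorted(bad)}"
                )
            if len(self.sequence) != self.length_bp:
                raise ValueError(
                    f"replicon {self.name}: length_bp={self.length_bp} but "
                    f"sequence has {len(self.sequence)} bp"
                )
            if self.gc_percent is None:
                self.gc_percent = 100.0 * gc_fraction(self.sequence)
        if self.gc_percent is not None and not 0.0 <= self.gc_percent <= 100.0:
            raise ValueError("gc_percent must be within [0, 100]")

    @classmethod
    def from_sequence(
        cls, name: str, sequence: str, role: str = "plasmid", topology: str = "circular"
    ) -> "Replicon":
        return cls(
            name=name,
            role=role,
            length_bp=len(sequence),
            sequence=sequence,
            topology=topology,
        )

    @property
    def has_sequence(self) -> bool:
        return self.sequence is not None


@dataclass
class GenomeModel:
    """An ordered collection of replicons with exactly one chromosome."""

    replicons: list[Replicon]

    def __post_init__(self) -> None:
        names = [r.name for r in self.replicons]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate replicon names: {dupes}")
        n_chrom = sum(r.role == "chromosome" for r in self.replicons)
        if n_chrom != 1:
            raise ValueError(f"genome must have exactly one chromosome, got {n_chrom}")

    def __iter__(self) -> Iterator[Replicon]:
        return iter(self.replicons)

    def __len__(self) -> int:
        return len(self.replicons)

    def __getitem__(self, name: str) -> Replicon:
        for r in self.replicons:
            if r.name == name:
                return r
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.replicons)

    @property
    def chromosome(self) -> Replicon:
        return next(r for r in self.replicons if r.role == "chromosome")

    @property
    def plasmids(self) -> list[Replicon]:
        return [r for r in self.replicons if r.role == "plasmid"]

    @property
    def total_length(self) -> int:
        return sum(r.length_bp for r in self.replicons)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.replicons]


@dataclass
class GCSkewTrack:
    """Windowed GC content and GC skew for one replicon.

    ``values`` has columns ``start``, ``end``, ``gc_fraction``,
    ``skew`` where skew = (G − C)/(G + C), 0 when a window has no G or C.
    Windows are 0-based half-open and tile the replicon; the last window may be
    partial.
    """

    replicon: str
    window_bp: int
    values: pd.DataFrame = field(repr=False)

    def to_tsv(self, path: str) -> None:
        df = self.values.copy()
        df.insert(0, "replicon", self.replicon)
        df.to_csv(path, sep="\t", index=False)


def load_fasta(path, chromosome_name: Optional[str] = None) -> GenomeModel:
    """Read a multi-record FASTA into a :class:`GenomeModel`.

    The chromosome is the record named ``chromosome_name`` if given, else the
    longest record.  Record IDs must be unique; sequences may contain N but no
    other ambiguity codes.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    names = [rec.id for rec in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate FASTA record names: {dupes}")
    if chromosome_name is None:
        chromosome_name = max(records, key=lambda rec: len(rec.seq)).id
    elif chromosome_name not in names:
        raise ValueError(f"chromosome record {chromosome_name!r} not in FASTA")
    replicons = [
        Replicon.from_sequence(
            rec.id,
            str(rec.seq),
            role="chromosome" if rec.id == chromosome_name else "plasmid",
        )
        for rec in records
    ]
    return GenomeModel(replicons)


def write_fasta(genome: GenomeModel, path) -> None:
    """Write all sequenced replicons as 70-column wrapped FASTA."""
    records = []
    for r in genome:
        if not r.has_sequence:
            raise ValueError(f"replicon {r.name} has no sequence")
        records.append(SeqRecord(Seq(r.sequence), id=r.name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)


# Aminobacter sp. MSH1 substrain DK1: one chromosome and seven plasmids.
# Lengths in bp; GC in percent as deposited with the accessions.
_MSH1_REGISTRY = [
    ("chromosome", "chromosome", 5_301_518, 63.2),
    ("pBAM1", "plasmid", 40_559, 64.4),
    ("pBAM2", "plasmid", 53_893, 56.0),
    ("pUSP1", "plasmid", 367_423, 63.1),
    ("pUSP2", "plasmid", 365_485, 60.1),
    ("pUSP3", "plasmid", 97_029, 60.5),
    ("pUSP4", "plasmid", 64_122, 61.9),
    ("pUSP5", "plasmid", 31_577, 62.9),
]


def msh1_registry() -> GenomeModel:
    """The sequence-free MSH1 DK1 replicon registry.

    Eight circular replicons: a 5.30 Mb chromosome, the catabolic plasmids
    pBAM1/pBAM2, the repABC megaplasmids pUSP1/pUSP2 and the smaller
    pUSP3–pUSP5, totalling 6,321,606 bp.  Lengths and GC are the published
    values; sequences are absent (use :func:`random_replicon` to attach
    synthetic sequences, or supply the accession FASTA files and cross-check
    with :func:`validate_registry`).
    """
    return GenomeModel(
        [
            Replicon(name=n, role=role, length_bp=length, gc_percent=gc)
            for n, role, length, gc in _MSH1_REGISTRY
        ]
    )


def random_replicon(
    name: str,
    length_bp: int,
    gc_target: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    role: str = "plasmid",
) -> Replicon:
    """Random replicon with i.i.d. bases at a target GC.

    P(G) = P(C) = gc_target/2 and P(A) = P(T) = (1 − gc_target)/2 per base,
    independently; reproducible for a fixed seed (or caller-supplied ``rng``).
    """
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must be within [0, 1]")
    if length_bp < 1:
        raise ValueError("length_bp must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = [
        (1.0 - gc_target) / 2,
        gc_target / 2,
        gc_target / 2,
        (1.0 - gc_target) / 2,
    ]
    codes = rng.choice(4, size=length_bp, p=probs)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = alphabet[codes].tobytes().decode("ascii")
    return Replicon.from_sequence(name, seq, role=role)


def _window_bounds(length: int, window_bp: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, window_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, length)
    return starts, ends


def gc_skew_track(replicon: Replicon, window_bp: int) -> GCSkewTrack:
    """Windowed GC fraction and GC skew (G − C)/(G + C) for a replicon.

    GC-skew sign changes along a bacterial replicon are associated with the
    replication origin and terminus; the track is emitted as data (BED-like
    TSV), not as a figure.  N bases count toward window width but are excluded
    from both the GC numerator and denominator.
    """
    if replicon.sequence is None:
        raise ValueError(f"replicon {replicon.name} has no sequence")
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    arr = np.frombuffer(replicon.sequence.encode("ascii"), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    is_acgt = (arr != ord("N")).astype(np.int64)
    starts, ends = _window_bounds(len(arr), window_bp)
    g = np.add.reduceat(is_g, starts)
    c = np.add.reduceat(is_c, starts)
    acgt = np.add.reduceat(is_acgt, starts)
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(acgt > 0, (g + c) / np.maximum(acgt, 1), 0.0)
        skew = np.where(g + c > 0, (g - c) / np.maximum(g + c, 1), 0.0)
    df = pd.DataFrame(
        {"start": starts, "end": ends, "gc_fraction": gc, "skew": skew}
    )
    return GCSkewTrack(replicon=replicon.name, window_bp=window_bp, values=df)


def validate_registry(
    genome: GenomeModel, registry: Optional[GenomeModel] = None, gc_tol: float = 0.05
) -> pd.DataFrame:
    """Cross-check computed lengths/GC of a sequenced genome against a registry.

    Matches replicons by name; returns one row per shared name with the
    registry (printed) and computed values and boolean ``length_ok`` /
    ``gc_ok`` columns (GC compared to ``gc_tol`` percentage points).
    """
    if registry is None:
        registry = msh1_registry()
    rows = []
    for reg in registry:
        if reg.name not in genome:
            continue
        rep = genome[reg.name]
        gc_obs = (
            100.0 * gc_fraction(rep.sequence) if rep.has_sequence else rep.gc_percent
        )
        rows.append(
            {
                "replicon": reg.name,
                "length_registry": reg.length_bp,
                "length_observed": rep.length_bp,
                "length_ok": reg.length_bp == rep.length_bp,
                "gc_registry": reg.gc_percent,
                "gc_observed": None if gc_obs is None else round(gc_obs, 3),
                "gc_ok": gc_obs is not None
                and reg.gc_percent is not None
                and abs(gc_obs - reg.gc_percent) <= gc_tol,
            }
        )
    return pd.DataFrame(rows)
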