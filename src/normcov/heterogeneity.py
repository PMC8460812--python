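"""Within-culture sequence heterogeneity: pileup, variant screen, comparison.

Re-implements the substrain-comparison screen: per-position allele counts from
read alignments, a variant call when the alternate-allele fraction reaches the
consensus cutoff τ (default 0.35, boundary inclusive), and a two-sample
classification separating *fixed differences* between cultures from *shared*
or *private* heterogeneity within them.

Indel alleles are out of the caller's scope (the simulator produces none):
I/D CIGAR operations are tallied per site and reported, but only substitution
alleles are ever called.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .readsim import AlignmentSet
from .replicons import GenomeModel

__all__ = [
    "PileupColumn",
    "VariantCall",
    "build_pileup",
    "call_variants",
    "compare_samples",
    "write_vcf",
    "calls_to_frame",
]

_BASES = "ACGT"
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class PileupColumn:
    """Base counts at one covered reference position (N bases excluded).

    ``indels`` tallies reads whose CIGAR opens an insertion or deletion at
    this position; the tally is reported but indel alleles are never called.
    """

    replicon: str
    pos: int  # 0-based
    ref_base: str
    counts: dict[str, int]
    depth: int
    indels: int = 0


@dataclass(frozen=True)
class VariantCall:
    """A substitution allele at or above the consensus cutoff."""

    replicon: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    alt_fraction: float
    depth: int
    sample: str = ""


def _count_matrix(records, length: int) -> tuple[np.ndarray, np.ndarray]:
    """(L, 4) base-count matrix plus per-position indel tally for one replicon.

    M/=/X segments contribute base counts; I/D operations only bump the indel
    tally at the position where they open.  Other operations are rejected.
    """
    counts = np.zeros((length, 4), dtype=np.int64)
    indels = np.zeros(length, dtype=np.int64)
    for rec in records:
        arr = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        ops = _CIGAR_RE.findall(rec.cigar)
        if sum(len(n) + 1 for n, _ in ops) != len(rec.cigar):
            raise ValueError(f"malformed CIGAR {rec.cigar!r}")
        consumed = sum(int(n) for n, op in ops if op in "MI=X")
        if consumed != len(arr):
            raise ValueError(
                f"record {rec.read_id}/{rec.mate}: sequence length "
                f"{len(arr)} inconsistent with CIGAR {rec.cigar}"
            )
        ref_pos = rec.start
        read_pos = 0
        for n_str, op in ops:
            n = int(n_str)
            if op in "M=X":
                seg = arr[read_pos : read_pos + n]
                positions = np.arange(ref_pos, ref_pos + n)
                for i, base in enumerate(_BASES):
                    mask = seg == ord(base)
                    if mask.any():
                        np.add.at(counts[:, i], positions[mask], 1)
                ref_pos += n
                read_pos += n
            elif op == "I":
                if ref_pos < length:
                    indels[ref_pos] += 1
                read_pos += n
            elif op == "D":
                if ref_pos < length:
                    indels[ref_pos] += 1
                ref_pos += n
            else:
                raise ValueError(
                    f"unsupported CIGAR operation {op!r} in {rec.cigar!r}"
                )
    return counts, indels


def build_pileup(
    alignments: AlignmentSet, genome: GenomeModel
) -> Iterator[PileupColumn]:
    """Stream pileup columns for every covered position, in coordinate order.

    Only M/=/X-aligned bases contribute; N bases in reads are skipped.
    Positions with no coverage are absent from the stream.
    """
    by_rep = alignments.by_replicon()
    for name in alignments.header:
        if name not in genome:
            raise ValueError(f"alignment replicon {name!r} not in genome")
        rep = genome[name]
        if not rep.has_sequence:
            raise ValueError(f"replicon {name} has no sequence")
        records = by_rep[name]
        if not records:
            continue
        counts, indels = _count_matrix(records, rep.length_bp)
        depth = counts.sum(axis=1)
        for pos in np.nonzero(depth)[0]:
            yield PileupColumn(
                replicon=name,
                pos=int(pos),
                ref_base=rep.sequence[pos],
                counts={b: int(counts[pos, i]) for i, b in enumerate(_BASES)},
                depth=int(depth[pos]),
                indels=int(indels[pos]),
            )


def call_variants(
    pileup: Iterable[PileupColumn],
    threshold: float = 0.35,
    min_depth: int = 10,
    sample: str = "",
) -> list[VariantCall]:
    """Call substitution alleles at alternate fraction >= threshold.

    The cutoff is the alternate-allele fraction (count of the non-reference
    base over total A/C/G/T depth), with an inclusive boundary: a site at
    exactly the threshold is called.  Multiple alternate bases at one site are
    evaluated independently and can each be called.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    calls: list[VariantCall] = []
    for col in pileup:
        if col.depth < min_depth:
            continue
        for base in _BASES:
            if base == col.ref_base:
                continue
            frac = col.counts[base] / col.depth
            if frac >= threshold:
                calls.append(
                    VariantCall(
                        replicon=col.replicon,
                        pos=col.pos,
                        ref_base=col.ref_base,
                        alt_base=base,
                        alt_fraction=frac,
                        depth=col.depth,
                        sample=sample,
                    )
                )
    return calls


def _alt_fraction(
    pileup_index: dict[tuple[str, int], PileupColumn], replicon: str, pos: int, alt: str
) -> tuple[float, int]:
    col = pileup_index.get((replicon, pos))
    if col is None or col.depth == 0:
        return 0.0, 0
    return col.counts[alt] / col.depth, col.depth


def compare_samples(
    calls_a: list[VariantCall],
    calls_b: list[VariantCall],
    pileup_a: Iterable[PileupColumn],
    pileup_b: Iterable[PileupColumn],
    threshold: float = 0.35,
    fixed_high: float = 0.95,
    fixed_low: float = 0.05,
) -> pd.DataFrame:
    """Classify the union of called sites across two samples.

    Decision table on the two alternate fractions (f_A, f_B):

    * ``fixed_difference``     — one >= 0.95 and the other <= 0.05;
    * ``shared_heterogeneity`` — both in [τ, 0.95);
    * ``private_heterogeneity``— exactly one in [τ, 0.95), the other <= 0.05;
    * ``ambiguous``            — anything else (e.g. one in (0.05, τ)).

    Shared heterogeneity at many sites indicates the cultures were already
    genetically heterogeneous before they diverged, rather than having
    accumulated fixed differences.
    """
    idx_a = {(c.replicon, c.pos): c for c in pileup_a}
    idx_b = {(c.replicon, c.pos): c for c in pileup_b}
    sites = sorted(
        {(c.replicon, c.pos, c.ref_base, c.alt_base) for c in calls_a}
        | {(c.replicon, c.pos, c.ref_base, c.alt_base) for c in calls_b}
    )
    rows = []
    for replicon, pos, ref, alt in sites:
        fa, da = _alt_fraction(idx_a, replicon, pos, alt)
        fb, db = _alt_fraction(idx_b, replicon, pos, alt)
        het_a = threshold <= fa < fixed_high
        het_b = threshold <= fb < fixed_high
        if (fa >= fixed_high and fb <= fixed_low) or (
            fb >= fixed_high and fa <= fixed_low
        ):
            klass = "fixed_difference"
        elif het_a and het_b:
            klass = "shared_heterogeneity"
        elif (het_a and fb <= fixed_low) or (het_b and fa <= fixed_low):
            klass = "private_heterogeneity"
        else:
            klass = "ambiguous"
        rows.append(
            {
                "replicon": replicon,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "alt_fraction_a": fa,
                "alt_fraction_b": fb,
                "depth_a": da,
                "depth_b": db,
                "class": klass,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "replicon",
            "pos",
            "ref",
            "alt",
            "alt_fraction_a",
            "alt_fraction_b",
            "depth_a",
            "depth_b",
            "class",
        ],
    )


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon": c.replicon,
                "pos": c.pos,
                "ref": c.ref_base,
                "alt": c.alt_base,
                "alt_fraction": c.alt_fraction,
                "depth": c.depth,
                "sample": c.sample,
            }
        for c in calls
        ],
        columns=["replicon", "pos", "ref", "alt", "alt_fraction", "depth", "sample"],
    )


def write_vcf(calls: list[VariantCall], genome: GenomeModel, path) -> None:
    """Emit calls as minimal VCF v4.2 (POS 1-based; INFO carries AF and DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=normcov\n")
        for rep in genome:
            fh.write(f"##contig=<ID={rep.name},length={rep.length_bp}>\n")
        fh.write(
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">\n'
        )
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.replicon, c.pos, c.alt_base)):
            fh.write(
                f"{c.replicon}\t{c.pos + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\t.\t"
                f"AF={c.alt_fraction:.4f};DP={c.depth}\n"
            )
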