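"""CIGAR refinement and per-read variant event extraction.

Read aligners such as BWA-MEM encode aligned blocks as CIGAR ``M`` runs that
conflate matches and mismatches.  To see a complex indel as a haplotype on a
single read, each ``M`` run is first resolved against the reference into
maximal runs of ``=`` (match) and ``X`` (mismatch); the refined alignment is
then scanned once, in read order, for variant events: mismatch runs,
insertions and deletions, each with reference and read coordinates and the
Phred qualities of the supporting bases.

Reference coordinates are 1-based inclusive throughout (VCF/HGVS
convention); read offsets are 0-based and only used for indexing into the
read sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: CIGAR operations that consume read bases.
READ_CONSUMING = frozenset("M=XIS")
#: CIGAR operations that consume reference bases.
REF_CONSUMING = frozenset("M=XDN")

_VALID_OPS = frozenset("M=XIDNSHP")
# pysam numeric cigar codes, in order
_CODE_TO_OP = "MIDNSHP=X"
_OP_TO_CODE = {op: i for i, op in enumerate(_CODE_TO_OP)}


class MalformedAlignmentError(ValueError):
    """Read length inconsistent with its CIGAR (read is skipped upstream)."""


class CoordinateError(ValueError):
    """Supplied reference window does not cover the alignment's span."""


@dataclass(frozen=True)
class CigarOp:
    """A single CIGAR run: operation character and length in bases."""

    op: str
    length: int

    def __post_init__(self) -> None:
        if self.op not in _VALID_OPS:
            raise ValueError(f"invalid CIGAR operation {self.op!r}")
        if self.length < 1:
            raise ValueError(f"CIGAR length must be >= 1, got {self.length}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.length}{self.op}"


def ops_from_cigartuples(cigartuples: Iterable[tuple[int, int]]) -> list[CigarOp]:
    """Convert pysam ``cigartuples`` into :class:`CigarOp` objects."""
    return [CigarOp(_CODE_TO_OP[code], length) for code, length in cigartuples]


def ops_to_cigartuples(ops: Iterable[CigarOp]) -> list[tuple[int, int]]:
    return [(_OP_TO_CODE[o.op], o.length) for o in ops]


def ops_to_cigarstring(ops: Iterable[CigarOp]) -> str:
    return "".join(f"{o.length}{o.op}" for o in ops)


def read_span(ops: Iterable[CigarOp]) -> int:
    """Total read bases consumed by *ops* (``M``, ``=``, ``X``, ``I``, ``S``)."""
    return sum(o.length for o in ops if o.op in READ_CONSUMING)


def ref_span(ops: Iterable[CigarOp]) -> int:
    """Total reference bases consumed by *ops* (``M``, ``=``, ``X``, ``D``, ``N``)."""
    return sum(o.length for o in ops if o.op in REF_CONSUMING)


def _push(out: list[CigarOp], op: str, length: int) -> None:
    if length == 0:
        return
    if out and out[-1].op == op:
        out[-1] = CigarOp(op, out[-1].length + length)
    else:
        out.append(CigarOp(op, length))


def refine_cigar(ops: Sequence[CigarOp], read_seq: str, ref_window: str) -> list[CigarOp]:
    """Split every ``M`` run into maximal ``=``/``X`` runs by base comparison.

    Parameters
    ----------
    ops
        CIGAR runs of the alignment (may already be refined; refinement is
        idempotent).
    read_seq
        Full read sequence (including soft-clipped bases), any case.
    ref_window
        Reference bases covering the alignment's full reference span,
        starting at the leftmost aligned reference base.

    Comparison is case-insensitive; an ``N`` on either side compares as a
    mismatch.  All non-``M`` runs are preserved in order, and adjacent runs
    of the same refined operation are merged.
    """
    read = read_seq.upper()
    ref = ref_window.upper()
    if read_span(ops) != len(read):
        raise MalformedAlignmentError(
            f"CIGAR consumes {read_span(ops)} read bases but read has {len(read)}"
        )
    if ref_span(ops) > len(ref):
        raise CoordinateError(
            f"CIGAR consumes {ref_span(ops)} reference bases but window has {len(ref)}"
        )
    out: list[CigarOp] = []
    r = p = 0
    for o in ops:
        if o.op == "M":
            a = np.frombuffer(read[r : r + o.length].encode(), dtype=np.uint8)
            b = np.frombuffer(ref[p : p + o.length].encode(), dtype=np.uint8)
            mism = (a != b) | (a == ord("N")) | (b == ord("N"))
            # run-length encode the boolean mismatch vector
            bounds = np.flatnonzero(np.diff(mism)) + 1
            start = 0
            for stop in [*bounds.tolist(), o.length]:
                _push(out, "X" if mism[start] else "=", stop - start)
                start = stop
            r += o.length
            p += o.length
        else:
            _push(out, o.op, o.length)
            if o.op in READ_CONSUMING:
                r += o.length
            if o.op in REF_CONSUMING:
                p += o.length
    return out


@dataclass(frozen=True)
class VariantEvent:
    """One mismatch run, insertion or deletion observed on a single read.

    ``ref_start``/``ref_end`` are 1-based inclusive; an insertion is anchored
    at the reference base immediately to its left (``ref_start == ref_end``).
    ``quals`` holds the Phred scores of the alt bases, or of the two flanking
    read bases for a deletion.
    """

    kind: str  # mismatch | insertion | deletion
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    ref_bases: str
    alt_bases: str
    quals: tuple[int, ...]

    @property
    def op_count(self) -> int:
        """Operations this event contributes to the >=2-operation window rule.

        Each mismatched base counts separately (per-base M refinement); an
        insertion or deletion run counts once regardless of its length.
        """
        return len(self.alt_bases) if self.kind == "mismatch" else 1


@dataclass
class RefinedAlignment:
    """One read's alignment with ``M`` runs resolved into ``=``/``X`` runs."""

    read_id: str
    chrom: str
    ref_start: int  # 1-based leftmost aligned reference position
    ops: list[CigarOp]
    read_seq: str
    base_quals: list[int]
    ref_window: str  # reference bases over [ref_start, ref_end]
    mapq: int = 60
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_unmapped: bool = False

    @property
    def ref_end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        return self.ref_start + ref_span(self.ops) - 1

    @classmethod
    def from_pysam(cls, seg, ref_window: str) -> "RefinedAlignment":
        """Build (and refine) from a mapped :class:`pysam.AlignedSegment`."""
        ops = ops_from_cigartuples(seg.cigartuples)
        seq = seg.query_sequence
        quals = seg.query_qualities
        if seq is None or quals is None:
            raise MalformedAlignmentError(f"{seg.query_name}: missing SEQ or QUAL")
        return cls(
            read_id=seg.query_name,
            chrom=seg.reference_name,
            ref_start=seg.reference_start + 1,
            ops=refine_cigar(ops, seq, ref_window),
            read_seq=seq.upper(),
            base_quals=list(quals),
            ref_window=ref_window.upper(),
            mapq=seg.mapping_quality,
            is_secondary=seg.is_secondary,
            is_supplementary=seg.is_supplementary,
            is_duplicate=seg.is_duplicate,
            is_unmapped=seg.is_unmapped,
        )


def extract_events(aln: RefinedAlignment) -> list[VariantEvent]:
    """Scan a refined alignment and return its variant events in order.

    ``=`` and clipping runs produce no events; ``N`` (reference skip)
    produces no event but advances the reference coordinate.  Returns an
    empty list for a perfect read.
    """
    if any(o.op == "M" for o in aln.ops):
        raise ValueError("alignment must be refined (no M operations) before event extraction")
    events: list[VariantEvent] = []
    p = aln.ref_start
    r = 0
    w0 = aln.ref_start
    quals = aln.base_quals
    for o in aln.ops:
        L = o.length
        if o.op == "=":
            p += L
            r += L
        elif o.op == "X":
            events.append(
                VariantEvent(
                    kind="mismatch",
                    ref_start=p,
                    ref_end=p + L - 1,
                    read_start=r,
                    read_end=r + L - 1,
                    ref_bases=aln.ref_window[p - w0 : p - w0 + L],
                    alt_bases=aln.read_seq[r : r + L],
                    quals=tuple(quals[r : r + L]),
                )
            )
            p += L
            r += L
        elif o.op == "I":
            events.append(
                VariantEvent(
                    kind="insertion",
                    ref_start=p - 1,
                    ref_end=p - 1,
                    read_start=r,
                    read_end=r + L - 1,
                    ref_bases="",
                    alt_bases=aln.read_seq[r : r + L],
                    quals=tuple(quals[r : r + L]),
                )
            )
            r += L
        elif o.op == "D":
            flank = []
            if r - 1 >= 0:
                flank.append(quals[r - 1])
            if r < len(quals):
                flank.append(quals[r])
            events.append(
                VariantEvent(
                    kind="deletion",
                    ref_start=p,
                    ref_end=p + L - 1,
                    read_start=r - 1,
                    read_end=r - 1,
                    ref_bases=aln.ref_window[p - w0 : p - w0 + L],
                    alt_bases="",
                    quals=tuple(flank),
                )
            )
            p += L
        elif o.op == "N":
            p += L
        elif o.op == "S":
            r += L
        # H and P consume nothing
    return events
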