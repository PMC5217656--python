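"""Mutation engineering: write a specified (complex) variant into existing
read alignments at a target variant allele fraction.

This is the semi-simulation workhorse: given real or simulated alignments
and a delins specification, every primary read fully spanning the variant
(or a seeded random fraction of them, for VAF < 1) has the read bases
aligned across the span replaced by the alternate allele.  Base qualities
follow the net gain in bases: a net gain of zero (or a net loss) reuses the
original qualities positionally, while inserted extra bases borrow the
rounded mean quality of the flanking read bases.  Edited alignments can be
written back as SAM and converted to FASTQ for re-alignment.
"""

from __future__ import annotations

import gzip
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .refine import CigarOp, _push, ops_from_cigartuples, ops_to_cigartuples

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ReferenceAlleleMismatch(ValueError):
    """The variant's REF allele does not match the reference sequence."""


@dataclass(frozen=True)
class EngineeredVariant:
    """A delins specification applied to alignments by the engineer.

    ``ref_start``/``ref_end`` are 1-based inclusive reference coordinates of
    the replaced span; ``target_vaf`` is the fraction of fully spanning
    reads to edit (the semi-simulation default is 1.0, i.e. 100% VAF).
    """

    chrom: str
    ref_start: int
    ref_end: int
    ref_allele: str
    alt_allele: str
    target_vaf: float = 1.0

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start + 1 != len(self.ref_allele):
            raise ValueError(
                f"span {self.ref_start}-{self.ref_end} inconsistent with "
                f"ref allele length {len(self.ref_allele)}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("ref and alt alleles must be non-empty")
        if not 0.0 < self.target_vaf <= 1.0:
            raise ValueError(f"target_vaf must be in (0, 1], got {self.target_vaf}")

    @property
    def net_gain(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @classmethod
    def from_vcf_fields(cls, chrom: str, pos: int, ref: str, alt: str,
                        target_vaf: float = 1.0) -> "EngineeredVariant":
        return cls(chrom, pos, pos + len(ref) - 1, ref.upper(), alt.upper(), target_vaf)


@dataclass
class EditLog:
    """Record of one engineering pass: which reads were and were not edited."""

    variant: EngineeredVariant
    n_spanning: int = 0
    edited: list[str] = field(default_factory=list)
    partial_overlap: list[str] = field(default_factory=list)
    unselected: list[str] = field(default_factory=list)


def assign_qualities(
    original_quals: Sequence[int],
    span: tuple[int, int],
    net_gain: int,
    flank_w: int = 5,
    alt_len: int | None = None,
) -> list[int]:
    """Phred qualities for the alternate bases replacing read span [a, b).

    ``net_gain <= 0``: the replaced bases reuse the original qualities
    positionally (truncated for deletions).  ``net_gain >= 1``: every alt
    base receives the rounded mean of up to *flank_w* read bases on each
    side of the span (whichever flank exists at a read edge).
    """
    a, b = span
    if alt_len is None:
        alt_len = (b - a) + net_gain
    if alt_len < 0:
        raise ValueError("alt length is negative")
    if net_gain <= 0:
        seg = list(original_quals[a:b])
        if len(seg) < alt_len:  # read had a deletion inside the span
            pad = seg[-1] if seg else 30
            seg = seg + [pad] * (alt_len - len(seg))
        return seg[:alt_len]
    flanks = list(original_quals[max(0, a - flank_w) : a]) + list(original_quals[b : b + flank_w])
    if not flanks:
        raise ValueError("no flanking bases available; read cannot span the variant")
    q = int(round(float(np.mean(flanks))))
    return [q] * alt_len


def _delins_ops(ref_len: int, alt_len: int) -> list[CigarOp]:
    """A consistent (not necessarily optimal) CIGAR for alt aligned over ref."""
    m = min(ref_len, alt_len)
    ops: list[CigarOp] = []
    if m:
        ops.append(CigarOp("M", m))
    if alt_len > m:
        ops.append(CigarOp("I", alt_len - m))
    if ref_len > m:
        ops.append(CigarOp("D", ref_len - m))
    return ops


def _split_for_edit(
    ops: Sequence[CigarOp], aln_ref_start1: int, start1: int, end1: int, read_len: int
) -> tuple[int, int, list[CigarOp], list[CigarOp]]:
    """Split a CIGAR around reference span [start1, end1] (1-based inclusive).

    Returns (a, b, pre_ops, post_ops) where read offsets [a, b) are the
    bases aligned across the span (insertions anchored inside included).
    """
    p = aln_ref_start1
    r = 0
    pre: list[CigarOp] = []
    post: list[CigarOp] = []
    a: int | None = None
    b: int | None = None
    for o in ops:
        L = o.length
        if o.op in "M=X":
            n1 = min(L, max(0, start1 - p))
            n2 = max(0, min(end1, p + L - 1) - max(start1, p) + 1)
            n3 = L - n1 - n2
            if n1:
                _push(pre, o.op, n1)
            if n2 and a is None:
                a = r + n1
            if n3:
                if b is None:
                    b = r + n1 + n2
                _push(post, o.op, n3)
            p += L
            r += L
        elif o.op in "DN":
            n1 = min(L, max(0, start1 - p))
            n2 = max(0, min(end1, p + L - 1) - max(start1, p) + 1)
            n3 = L - n1 - n2
            if n1:
                _push(pre, o.op, n1)
            if n3:
                _push(post, o.op, n3)
            p += L
        elif o.op == "I":
            anchor = p - 1
            if anchor < start1:
                _push(pre, o.op, L)
            elif anchor <= end1:
                if a is None:
                    a = r
            else:
                if b is None:
                    b = r
                _push(post, o.op, L)
            r += L
        elif o.op == "S":
            if a is None and b is None:
                _push(pre, o.op, L)
            else:
                if b is None:
                    b = r
                _push(post, o.op, L)
            r += L
        elif o.op == "H":
            _push(pre if a is None and b is None else post, o.op, L)
    if b is None:
        b = read_len
    if a is None:
        a = b
    return a, b, pre, post


def _edit_segment(seg: pysam.AlignedSegment, variant: EngineeredVariant,
                  flank_w: int = 5) -> None:
    """Rewrite one spanning read in place so it carries the variant."""
    ops = ops_from_cigartuples(seg.cigartuples)
    seq = seg.query_sequence
    quals = list(seg.query_qualities)
    a, b, pre, post = _split_for_edit(
        ops, seg.reference_start + 1, variant.ref_start, variant.ref_end, len(seq)
    )
    alt = variant.alt_allele
    mid_quals = assign_qualities(quals, (a, b), variant.net_gain, flank_w, alt_len=len(alt))
    new_ops: list[CigarOp] = []
    for o in pre + _delins_ops(len(variant.ref_allele), len(alt)) + post:
        _push(new_ops, o.op, o.length)
    seg.query_sequence = seq[:a] + alt + seq[b:]
    seg.query_qualities = quals[:a] + mid_quals + quals[b:]
    seg.cigartuples = ops_to_cigartuples(new_ops)


def engineer_segments(
    segments: Sequence[pysam.AlignedSegment],
    variant: EngineeredVariant,
    rng: random.Random | None = None,
    reference: str | None = None,
    flank_w: int = 5,
) -> EditLog:
    """Edit (in place) the reads of *segments* that fully span the variant.

    With ``target_vaf < 1`` a seeded random subset of ``round(vaf * n)``
    spanning reads is edited.  Reads only partially overlapping the span are
    left unmodified and listed in the edit log.  If *reference* (the
    reference bases over the variant span) is given, it must match the
    variant's REF allele.
    """
    if reference is not None and reference.upper() != variant.ref_allele.upper():
        raise ReferenceAlleleMismatch(
            f"{variant.chrom}:{variant.ref_start} REF {variant.ref_allele} does not "
            f"match reference {reference.upper()}"
        )
    log = EditLog(variant=variant)
    spanning: list[pysam.AlignedSegment] = []
    for seg in segments:
        if (seg.is_unmapped or seg.is_secondary or seg.is_supplementary
                or seg.reference_name != variant.chrom):
            continue
        s1 = seg.reference_start + 1
        e1 = seg.reference_end  # 1-based inclusive end
        if s1 <= variant.ref_start and e1 >= variant.ref_end:
            spanning.append(seg)
        elif s1 <= variant.ref_end and e1 >= variant.ref_start:
            log.partial_overlap.append(seg.query_name)
    log.n_spanning = len(spanning)
    if not spanning:
        logger.warning(
            "no reads fully span %s:%d-%d; nothing engineered",
            variant.chrom, variant.ref_start, variant.ref_end,
        )
        return log
    if variant.target_vaf >= 1.0:
        chosen = spanning
    else:
        k = int(round(variant.target_vaf * len(spanning)))
        rng = rng or random.Random(0)
        chosen_set = set(rng.sample(range(len(spanning)), k))
        chosen = [seg for i, seg in enumerate(spanning) if i in chosen_set]
        log.unselected = [
            seg.query_name for i, seg in enumerate(spanning) if i not in chosen_set
        ]
    for seg in chosen:
        _edit_segment(seg, variant, flank_w)
        log.edited.append(seg.query_name)
    return log


def engineer_reads(
    alignments,
    fasta_path,
    variants: EngineeredVariant | Iterable[EngineeredVariant],
    out_sam=None,
    seed: int = 0,
    fastq_out=None,
    log_out=None,
) -> list[EditLog]:
    """File-level engineering: SAM/BAM in, edited SAM (and FASTQ, TSV log) out.

    The REF allele of every variant is checked against the reference FASTA
    before any read is touched; a mismatch aborts the run.
    """
    if isinstance(variants, EngineeredVariant):
        variants = [variants]
    variants = list(variants)
    rng = random.Random(seed)
    with pysam.AlignmentFile(str(alignments)) as fh:
        header = fh.header
        segments = list(fh.fetch(until_eof=True))
    with pysam.FastaFile(str(fasta_path)) as fa:
        logs = []
        for var in variants:
            ref = fa.fetch(var.chrom, var.ref_start - 1, var.ref_end)
            logs.append(engineer_segments(segments, var, rng, reference=ref))
    if out_sam is not None:
        mode = "wb" if str(out_sam).endswith(".bam") else "w"
        with pysam.AlignmentFile(str(out_sam), mode, header=header) as out:
            for seg in segments:
                out.write(seg)
    if fastq_out is not None:
        write_fastq(sam_to_fastq(segments), fastq_out)
    if log_out is not None:
        write_edit_log(logs, log_out)
    return logs


def sam_to_fastq(
    segments: Iterable[pysam.AlignedSegment],
) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality string) in original sequencing orientation.

    One record per primary alignment; reverse-strand alignments are
    reverse-complemented and their qualities reversed.
    """
    for seg in segments:
        if seg.is_secondary or seg.is_supplementary:
            continue
        seq = seg.query_sequence
        quals = list(seg.query_qualities)
        if seg.is_reverse:
            seq = seq.translate(_COMP)[::-1]
            quals = quals[::-1]
        yield seg.query_name, seq, "".join(chr(q + 33) for q in quals)


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_edit_log(logs: Sequence[EditLog], path) -> None:
    with open(path, "w") as fh:
        fh.write("#record\tchrom\tpos\tref\talt\tvaf\tdetail\n")
        for log in logs:
            v = log.variant
            base = f"{v.chrom}\t{v.ref_start}\t{v.ref_allele}\t{v.alt_allele}\t{v.target_vaf}"
            fh.write(f"variant\t{base}\tspanning={log.n_spanning};edited={len(log.edited)}\n")
            for name in log.edited:
                fh.write(f"edited_read\t{base}\t{name}\n")
            for name in log.partial_overlap:
                fh.write(f"partial_overlap\t{base}\t{name}\n")
            for name in log.unselected:
                fh.write(f"unselected\t{base}\t{name}\n")


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim common flanking bases (suffix then prefix), adjusting pos."""
    ref = ref.upper()
    alt = alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref = ref[:-1]
        alt = alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return pos, ref, alt


def evaluate_sensitivity(truth: Sequence[EngineeredVariant], calls) -> float:
    """Fraction of truth variants matched by some call.

    A truth variant counts as detected when a call agrees on chromosome and
    on (pos, ref, alt) after trimming common flanking bases from both.
    """
    call_keys = {
        (c.chrom,) + normalize_variant(c.pos, c.ref_allele, c.alt_allele) for c in calls
    }
    if not truth:
        return 1.0
    detected = sum(
        1
        for t in truth
        if (t.chrom,) + normalize_variant(t.ref_start, t.ref_allele, t.alt_allele)
        in call_keys
    )
    return detected / len(truth)
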