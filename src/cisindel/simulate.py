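"""Synthetic reference and read generation with a known truth set.

Reads are written pre-aligned (M-only CIGARs at known positions) so the
whole calling stack, including CIGAR refinement, is exercised hermetically
without an external aligner.  Two layouts are supported: shotgun-style
phased tiling that gives exact uniform coverage away from the contig ends,
and amplicon mode with fixed start positions at very high depth.  Variants
are spiked in through the mutation engineer, so the truth manifest and the
caller output are directly comparable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pysam

from .engineer import EditLog, EngineeredVariant, engineer_segments, sam_to_fastq, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_FASTA_WIDTH = 60


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    The seed fully determines the output; ``base_qual`` is either a constant
    Phred score or a per-cycle profile of length ``read_length``.
    """

    contig_length: int
    read_length: int = 150
    mean_depth: int = 50
    substitution_error_rate: float = 0.0
    base_qual: int | Sequence[int] = 35
    variants: list[EngineeredVariant] = field(default_factory=list)
    seed: int = 0
    contig_name: str = "sim1"
    amplicon_starts: list[int] | None = None  # 0-based; fixed-depth amplicon mode

    def __post_init__(self) -> None:
        if self.contig_length < self.read_length:
            raise ValueError("contig_length must be >= read_length")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1)")


def make_reference(spec: SimulationSpec, path) -> str:
    """Write a seeded uniform-random contig as an indexed FASTA; return it."""
    rng = np.random.default_rng(spec.seed)
    seq = rng.choice(_BASES, size=spec.contig_length).tobytes().decode()
    with open(path, "w") as fh:
        fh.write(f">{spec.contig_name}\n")
        for i in range(0, len(seq), _FASTA_WIDTH):
            fh.write(seq[i : i + _FASTA_WIDTH] + "\n")
    pysam.faidx(str(path))
    return seq


def _read_starts(spec: SimulationSpec) -> Iterator[int]:
    """0-based start positions.

    Shotgun mode tiles ``mean_depth`` phases of end-to-end reads, phase k
    shifted by ``k * read_length / mean_depth``, so every position at least
    one read length from the contig ends is covered exactly ``mean_depth``
    times.  Amplicon mode emits ``mean_depth`` reads per fixed start.
    """
    rl = spec.read_length
    if spec.amplicon_starts is not None:
        for start in spec.amplicon_starts:
            if start + rl > spec.contig_length:
                raise ValueError(f"amplicon at {start} extends beyond the contig")
            for _ in range(spec.mean_depth):
                yield start
        return
    for k in range(spec.mean_depth):
        offset = (k * rl) // spec.mean_depth
        yield from range(offset, spec.contig_length - rl + 1, rl)


def _qual_profile(spec: SimulationSpec) -> list[int]:
    if isinstance(spec.base_qual, int):
        return [spec.base_qual] * spec.read_length
    profile = list(spec.base_qual)
    if len(profile) != spec.read_length:
        raise ValueError("base_qual profile length must equal read_length")
    return profile


def simulate_reads(
    spec: SimulationSpec,
    fasta_path,
    out_bam,
    truth_tsv=None,
    fastq_out=None,
) -> list[EditLog]:
    """Generate a sorted, indexed BAM (plus optional truth TSV and FASTQ).

    Substitution errors are injected per base at the configured rate; each
    variant is then engineered into ``round(vaf * n_spanning)`` spanning
    reads with a seed derived from the spec seed.  Returns the edit logs
    (the machine-readable truth).
    """
    with pysam.FastaFile(str(fasta_path)) as fa:
        if spec.contig_name not in fa.references:
            raise ValueError(f"contig {spec.contig_name!r} not in {fasta_path}")
        ref = fa.fetch(spec.contig_name).upper()
    for var in spec.variants:
        if var.ref_end > len(ref) or var.ref_start < 1:
            raise ValueError(f"variant span {var.ref_start}-{var.ref_end} exceeds the contig")

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": spec.contig_name, "LN": len(ref)}],
        }
    )
    rng = np.random.default_rng([spec.seed, 1])
    rl = spec.read_length
    quals = _qual_profile(spec)
    segments = []
    for i, start in enumerate(_read_starts(spec)):
        seq = np.frombuffer(ref[start : start + rl].encode(), dtype=np.uint8).copy()
        if spec.substitution_error_rate > 0.0:
            hits = np.flatnonzero(rng.random(rl) < spec.substitution_error_rate)
            for j in hits:
                cur = np.searchsorted(_BASES, seq[j])
                seq[j] = _BASES[(cur + rng.integers(1, 4)) % 4]
        seg = pysam.AlignedSegment(header)
        seg.query_name = f"sim_{i:06d}"
        seg.flag = 16 if i % 2 else 0
        seg.reference_id = 0
        seg.reference_start = start
        seg.mapping_quality = 60
        seg.query_sequence = seq.tobytes().decode()
        seg.query_qualities = quals
        seg.cigartuples = [(0, rl)]
        segments.append(seg)

    logs = []
    for i, var in enumerate(spec.variants):
        sub_rng = random.Random((spec.seed * 100003 + i) % (2**31))
        reference = ref[var.ref_start - 1 : var.ref_end]
        logs.append(engineer_segments(segments, var, sub_rng, reference=reference))

    segments.sort(key=lambda s: (s.reference_start, s.query_name))
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as out:
        for seg in segments:
            out.write(seg)
    pysam.index(str(out_bam))
    if truth_tsv is not None:
        write_truth_manifest(logs, truth_tsv)
    if fastq_out is not None:
        write_fastq(sam_to_fastq(segments), fastq_out)
    return logs


def write_truth_manifest(logs: Sequence[EditLog], path) -> None:
    """TSV truth manifest: one variant row plus one row per edited read."""
    with open(path, "w") as fh:
        fh.write("#record\tchrom\tpos\tend\tref\talt\tvaf\tdetail\n")
        for log in logs:
            v = log.variant
            base = (
                f"{v.chrom}\t{v.ref_start}\t{v.ref_end}\t{v.ref_allele}"
                f"\t{v.alt_allele}\t{v.target_vaf}"
            )
            fh.write(f"variant\t{base}\tspanning={log.n_spanning};edited={len(log.edited)}\n")
            for name in log.edited:
                fh.write(f"edited_read\t{base}\t{name}\n")


def load_truth_manifest(path) -> list[tuple[EngineeredVariant, list[str]]]:
    out: list[tuple[EngineeredVariant, list[str]]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            rec, chrom, pos, end, ref, alt, vaf, detail = line.rstrip("\n").split("\t")
            if rec == "variant":
                var = EngineeredVariant(chrom, int(pos), int(end), ref, alt, float(vaf))
                out.append((var, []))
            elif rec == "edited_read":
                out[-1][1].append(detail)
    return out
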