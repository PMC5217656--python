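"""Complex indel calling: event clustering, candidate windows, aggregation
and mark-or-remove filtering.

A complex indel (delins) is reported when a single read carries at least two
variant operations (mismatched bases, insertion runs, deletion runs) that
are at most ``l`` reference bases apart, spanning at least two nucleotides
on the reference or the read.  Identical alleles are aggregated across
reads into a locus-level call with allele depth, total depth and allele
frequency, then filtered on base quality, depth and allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pysam

from .refine import (
    MalformedAlignmentError,
    RefinedAlignment,
    VariantEvent,
    extract_events,
)

logger = logging.getLogger(__name__)

FILTER_LOW_QUAL = "low_qual"
FILTER_LOW_DEPTH = "low_depth"
FILTER_LOW_AF = "low_af"


@dataclass(frozen=True)
class FilterConfig:
    """Calling and filtering parameters.

    ``max_distance`` is the maximum reference gap *l* between consecutive
    in-cis events chained into one window (default 5).  Threshold filters
    mark calls by default; the ``skip_*`` switches remove marked calls from
    the output instead.
    """

    max_distance: int = 5
    min_af: float = 0.0
    min_depth: int = 0
    min_qual: float = 20.0
    skip_lowqual: bool = False
    skip_lowdepth: bool = False
    skip_lowaf: bool = False
    max_pileup_depth: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_af <= 1.0:
            raise ValueError(f"min_af must be in [0, 1], got {self.min_af}")
        if self.max_distance < 0:
            raise ValueError(f"max_distance must be >= 0, got {self.max_distance}")


@dataclass(frozen=True)
class CandidateCall:
    """A per-read complex-indel window (one haplotype observation)."""

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    ref_allele: str
    alt_allele: str
    events: tuple[VariantEvent, ...]
    mean_alt_qual: float
    n_ops: int


@dataclass
class ComplexIndelCall:
    """An aggregated locus/allele call with depth, AF and filter status."""

    chrom: str
    pos: int  # 1-based first affected reference base
    ref_end: int
    ref_allele: str
    alt_allele: str
    allele_depth: int
    mean_qual: float
    n_ops: int
    total_depth: int = 0
    af: float = 0.0
    filters: frozenset[str] = frozenset()

    @property
    def is_pass(self) -> bool:
        return not self.filters


def cluster_events(events: Sequence[VariantEvent], l: int) -> list[list[VariantEvent]]:
    """Chain events whose reference gap is at most *l* into clusters.

    The gap between consecutive events is the number of reference bases
    strictly between one event's ``ref_end`` and the next event's
    ``ref_start``; chaining is transitive, so a cluster may extend well past
    *l* in total.  Singleton clusters are returned (callers drop them via
    the >=2-operation rule).
    """
    clusters: list[list[VariantEvent]] = []
    cur: list[VariantEvent] = []
    cur_end = 0
    for ev in events:
        if not cur:
            cur = [ev]
            cur_end = ev.ref_end
            continue
        gap = ev.ref_start - cur_end - 1
        if gap <= l:
            cur.append(ev)
        else:
            clusters.append(cur)
            cur = [ev]
        cur_end = max(cur_end, ev.ref_end) if len(cur) > 1 else ev.ref_end
    if cur:
        clusters.append(cur)
    return clusters


def _alt_over_span(aln: RefinedAlignment, start: int, end: int) -> tuple[str, list[int]]:
    """Read bases (and their quals) aligned across reference span [start, end].

    Mismatch bases substitute, insertion bases (anchored inside the span)
    are included, deleted bases are omitted, matched bases are copied.
    """
    parts: list[str] = []
    quals: list[int] = []
    p = aln.ref_start
    r = 0
    for o in aln.ops:
        L = o.length
        if o.op in "=XM":
            lo = max(p, start)
            hi = min(p + L - 1, end)
            if lo <= hi:
                a = r + (lo - p)
                b = r + (hi - p) + 1
                parts.append(aln.read_seq[a:b])
                quals.extend(aln.base_quals[a:b])
            p += L
            r += L
        elif o.op == "I":
            if start <= p - 1 <= end:
                parts.append(aln.read_seq[r : r + L])
                quals.extend(aln.base_quals[r : r + L])
            r += L
        elif o.op in "DN":
            p += L
        elif o.op == "S":
            r += L
    return "".join(parts), quals


def window_to_candidate(
    cluster: Sequence[VariantEvent], aln: RefinedAlignment
) -> CandidateCall | None:
    """Turn one event cluster into a candidate call, or ``None``.

    Rejected when the cluster carries fewer than two operations, when
    neither allele reaches two nucleotides, or when the window's reference
    span is not fully contained in the aligned (non-clipped) part of the
    read.
    """
    n_ops = sum(ev.op_count for ev in cluster)
    if n_ops < 2:
        return None
    start = min(ev.ref_start for ev in cluster)
    end = max(ev.ref_end for ev in cluster)
    if start < aln.ref_start or end > aln.ref_end:
        logger.debug(
            "%s: window %d-%d extends beyond aligned span %d-%d, rejected",
            aln.read_id, start, end, aln.ref_start, aln.ref_end,
        )
        return None
    ref_allele = aln.ref_window[start - aln.ref_start : end - aln.ref_start + 1]
    alt_allele, alt_quals = _alt_over_span(aln, start, end)
    if not ref_allele or not alt_allele or ref_allele == alt_allele:
        return None
    if max(len(ref_allele), len(alt_allele)) < 2:
        return None
    if not alt_quals:  # pure-deletion window: fall back to flanking quals
        alt_quals = [q for ev in cluster for q in ev.quals]
    return CandidateCall(
        read_id=aln.read_id,
        chrom=aln.chrom,
        ref_start=start,
        ref_end=end,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        events=tuple(cluster),
        mean_alt_qual=float(np.mean(alt_quals)),
        n_ops=n_ops,
    )


def aggregate_candidates(candidates: Iterable[CandidateCall]) -> list[ComplexIndelCall]:
    """Group per-read candidates into per-allele calls.

    Grouping key is (chrom, ref_start, ref_end, alt_allele): distinct alt
    alleles at overlapping spans stay separate calls.  Allele depth counts
    distinct supporting reads.
    """
    groups: dict[tuple[str, int, int, str], list[CandidateCall]] = {}
    for cand in candidates:
        key = (cand.chrom, cand.ref_start, cand.ref_end, cand.alt_allele)
        groups.setdefault(key, []).append(cand)
    calls = []
    for (chrom, start, end, alt), members in groups.items():
        calls.append(
            ComplexIndelCall(
                chrom=chrom,
                pos=start,
                ref_end=end,
                ref_allele=members[0].ref_allele,
                alt_allele=alt,
                allele_depth=len({m.read_id for m in members}),
                mean_qual=float(np.mean([m.mean_alt_qual for m in members])),
                n_ops=max(m.n_ops for m in members),
            )
        )
    return calls


def _read_is_eligible(seg: pysam.AlignedSegment) -> bool:
    return not (
        seg.is_unmapped
        or seg.is_secondary
        or seg.is_supplementary
        or seg.is_duplicate
        or seg.is_qcfail
    )


def compute_total_depth(
    bam: pysam.AlignmentFile, chrom: str, pos: int, max_pileup_depth: int = 1_000_000
) -> int:
    """Number of eligible reads whose aligned span covers 1-based *pos*.

    Counts reads directly from the index (no pileup), so deep amplicon data
    is never truncated below ``max_pileup_depth``.
    """
    if chrom not in bam.references:
        raise ValueError(f"contig {chrom!r} not present in BAM header")
    if not 1 <= pos <= bam.get_reference_length(chrom):
        raise ValueError(f"position {chrom}:{pos} is off the contig")
    pos0 = pos - 1
    n = 0
    for seg in bam.fetch(chrom, pos0, pos0 + 1):
        if not _read_is_eligible(seg):
            continue
        if seg.reference_start <= pos0 < seg.reference_end:
            n += 1
            if n >= max_pileup_depth:
                break
    return n


def apply_filters(call: ComplexIndelCall, cfg: FilterConfig) -> ComplexIndelCall:
    """Return *call* with its filter set populated (PASS == empty set)."""
    filters = set()
    if call.af < cfg.min_af:
        filters.add(FILTER_LOW_AF)
    if call.total_depth < cfg.min_depth:
        filters.add(FILTER_LOW_DEPTH)
    if call.mean_qual < cfg.min_qual:
        filters.add(FILTER_LOW_QUAL)
    return replace(call, filters=frozenset(filters))


def _removed_by_skip(call: ComplexIndelCall, cfg: FilterConfig) -> bool:
    return (
        (cfg.skip_lowaf and FILTER_LOW_AF in call.filters)
        or (cfg.skip_lowdepth and FILTER_LOW_DEPTH in call.filters)
        or (cfg.skip_lowqual and FILTER_LOW_QUAL in call.filters)
    )


def _load_bed(path) -> list[tuple[str, int, int]]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions


def _iter_reads(bam: pysam.AlignmentFile, regions):
    if regions is None:
        yield from bam.fetch()
        return
    seen: set[tuple[str, int, int]] = set()
    for chrom, start, end in regions:
        for seg in bam.fetch(chrom, start, end):
            key = (seg.query_name, seg.reference_start, seg.flag)
            if key in seen:
                continue
            seen.add(key)
            yield seg


def call_complex_indels(
    bam_path,
    fasta_path,
    cfg: FilterConfig | None = None,
    regions=None,
) -> tuple[list[ComplexIndelCall], dict]:
    """Run the full per-read calling pipeline over a sorted, indexed BAM.

    refine -> extract events -> chain clusters -> candidate windows ->
    aggregate alleles -> depth/AF -> mark-or-remove filters.  Returns the
    calls sorted by (BAM header contig order, pos, ref, alt) and a stats
    dict (read/candidate/call counts).

    *regions* may be a BED path or an iterable of (chrom, start0, end0).
    """
    cfg = cfg or FilterConfig()
    stats = {
        "reads_seen": 0,
        "reads_skipped_flags": 0,
        "reads_skipped_malformed": 0,
        "candidates": 0,
        "calls_total": 0,
        "calls_removed": 0,
    }
    if isinstance(regions, (str, bytes)) or hasattr(regions, "__fspath__"):
        regions = _load_bed(regions)
    candidates: list[CandidateCall] = []
    with pysam.AlignmentFile(str(bam_path)) as bam, pysam.FastaFile(str(fasta_path)) as fa:
        missing = [c for c in bam.references if c not in fa.references]
        if missing:
            raise ValueError(
                f"contigs {missing} present in BAM header but absent from "
                f"reference FASTA {fasta_path}"
            )
        for seg in _iter_reads(bam, regions):
            stats["reads_seen"] += 1
            if not _read_is_eligible(seg):
                stats["reads_skipped_flags"] += 1
                continue
            window = fa.fetch(seg.reference_name, seg.reference_start, seg.reference_end)
            try:
                aln = RefinedAlignment.from_pysam(seg, window)
            except MalformedAlignmentError as exc:
                logger.warning("skipping malformed alignment: %s", exc)
                stats["reads_skipped_malformed"] += 1
                continue
            events = extract_events(aln)
            if not events:
                continue
            for cluster in cluster_events(events, cfg.max_distance):
                cand = window_to_candidate(cluster, aln)
                if cand is not None:
                    candidates.append(cand)
        stats["candidates"] = len(candidates)

        calls = aggregate_candidates(candidates)
        depth_cache: dict[tuple[str, int], int] = {}
        out = []
        for call in calls:
            key = (call.chrom, call.pos)
            if key not in depth_cache:
                depth_cache[key] = compute_total_depth(
                    bam, call.chrom, call.pos, cfg.max_pileup_depth
                )
            call.total_depth = depth_cache[key]
            call.af = call.allele_depth / call.total_depth if call.total_depth else 0.0
            call = apply_filters(call, cfg)
            stats["calls_total"] += 1
            if _removed_by_skip(call, cfg):
                stats["calls_removed"] += 1
                continue
            out.append(call)
        contig_order = {name: i for i, name in enumerate(bam.references)}
    out.sort(key=lambda c: (contig_order[c.chrom], c.pos, c.ref_allele, c.alt_allele))
    logger.info(
        "processed %d reads, %d candidate windows, %d calls (%d removed by filters)",
        stats["reads_seen"], stats["candidates"],
        stats["calls_total"] - stats["calls_removed"], stats["calls_removed"],
    )
    return out, stats
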