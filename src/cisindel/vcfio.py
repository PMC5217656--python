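"""VCF 4.1 serialization of complex indel calls.

Calls are written delins-style: REF and ALT are both non-empty by the
calling invariant, so no anchor-base padding is used and the record maps
directly onto HGVS ``delins`` notation.  Multi-allelic sites are emitted as
separate records so every allele keeps its own AD/AF.  Output bytes are
deterministic for a fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import pysam

from .caller import ComplexIndelCall

FILEFORMAT = "VCFv4.1"

_INFO_META = [
    ("DP", "1", "Integer", "Total read depth at POS (primary, mapped, non-duplicate reads)"),
    ("AD", "1", "Integer", "Number of reads supporting the alternate allele"),
    ("AF", "1", "Float", "Alternate allele frequency (AD/DP)"),
    ("NOPS", "1", "Integer", "Variant operations in the window (mismatched bases + indel runs)"),
    ("SPAN", "1", "Integer", "1-based inclusive reference end of the variant window"),
]
_FILTER_META = [
    ("low_qual", "Mean alternate base quality below min_qual"),
    ("low_depth", "Total depth below min_depth"),
    ("low_af", "Allele frequency below min_af"),
]

_ALLELE_ALPHABET = frozenset("ACGTN")


class ReferenceMismatchError(RuntimeError):
    """REF allele does not match the reference FASTA (coordinate bug)."""


@dataclass(frozen=True)
class VcfRecord:
    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    qual: float
    filter: str
    info: tuple[tuple[str, str], ...]

    def to_line(self) -> str:
        info = ";".join(f"{k}={v}" for k, v in self.info)
        return (
            f"{self.chrom}\t{self.pos}\t{self.id}\t{self.ref}\t{self.alt}"
            f"\t{self.qual:.1f}\t{self.filter}\t{info}"
        )


def to_vcf_record(call: ComplexIndelCall) -> VcfRecord:
    """Serialize one aggregated call as a delins-style VCF record."""
    for allele in (call.ref_allele, call.alt_allele):
        if not allele or set(allele) - _ALLELE_ALPHABET:
            raise ValueError(f"invalid allele {allele!r} in call at {call.chrom}:{call.pos}")
    filt = "PASS" if not call.filters else ";".join(sorted(call.filters))
    info = (
        ("DP", str(call.total_depth)),
        ("AD", str(call.allele_depth)),
        ("AF", f"{call.af:.4f}"),
        ("NOPS", str(call.n_ops)),
        ("SPAN", str(call.ref_end)),
    )
    return VcfRecord(
        chrom=call.chrom,
        pos=call.pos,
        id=".",
        ref=call.ref_allele,
        alt=call.alt_allele,
        qual=round(call.mean_qual, 1),
        filter=filt,
        info=info,
    )


def verify_reference(calls: Iterable[ComplexIndelCall], fasta_path) -> None:
    """Assert every call's REF equals the reference FASTA substring at POS."""
    with pysam.FastaFile(str(fasta_path)) as fa:
        for call in calls:
            expected = fa.fetch(call.chrom, call.pos - 1, call.pos - 1 + len(call.ref_allele))
            if expected.upper() != call.ref_allele:
                raise ReferenceMismatchError(
                    f"{call.chrom}:{call.pos} REF={call.ref_allele} but reference "
                    f"has {expected.upper()}"
                )


def write_vcf(
    calls: Sequence[ComplexIndelCall],
    out: TextIO | str,
    contigs: Sequence[tuple[str, int]],
    source: str = "cisindel",
    params: str | None = None,
) -> None:
    """Write calls as a VCF 4.1 file (header-only when there are no calls).

    *contigs* lists (name, length) pairs in header order, typically taken
    from the FASTA index; records are emitted grouped by that order.
    """
    order = {name: i for i, (name, _) in enumerate(contigs)}
    for call in calls:
        if call.chrom not in order:
            raise ValueError(f"call contig {call.chrom!r} not among header contigs")
    records = sorted(
        (to_vcf_record(c) for c in calls),
        key=lambda r: (order[r.chrom], r.pos, r.ref, r.alt),
    )
    lines = [f"##fileformat={FILEFORMAT}", f"##source={source}"]
    if params:
        lines.append(f"##{source}_params={params}")
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    for key, number, typ, desc in _INFO_META:
        lines.append(f'##INFO=<ID={key},Number={number},Type={typ},Description="{desc}">')
    for key, desc in _FILTER_META:
        lines.append(f'##FILTER=<ID={key},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    lines.extend(r.to_line() for r in records)
    text = "\n".join(lines) + "\n"
    if hasattr(out, "write"):
        out.write(text)
    else:
        with open(out, "w") as fh:
            fh.write(text)
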