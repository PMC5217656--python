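"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a deliberately different route from
the implementation it checks: column-by-column alignment walks instead of
run-length arithmetic, pairwise merging to a fixed point instead of linear
chaining, naive counting instead of grouped aggregation.
"""

from __future__ import annotations

import random

from cisindel.refine import CigarOp, RefinedAlignment, VariantEvent

BASES = "ACGT"


def random_alignment(rng: random.Random) -> tuple[list[CigarOp], str, str]:
    """A random unrefined alignment: (ops with M runs, read_seq, ref_window)."""
    ops: list[tuple[str, int]] = []
    if rng.random() < 0.3:
        ops.append(("S", rng.randint(1, 5)))
    for _ in range(rng.randint(1, 5)):
        ops.append(("M", rng.randint(1, 20)))
        if rng.random() < 0.5:
            ops.append((rng.choice("ID"), rng.randint(1, 4)))
    ops.append(("M", rng.randint(1, 10)))  # alignments end on an aligned base
    if rng.random() < 0.3:
        ops.append(("S", rng.randint(1, 5)))
    ref_len = sum(n for op, n in ops if op in "MD")
    ref = "".join(rng.choice(BASES) for _ in range(ref_len))
    read = []
    p = 0
    for op, n in ops:
        if op == "M":
            for i in range(n):
                base = ref[p + i]
                if rng.random() < 0.15:
                    base = rng.choice([b for b in BASES if b != base])
                read.append(base)
            p += n
        elif op == "D":
            p += n
        else:  # I or S
            read.extend(rng.choice(BASES) for _ in range(n))
    return [CigarOp(op, n) for op, n in ops], "".join(read), ref


def alignment_columns(ops, read_seq, ref_window, ref_start=1):
    """Walk an alignment one column at a time.

    Yields (kind, ref_pos, read_off, ref_base, read_base) with kind in
    {aligned, ins, del, clip}; aligned columns carry both bases so a caller
    can classify match vs mismatch itself.
    """
    p = ref_start
    r = 0
    for o in ops:
        for _ in range(o.length):
            if o.op in "M=X":
                yield ("aligned", p, r, ref_window[p - ref_start], read_seq[r])
                p += 1
                r += 1
            elif o.op == "I":
                yield ("ins", p - 1, r, "", read_seq[r])
                r += 1
            elif o.op in "DN":
                yield ("del" if o.op == "D" else "skip", p, -1, ref_window[p - ref_start], "")
                p += 1
            elif o.op == "S":
                yield ("clip", -1, r, "", read_seq[r])
                r += 1


def oracle_mismatch_count(ops, read_seq, ref_window) -> int:
    """Mismatch columns by independent per-column comparison (N mismatches)."""
    n = 0
    for kind, _p, _r, rb, qb in alignment_columns(ops, read_seq.upper(), ref_window.upper()):
        if kind == "aligned" and (rb != qb or "N" in (rb, qb)):
            n += 1
    return n


def oracle_events(aln: RefinedAlignment) -> list[tuple[str, int, int, str, str]]:
    """Events as (kind, ref_start, ref_end, ref_bases, alt_bases) from a
    one-column-at-a-time walk, grouping consecutive columns of one kind."""
    out = []
    cur = None  # [kind, ref_start, ref_end, ref_bases, alt_bases]
    for kind, p, _r, rb, qb in alignment_columns(
        aln.ops, aln.read_seq, aln.ref_window, aln.ref_start
    ):
        if kind == "aligned":
            ckind = "mismatch" if (rb != qb or "N" in (rb, qb)) else None
        elif kind == "ins":
            ckind = "insertion"
        elif kind == "del":
            ckind = "deletion"
        else:
            ckind = None
        if ckind is None:
            if cur:
                out.append(tuple(cur))
                cur = None
            continue
        if cur and cur[0] == ckind and (
            (ckind == "insertion" and cur[2] == p) or (ckind != "insertion" and cur[2] == p - 1)
        ):
            cur[2] = p if ckind != "insertion" else cur[2]
            cur[3] += rb
            cur[4] += qb
        else:
            if cur:
                out.append(tuple(cur))
            cur = [ckind, p, p, rb, qb]
        if ckind == "insertion":
            cur[2] = cur[1]
    if cur:
        out.append(tuple(cur))
    return out


def reconstruct_read(aln: RefinedAlignment, events) -> str:
    """Apply events to the reference window; must reproduce the aligned read
    bases (soft-clipped ends excluded)."""
    seq = list(aln.ref_window)
    for ev in sorted(events, key=lambda e: (e.ref_start, e.kind == "insertion"), reverse=True):
        i = ev.ref_start - aln.ref_start
        if ev.kind == "mismatch":
            seq[i : i + len(ev.ref_bases)] = list(ev.alt_bases)
        elif ev.kind == "deletion":
            del seq[i : i + len(ev.ref_bases)]
        else:  # insertion after anchor base i
            seq[i + 1 : i + 1] = list(ev.alt_bases)
    return "".join(seq)


def aligned_read_portion(aln: RefinedAlignment) -> str:
    left = aln.ops[0].length if aln.ops and aln.ops[0].op == "S" else 0
    right = aln.ops[-1].length if aln.ops and aln.ops[-1].op == "S" else 0
    return aln.read_seq[left : len(aln.read_seq) - right]


def random_events(rng: random.Random) -> list[VariantEvent]:
    """Sorted, non-overlapping random events for clustering tests."""
    events = []
    p = rng.randint(1, 20)
    for _ in range(rng.randint(0, 15)):
        kind = rng.choice(["mismatch", "insertion", "deletion"])
        if kind == "insertion":
            ev = VariantEvent("insertion", p, p, 0, 0, "", "A", (30,))
        else:
            L = rng.randint(1, 4)
            alt = "C" * L if kind == "mismatch" else ""
            ev = VariantEvent(kind, p, p + L - 1, 0, 0, "A" * L, alt, (30,) * L)
        events.append(ev)
        p = ev.ref_end + rng.randint(1, 15)
    return events


def _interval_gap(a: VariantEvent, b: VariantEvent) -> int:
    if b.ref_start > a.ref_end:
        return b.ref_start - a.ref_end - 1
    if a.ref_start > b.ref_end:
        return a.ref_start - b.ref_end - 1
    return -1  # overlapping or touching


def oracle_clusters(events, l: int) -> list[list[VariantEvent]]:
    """Merge all cluster pairs containing events within gap l, to fixed point."""
    clusters = [[e] for e in events]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    _interval_gap(a, b) <= l for a in clusters[i] for b in clusters[j]
                ):
                    clusters[i] = clusters[i] + clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    for c in clusters:
        c.sort(key=lambda e: (e.ref_start, e.ref_end))
    clusters.sort(key=lambda c: c[0].ref_start)
    return clusters
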