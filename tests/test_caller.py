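"""Event clustering, candidate windows, aggregation, depth and filters."""

import pytest

from cisindel.caller import (
    ComplexIndelCall,
    FilterConfig,
    aggregate_candidates,
    apply_filters,
    call_complex_indels,
    cluster_events,
    compute_total_depth,
    window_to_candidate,
)
from cisindel.engineer import EngineeredVariant
from cisindel.refine import RefinedAlignment, VariantEvent, extract_events, refine_cigar
from cisindel.simulate import SimulationSpec
from conftest import find_motif
from oracles import oracle_clusters, random_events


def mk_event(kind, start, end, ref="A", alt="C"):
    if kind == "insertion":
        return VariantEvent(kind, start, start, 0, 0, "", alt, (30,))
    if kind == "deletion":
        return VariantEvent(kind, start, end, 0, 0, ref * (end - start + 1), "", (30, 30))
    L = end - start + 1
    return VariantEvent(kind, start, end, 0, 0, ref * L, alt * L, (30,) * L)


def refined(cigar_pairs, read, ref, ref_start=1, quals=None):
    from cisindel.refine import CigarOp

    ops = [CigarOp(op, n) for op, n in cigar_pairs]
    return RefinedAlignment(
        read_id="r1",
        chrom="c1",
        ref_start=ref_start,
        ops=refine_cigar(ops, read, ref),
        read_seq=read,
        base_quals=quals or [30] * len(read),
        ref_window=ref,
    )


class TestClusterEvents:
    def test_gap_within_l_chains_two_events(self):
        evs = [mk_event("mismatch", 100, 100), mk_event("mismatch", 104, 104)]
        assert cluster_events(evs, 5) == [evs]

    def test_gap_beyond_l_splits(self):
        evs = [mk_event("mismatch", 100, 100), mk_event("mismatch", 107, 107)]
        assert cluster_events(evs, 5) == [[evs[0]], [evs[1]]]

    def test_chaining_is_transitive(self):
        evs = [mk_event("mismatch", p, p) for p in (100, 105, 110)]
        assert cluster_events(evs, 4) == [evs]  # 100-110 span far beyond l=4

    def test_insertion_adjacent_to_deletion_has_gap_zero(self):
        ins = mk_event("insertion", 100, 100)
        dele = mk_event("deletion", 101, 102)
        assert cluster_events([ins, dele], 0) == [[ins, dele]]

    def test_matches_pairwise_merge_fixed_point_oracle(self, rng):
        for _ in range(1000):
            events = random_events(rng)
            l = rng.randint(0, 10)
            assert cluster_events(events, l) == oracle_clusters(events, l)


class TestWindowToCandidate:
    def test_contiguous_mnv_no_net_change(self):
        # same class as chr1 delTTinsCC: ref TT -> read CC
        aln = refined([("M", 8)], "AAACCAAA", "AAATTAAA", ref_start=101)
        events = extract_events(aln)
        (cluster,) = cluster_events(events, 5)
        cand = window_to_candidate(cluster, aln)
        assert cand is not None
        assert (cand.ref_start, cand.ref_allele, cand.alt_allele) == (104, "TT", "CC")
        assert cand.n_ops == 2

    def test_net_deletion_delins(self):
        # same class as chr3 delGGinsC: 2-base deletion plus adjacent mismatch
        aln = refined([("M", 3), ("D", 2), ("M", 4)], "AAACTTT", "AAAGGCTTT", ref_start=11)
        # make read base after the deletion a mismatch: ref C -> read C is match;
        # use a read carrying X next to D instead
        aln = refined([("M", 3), ("D", 2), ("M", 4)], "AAACTTT", "AAAGGGTTT", ref_start=11)
        events = extract_events(aln)
        (cluster,) = cluster_events(events, 5)
        cand = window_to_candidate(cluster, aln)
        assert cand is not None
        assert (cand.ref_start, cand.ref_allele, cand.alt_allele) == (14, "GGG", "C")
        assert len(cand.alt_allele) < len(cand.ref_allele)  # net deletion

    def test_net_insertion_delins(self):
        # same class as chr15 delCACCinsACACT
        # ref 23-26 CACC; read carries ACAC over it plus an inserted T
        aln = refined([("M", 6), ("I", 1), ("M", 2)], "AAACACTGG", "AACACCGG", ref_start=21)
        events = extract_events(aln)
        (cluster,) = cluster_events(events, 5)
        cand = window_to_candidate(cluster, aln)
        assert cand is not None
        assert (cand.ref_start, cand.ref_allele, cand.alt_allele) == (23, "CACC", "ACACT")

    def test_singleton_single_base_mismatch_rejected(self):
        aln = refined([("M", 8)], "AAACAAAA", "AAATAAAA")
        (cluster,) = cluster_events(extract_events(aln), 5)
        assert window_to_candidate(cluster, aln) is None

    def test_two_base_mismatch_run_counts_two_operations(self):
        # one X run of length 2 is a contiguous MNV and must qualify
        aln = refined([("M", 8)], "AAACCAAA", "AAATTAAA")
        (cluster,) = cluster_events(extract_events(aln), 5)
        assert len(cluster) == 1  # one multi-base mismatch event
        cand = window_to_candidate(cluster, aln)
        assert cand is not None and cand.n_ops == 2

    def test_matched_bases_between_events_are_copied(self):
        aln = refined([("M", 9)], "AACAACAAA", "AATAATAAA", ref_start=1)
        (cluster,) = cluster_events(extract_events(aln), 5)
        cand = window_to_candidate(cluster, aln)
        assert (cand.ref_allele, cand.alt_allele) == ("TAAT", "CAAC")

    def test_mean_alt_qual_over_window_bases(self):
        aln = refined(
            [("M", 6)], "AACCAA", "AATTAA", quals=[10, 10, 20, 30, 10, 10]
        )
        (cluster,) = cluster_events(extract_events(aln), 5)
        cand = window_to_candidate(cluster, aln)
        assert cand.mean_alt_qual == pytest.approx(25.0)


class TestAggregate:
    def test_identical_candidates_group_into_one_call(self):
        aln = refined([("M", 8)], "AAACCAAA", "AAATTAAA")
        (cluster,) = cluster_events(extract_events(aln), 5)
        cands = []
        for rid in ("a", "b", "c"):
            c = window_to_candidate(cluster, aln)
            cands.append(type(c)(**{**c.__dict__, "read_id": rid}))
        (call,) = aggregate_candidates(cands)
        assert call.allele_depth == 3

    def test_distinct_alt_alleles_stay_separate_calls(self):
        # two different alleles over one span, as seen in multi-clone samples
        a1 = refined([("M", 8)], "AAACCAAA", "AAATTAAA")
        a2 = refined([("M", 8)], "AAAGCAAA", "AAATTAAA")
        a2.read_id = "r2"
        cands = [
            window_to_candidate(cluster_events(extract_events(a), 5)[0], a)
            for a in (a1, a2)
        ]
        calls = aggregate_candidates(cands)
        assert len(calls) == 2
        assert {c.alt_allele for c in calls} == {"CC", "GC"}

    def test_allele_depth_equals_counting_oracle(self, rng):
        aln = refined([("M", 8)], "AAACCAAA", "AAATTAAA")
        (cluster,) = cluster_events(extract_events(aln), 5)
        base = window_to_candidate(cluster, aln)
        read_ids = [f"r{rng.randint(0, 20)}" for _ in range(200)]
        cands = [type(base)(**{**base.__dict__, "read_id": rid}) for rid in read_ids]
        (call,) = aggregate_candidates(cands)
        assert call.allele_depth == len(set(read_ids))


def mk_call(af=0.5, depth=100, qual=35.0):
    ad = max(1, int(round(af * depth)))
    return ComplexIndelCall(
        chrom="c1", pos=10, ref_end=11, ref_allele="TT", alt_allele="CC",
        allele_depth=ad, mean_qual=qual, n_ops=2, total_depth=depth, af=af,
    )


class TestFilters:
    def test_af_below_germline_threshold_is_marked(self):
        call = apply_filters(mk_call(af=0.19), FilterConfig(min_af=0.2))
        assert call.filters == {"low_af"}

    def test_af_above_somatic_threshold_passes(self):
        call = apply_filters(mk_call(af=0.021), FilterConfig(min_af=0.02))
        assert call.is_pass

    def test_vacuous_thresholds_pass_everything(self):
        cfg = FilterConfig(min_af=0.0, min_depth=0, min_qual=0.0)
        for call in (mk_call(0.01, 5, 3.0), mk_call(1.0, 10000, 40.0)):
            assert apply_filters(call, cfg).is_pass

    def test_each_threshold_marks_its_own_filter(self):
        cfg = FilterConfig(min_af=0.2, min_depth=200, min_qual=20.0)
        call = apply_filters(mk_call(af=0.1, depth=100, qual=10.0), cfg)
        assert call.filters == {"low_af", "low_depth", "low_qual"}

    def test_pass_set_shrinks_as_thresholds_rise(self):
        calls = [mk_call(af, 100, q) for af in (0.05, 0.3, 0.9) for q in (15.0, 35.0)]

        def pass_set(cfg):
            return {
                i for i, c in enumerate(calls) if apply_filters(c, cfg).is_pass
            }

        weak = pass_set(FilterConfig(min_af=0.02, min_qual=10))
        mid = pass_set(FilterConfig(min_af=0.2, min_qual=10))
        strong = pass_set(FilterConfig(min_af=0.2, min_qual=20))
        assert strong <= mid <= weak


class TestPipeline:
    def test_clean_reads_produce_zero_calls(self, simulated):
        spec = SimulationSpec(contig_length=3000, read_length=100, mean_depth=20, seed=5)
        fasta, bam, _, _ = simulated(spec)
        calls, stats = call_complex_indels(bam, fasta)
        assert calls == []
        assert stats["candidates"] == 0

    def test_uniform_coverage_depth_is_exact_mid_contig(self, simulated):
        import pysam

        spec = SimulationSpec(contig_length=2000, read_length=100, mean_depth=100, seed=7)
        fasta, bam, _, _ = simulated(spec)
        with pysam.AlignmentFile(str(bam)) as fh:
            for pos in (900, 1000, 1100):
                assert compute_total_depth(fh, "sim1", pos) == 100
            with pytest.raises(ValueError, match="off the contig"):
                compute_total_depth(fh, "sim1", 5000)

    def test_engineered_delins_round_trip_at_full_vaf(self, simulated):
        spec = SimulationSpec(contig_length=4000, read_length=150, mean_depth=50, seed=11)
        from cisindel.simulate import make_reference

        # need the sequence before choosing the variant, so build in two steps
        fasta, bam, logs, seq = simulated(spec)
        pos = find_motif(seq, "TT", 2000)
        spec.variants = [EngineeredVariant("sim1", pos, pos + 1, "TT", "GC")]
        fasta, bam, logs, seq = simulated(spec, name="ds2")
        calls, _ = call_complex_indels(bam, fasta)
        assert [(c.pos, c.ref_allele, c.alt_allele) for c in calls] == [(pos, "TT", "GC")]
        (call,) = calls
        assert call.is_pass
        assert call.allele_depth == len(logs[0].edited)

    def test_isolated_snvs_never_produce_calls(self, tmp_path):
        import pysam

        from cisindel.simulate import SimulationSpec, make_reference

        spec = SimulationSpec(contig_length=2000, read_length=150, mean_depth=1, seed=13)
        fasta = tmp_path / "iso.fa"
        seq = make_reference(spec, fasta)
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "sim1", "LN": 2000}]}
        )
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        segs = []
        for i in range(50):
            start = 10 * i
            bases = list(seq[start : start + 150])
            for off in range(7, 150, 10):  # SNVs 10 bp apart: gap 9 > l=5
                bases[off] = flip[bases[off]]
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"iso_{i}"
            seg.reference_id = 0
            seg.reference_start = start
            seg.mapping_quality = 60
            seg.query_sequence = "".join(bases)
            seg.query_qualities = [35] * 150
            seg.cigartuples = [(0, 150)]
            segs.append(seg)
        bam = tmp_path / "iso.bam"
        with pysam.AlignmentFile(str(bam), "wb", header=header) as out:
            for seg in segs:
                out.write(seg)
        pysam.index(str(bam))
        calls, stats = call_complex_indels(bam, fasta)
        assert calls == []

    def test_contig_name_mismatch_is_fatal(self, simulated, tmp_path):
        spec = SimulationSpec(contig_length=1000, read_length=100, mean_depth=5, seed=17)
        fasta, bam, _, seq = simulated(spec)
        other = tmp_path / "other.fa"
        other.write_text(">not_sim1\n" + seq + "\n")
        import pysam

        pysam.faidx(str(other))
        with pytest.raises(ValueError, match="absent from"):
            call_complex_indels(bam, other)

    def test_duplicate_and_secondary_reads_are_ignored(self, tmp_path):
        import pysam

        from cisindel.simulate import SimulationSpec, make_reference

        spec = SimulationSpec(contig_length=1000, read_length=100, mean_depth=1, seed=19)
        fasta = tmp_path / "fl.fa"
        seq = make_reference(spec, fasta)
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "sim1", "LN": 1000}]}
        )
        bases = list(seq[100:200])
        bases[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bases[50]]
        bases[52] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bases[52]]
        segs = []
        for i, flag in enumerate([0, 1024, 256]):  # primary, duplicate, secondary
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"d_{i}"
            seg.flag = flag
            seg.reference_id = 0
            seg.reference_start = 100
            seg.mapping_quality = 60
            seg.query_sequence = "".join(bases)
            seg.query_qualities = [35] * 100
            seg.cigartuples = [(0, 100)]
            segs.append(seg)
        bam = tmp_path / "fl.bam"
        with pysam.AlignmentFile(str(bam), "wb", header=header) as out:
            for seg in segs:
                out.write(seg)
        pysam.index(str(bam))
        calls, stats = call_complex_indels(bam, fasta)
        assert stats["reads_skipped_flags"] == 2
        (call,) = calls
        assert call.allele_depth == 1 and call.total_depth == 1
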