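# Methods

## Model and procedure

`cisindel` treats each read alignment as one haplotype observation. A
complex indel (delins) manifests, after gapped alignment, as a cluster of
closely spaced mismatches, insertions and deletions *in cis* on individual
reads; the caller detects exactly that signature and reports the cluster as
a single allele rather than decomposed per-position calls.

The pipeline per read is: refine CIGAR `M` runs into `=`/`X` runs by
base-wise comparison against the reference FASTA; extract variant events
(one per `X` run, `I` run, `D` run); chain events whose reference gap —
bases strictly between one event's end and the next event's start — is at
most `max_distance` *l*; and accept a window as a candidate when it carries
at least two variant operations and `max(len(REF), len(ALT)) >= 2`.
Candidates identical in (chrom, span, ALT) are aggregated across reads into
a call with allele depth, total depth, allele frequency and mean alt base
quality, then marked or removed by the quality/depth/AF filters.

### Operation counting

The ≥2-operation rule counts **each mismatched base** as one operation, and
each insertion or deletion run as one. This reflects per-base refinement of
`M`: a contiguous 2-base MNV (e.g. `TT>CC`) is two `X` operations and
qualifies on its own, which is required for the MNV class to be callable at
all. Internally adjacent mismatch columns are stored as one multi-base
mismatch event; the event carries its own operation multiplicity.

### Coordinates and gap metric

Reference coordinates are 1-based inclusive (VCF/HGVS convention)
everywhere except read indexing, which uses 0-based offsets. Insertions are
anchored at the reference base immediately to their left, so an insertion
directly adjacent to a deletion has gap 0 and always chains. The gap is
measured in reference coordinates: this makes windows reproducible across
read orientations and differs from a read-coordinate metric only around
long indels.

### Alleles and normalization

The REF allele spans the first to last affected reference base of the
window; the ALT allele is the read bases aligned across that span
(mismatch bases substituted, inserted bases included, deleted bases
omitted, intervening matched bases copied). Calls are **not**
left-normalized or re-aligned: they are reported at aligner coordinates,
preserving direct HGVS delins correspondence. The sensitivity evaluator
compares variants after trimming common flanking bases (suffix first, then
prefix, adjusting POS), so cosmetically padded truth records still match.

### Depth and AF

Total depth at POS counts primary, mapped, non-duplicate, non-QC-fail
reads whose aligned span covers POS, fetched directly from the BAM index
with no pileup engine and hence no depth cap below `max_pileup_depth`
(default 10^6); deep amplicon piles (>8000X) are counted exactly. AF uses
the depth at the call's leftmost position, giving one well-defined
denominator per call. Reads overlapping a window only partially contribute
to DP but not AD, so an allele engineered into 100% of spanning reads shows
AF slightly below 1 at shotgun-style coverage; this is a property of the
denominator definition, not a calling loss.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_distance` (*l*) | 5 | max reference gap (bases) chained between in-cis events; 10 is the usual whole-genome setting |
| `min_qual` | 20 | Phred floor on the call-level mean alt base quality; a conventional floor, as call-level quality gating has no canonical default |
| `min_af` | 0 | AF floor; 0.2 typical for germline, 0.02 for somatic panels |
| `min_depth` | 0 | DP floor; 20 typical for whole-genome data |
| `skip_low*` | off | remove rather than mark filtered calls |
| `max_pileup_depth` | 1,000,000 | safety bound on depth counting |

Filters default to mark-don't-remove so that downstream tools see the full
call set with FILTER annotations.

## Mutation engineer

Given a delins and alignments, every primary read fully spanning the
variant span (or a seeded random subset of exactly `round(vaf * n)` reads
for a target VAF < 1) has its bases across the span replaced by the ALT
allele; the CIGAR is rewritten as `min(len)M` plus the residual `I` or `D`
— a consistent, not necessarily optimal, alignment that downstream
re-alignment would tidy. Base qualities follow the net gain in bases:
net gain ≤ 0 reuses the original qualities positionally (truncated for
deletions), net gain ≥ 1 assigns every alt base the rounded mean Phred of
up to `flank_w = 5` read bases on each side of the span ("similar to the
flanking bases"); 5 is the minimal local reading of that idea. Reads
partially overlapping a length-changing span have no well-defined partial
edit and are left unmodified but enumerated in the edit log, so truth
accounting stays exact. The REF allele is checked against the reference
FASTA before any read is touched.

## Synthetic data generator

The simulator emulates the two study designs this class of caller targets:
shotgun-style uniform coverage and fixed-start deep amplicons. Reads are
written pre-aligned with all-`M` CIGARs at known positions — deliberately
unrefined so the refinement stage is always exercised — with a constant or
per-cycle base-quality profile, seeded uniform substitution errors, and
variants spiked in through the engineer itself, which keeps the truth
manifest and the caller byte-comparable. Shotgun coverage uses phased
tiling (`mean_depth` phases of end-to-end reads, phase *k* shifted by
`k·read_length/mean_depth`), so mid-contig coverage is exactly
`mean_depth`; default conditions are 150 bp reads at 50X, error-free, Q35,
VAF 1.0, matching the semi-simulation design of engineering each variant
into clean spanning reads. Amplicon mode emits `mean_depth` identical-span
reads per start and is used at 9000X to exercise exact deep-depth counting.

What the generator does **not** emulate: indel sequencing errors, quality
decay along the read, paired-end structure, alignment ambiguity or
soft-clip rescue, GC or mappability bias. Passing tests therefore
demonstrate the correctness of refinement, chaining, allele construction,
aggregation, filtering and the engineering rules — not robustness to
aligner artifacts on real data, where re-alignment of engineered FASTQ
(the `--fastq` output exists for this) is the appropriate harness.

## Numerical and edge-case choices

- `N` in read or reference compares as mismatch (conservative); soft-clipped
  bases are never inspected; windows reaching outside the aligned span are
  rejected and logged.
- Deletion events carry the qualities of the two flanking read bases;
  pure-deletion windows fall back to those flanks for the mean quality.
- Aggregated mean quality is the unweighted mean of per-read window means;
  ties in output order are broken by (BAM header contig order, POS, REF,
  ALT), making output bytes deterministic.
- Multi-allelic loci are emitted as separate VCF records, never folded into
  one multi-ALT line, so each allele keeps its own AD/AF.
- The VCF writer emits text directly (deterministic bytes); validity is
  cross-checked in tests with two independent parsers (pysam, cyvcf2).
- All randomness (simulator, error injection, VAF subsampling) flows from
  a single integer seed; identical seeds give identical BAM records.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
contigs of 1–8 kb, 100–150 bp reads, 25–400X shotgun coverage, one 9000X
amplicon, 15 single-variant read sets for the allele-shape panel, and 1000
randomized instances for each brute-force oracle comparison (clustering
fixed point; column-walk refinement/reconstruction). The full suite runs in
a few seconds on one CPU.

## Known limitations

- No re-alignment or soft-clip rescue: an allele the aligner represents as
  clipping rather than in-cis events is invisible (by design, out of scope).
- Single-sample calling only; no tumor-normal subtraction, no genotyping
  (records carry no FORMAT/sample columns), no phasing across read pairs.
- Single-operation events (isolated SNVs, simple indels) are deliberately
  never reported; this is a complement to, not a replacement for, a
  general-purpose caller.
- AF at loci where many reads only partially overlap a long allele is
  conservatively biased low by the DP definition (see above).
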