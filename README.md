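# cisindel

Whole-read detection of **complex insertions and deletions** (delins) from
SAM/BAM alignments.

Complex indels — a simultaneous deletion and insertion at one locus, with a
net loss of bases, a net gain, or no length change at all (a
multiple-nucleotide variant, MNV) — are systematically missed by
conventional variant callers. Pileup-based callers examine one reference
position at a time across reads and so lose the haplotype: a delins aligned
by BWA-MEM as a cluster of mismatches, insertions and deletions is broken
into separate SNV/indel calls or discarded outright. In disease genes such
as *BRCA1/BRCA2* (germline) or *CALR*, *JAK2* and *KIT* (somatic), that
means pathogenic alleles are dropped or mis-annotated — an MNV decomposed
into independent SNVs can gain or lose a predicted protein truncation.

`cisindel` takes the opposite approach: **each read alignment is examined
as a whole**. Variants observed *in cis* on one read are one haplotype
observation, and closely spaced clusters of them are reported as a single
delins call.

## Algorithm

For every primary, mapped, non-duplicate read:

1. **CIGAR refinement.** Aligner `M` runs (match-or-mismatch) are resolved
   against the reference FASTA into maximal `=` (match) and `X` (mismatch)
   runs.
2. **Event extraction.** The refined alignment is scanned once for variant
   events: mismatch runs, insertions (`I`) and deletions (`D`), with
   reference/read coordinates and base qualities.
3. **Chaining.** Consecutive events at most *l* reference bases apart
   (default *l* = 5, `--max_distance`) are chained transitively into
   windows.
4. **Window rule.** A window qualifies as a complex indel call when it
   contains at least two variant operations (each mismatched base, `I` run
   or `D` run counts one) and spans at least two nucleotides on the
   reference or the read. The REF allele is the reference over the window,
   the ALT allele the read bases aligned across it.
5. **Aggregation and filtering.** Identical alleles are aggregated across
   reads: allele depth AD = supporting reads, total depth DP = reads
   covering POS (counted without any pileup cap, so >8000X amplicon data is
   handled exactly), allele frequency AF = AD/DP. Calls are marked — or
   removed with `--skip_lowqual/--skip_lowdepth/--skip_lowaf` — when mean
   alt base quality, DP, or AF fall below `--min_qual/--min_depth/--min_af`.

Calls are written as VCF 4.1 delins records (non-empty REF and ALT, no
anchor-base padding), one record per allele so co-located alleles from
different clones each keep their own AD/AF.

The package also ships the semi-simulation tooling used to validate this
kind of caller: a **mutation engineer** that writes a specified variant
into existing alignments at a target VAF (base qualities kept unchanged
when the net gain in bases is 0 or negative, borrowed from the flanking
bases when positive), a hermetic **read simulator** with a truth manifest,
and a **sensitivity evaluator**.

## Worked example

Simulate a 3 kb contig at 50X with two engineered delins alleles — an MNV
(`TT>CC`) and a net deletion (`GT>C`) — then call with the germline
profile and score sensitivity against the truth manifest:

```bash
cisindel simulate --fasta-out ref.fa --bam-out reads.bam --truth-out truth.tsv \
    --contig-length 3000 --depth 50 --seed 7 \
    --variant 1404:TT:CC --variant 2001:GT:C
cisindel call reads.bam ref.fa -o calls.vcf \
    --skip_lowqual --skip_lowdepth --skip_lowaf --min_af 0.2
cisindel evaluate truth.tsv calls.vcf
```

which prints:

```text
#CHROM  POS   ID  REF  ALT  QUAL  FILTER  INFO
sim1    1404  .   TT   CC   35.0  PASS    DP=50;AD=49;AF=0.9800;NOPS=2;SPAN=1405
sim1    2001  .   GT   C    35.0  PASS    DP=50;AD=49;AF=0.9800;NOPS=2;SPAN=2002

sensitivity     1.0000  (2 of 2)
```

Both engineered alleles are recovered at the exact position and allele.
AF is 0.98, not 1.00, because one of the 50 reads covering each locus only
partially overlaps the variant span: it is left unedited by design (partial
edits of a length-changing allele are not well defined) but still counts in
DP. `NOPS=2` records the two variant operations in each window (two
mismatched bases for the MNV; one mismatch plus one deletion for `GT>C`).

Typical filter profiles: `--skip_lowqual --skip_lowdepth --skip_lowaf`
with `--min_af 0.2` for germline amplicon panels, `--min_af 0.02` for
somatic panels, and `--max_distance 10 --min_af 0.2 --min_depth 20` for
whole-genome data.

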