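# Methods

## Model and assumptions

A CRISPR-Cas9-edited single-cell clone sequenced by deep amplicon
sequencing is modeled as a categorical mixture: each read is an exact copy
of one of a small number of allele haplotypes (the reference window with
0–n indels near the cut site), corrupted by rare random errors. Two error
channels matter in practice and are the only ones modeled: per-base
substitutions (polymerase and sequencer point errors) and rare spurious
1-bp indels. Under this model the dominant unique read sequences are the
exact haplotypes, each recurring thousands of times, while error reads are
spread over a long tail of near-unique sequences — which is why a simple
occurrence-count cutoff separates signal from noise without any quality
filtering.

Key assumptions: reads span the whole amplicon (single-end reads at least
as long as the window, or overlapping paired-end mates joined first);
inputs are already demultiplexed, one sample per FASTQ (or R1/R2 pair); a
"bulk population" file is just a sample with many low-frequency
signatures.

## Pipeline conventions

- **Coordinates** are 1-based inclusive at every module boundary, matching
  region notation (`chr21:34715869-34716164`) and VCF. Chromosome names
  must match FASTA record ids exactly; no `chr21`/`21` aliasing.
- **Uniqueness** is exact full-length string identity — no trimming, no
  N-masking, no reverse-complement merging (orientation is resolved by the
  aligner). Sum of unique counts always equals the processed-read count.
- **Cutoff** is inclusive: `count >= cutoff` retains the read; cutoff 0
  retains everything, so cutoffs 0 and 1 are equivalent.
- **Total-read denominator**: proportions divide by the sample's processed
  reads — all reads for single-end data, successfully joined pairs for
  paired-end (unjoined pairs are dropped and logged). Retained reads whose
  alignment fails the quality filter stay in both the total and the
  retained denominators but contribute no genotype.
- **Major threshold** is inclusive: a signature at exactly 1.0 % of total
  reads is major.

## Alignment

Local Smith–Waterman with affine gaps (Gotoh three-state recursion),
implemented in-repo with a numba kernel so results are bit-reproducible
with no external aligner. Defaults are the classic nucleotide scoring:
match +2, mismatch −3, gap open 5, gap extend 2 (a length-*L* gap costs
`5 + 2L`); all four are configurable. Both orientations are scored and the
better one kept (ties to the forward strand). N matches nothing.

Tie-breaking is fixed because the genotype signature depends on it: each
DP state tracks the minimum number of gap openings among optimal paths, so
equal-scoring alignments prefer fewer gap openings; the end cell with the
smallest reference coordinate is chosen among score ties; diagonal moves
are preferred during traceback. Residual indel-placement ambiguity is
canonicalized downstream by left-normalization, which makes the remaining
tie-break choices invisible in the output.

Alignment quality filters: `min_aligned_frac` 0.5 (fraction of the read
inside the local alignment) and `min_identity` 0.7 (matches over non-gap
columns) — permissive enough to keep large-deletion alleles, strict enough
to drop chimeras and junk reads.

**Recoverable deletion size is bounded by flank length.** A local aligner
bridges a deletion of *d* bases only when the shorter flanking match run
gains more than the gap costs: with match +2, open 5, extend 2 the flank
must exceed `(5 + 2d)/2` ≈ *d* + 2.5 bases. In a 296-bp window a centered
deletion up to ~95 bp is bridged; recovering a 200-bp deletion requires an
amplicon giving both flanks ≥ ~203 bp. This is a property of local
alignment itself (external local aligners behave the same), not of this
implementation; tests exercising 200-bp deletions therefore use a 700-bp
window. Deletions well beyond 40 bp are recovered whenever the amplicon
design leaves adequate flanks.

## Indel signatures and VCF normalization

Each insertion/deletion run in the alignment becomes a raw indel; each raw
indel is left-aligned (shifted left while the base before the event equals
its last base) and anchored on the preceding base, yielding a pure
anchored `CHR-POS-REF-ALT` record; the operation is idempotent and an
indel abutting the window's left edge is emitted right-anchored and
flagged. A read's **signature** is its position-sorted set of normalized
indels; the empty set is wild type. Substitutions are deliberately
excluded — they are overwhelmingly amplification/sequencing errors at this
depth, and excluding them makes two reads of the same allele with
different point errors genotype identically. Overlapping indels on one
read are kept verbatim and the signature flagged complex rather than
merged, since no principled merge rule exists.

The genotype unit is the per-read signature (all indels on the read), not
individual indels tallied independently: within an amplicon the signature
preserves phasing, so signature counts correspond to allele counts and can
be compared against the locus copy number of the cell line. Individual
variants still appear as separate VCF records, linked by a shared `SIGID`
INFO key (VCF has no native haplotype-call record; this convention is the
documented bridge).

## Proportions under the cutoff

`proportion = supporting retained reads / total reads`. At cutoff 0 this
estimates allele dosage directly (substitution-bearing reads still carry
the allele's indel signature and are counted). At high cutoffs only exact
haplotype copies are retained, so the expected proportion shrinks to
dosage × the error-free read probability `(1 − e)^L` (≈ 0.41 at
0.3 %/base over 296 bp). Relative proportions between alleles of similar
length are unaffected, and the major/minor classification is robust
because the 1 % threshold sits far below any real allele's scaled
proportion. Users comparing proportions across cutoffs should compare
ratios, or run at cutoff 0.

## Simulator

`amplicall.simulate` generates the study conditions used throughout the
tests: clones of 50,000–70,000 single-end full-amplicon reads over a
296-bp window; 2–4 alleles per clone (one 10-allele outlier clone per
cohort, emulating polyclonality or prolonged editing); NHEJ-like outcome
spectrum (deletions of 1–15 bp dominating, occasional 1–3-bp insertions,
events starting within ~10 bp of the cut site); substitution errors at
0.3 %/base; spurious 1-bp indels on 0.5 % of reads; ~3 % unalignable junk
reads per cohort clone. Qualities are constant ('I'): the pipeline reads
quality only at pair-merge mismatches. All randomness flows through one
seed; identical specs give byte-identical FASTQ.

What the simulator does **not** emulate: position- and quality-dependent
error curves, homopolymer-specific indel error enrichment, unaligned
read-end artifacts, PCR chimeras, coverage bias, and contamination between
samples. Passing tests therefore demonstrate correctness of the pipeline's
logic under a clean mixture-plus-noise model, not robustness to every
artifact of a real sequencing run.

## Numerical and degenerate-input choices

- Calls are sorted by descending proportion, ties lexicographically by
  signature text; matrix columns by total support, ties by key.
- Proportions print with 4 decimals in tables, 1 decimal as percentages in
  plots.
- Zero retained reads yields an empty report (warning, not an error); an
  empty FASTQ is an empty sample; a read aligning nowhere scores 0 with no
  ops and is filtered, never an exception.
- Pair joining picks the overlap with the lowest mismatch fraction (ties:
  longest overlap); at overlap mismatches the higher-quality base wins,
  mate 1 on ties or missing qualities.
- Plot and report writers embed no timestamps, so identical runs are
  byte-identical.

## Problem sizes used in the test and acceptance runs

Oracle checks run on hundreds of short random instances (reads/regions
≤ 30 bp against a brute-force explicit-gap DP; 500+ indels against
exhaustive equivalence-class enumeration). End-to-end checks use 20
simulated clones at 50,000 reads each and full cohort runs at 2,000–6,000
reads per clone; these sizes exercise every code path at realistic depth
while keeping a full validation run in the minutes range on one CPU.

## Known limitations

- One best local alignment per read: tandem duplications or chimeric reads
  spanning distant loci reduce to their single best hit.
- Substitution outcomes (base editing) and HDR knock-in matching are out
  of scope; so are frameshift/consequence annotation and genome-wide
  off-target discovery.
- Exact-match chromosome naming between region string and FASTA header is
  required by design.
- Proportions at high cutoffs underestimate absolute dosage as described
  above.
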