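# amplicall

Genotyping CRISPR-Cas9-edited cells from deep amplicon sequencing.

## The problem

Cas9 double-strand breaks are repaired mostly by nonhomologous end joining
(NHEJ), which leaves short random indels at the cut site. A single-cell
clone carries one editing outcome per allele — and loci are often not
diploid in common cell lines — so a clone's deep amplicon sequencing data
is a mixture of a few true allele haplotypes plus a long tail of
polymerase/sequencer error reads. `amplicall` turns a demultiplexed FASTQ
(or an R1/R2 pair, or one merged bulk-population file) per sample into an
allele-resolved genotype table in standard VCF `CHR-POS-REF-ALT` form.

## The method

For each sample:

1. **Collapse** reads by exact full-length identity into unique reads with
   occurrence counts; for paired-end data, mates are first joined by 3'
   overlap (minimum overlap 6, mismatch fraction ≤ 8 %).
2. **Cutoff**: retain unique reads with count ≥ *c* (default *c* = 30,
   inclusive; *c* = 0 retains everything). Error reads are spread thinly
   over many distinct sequences and rarely recur, so the cutoff — not
   quality filtering — removes them.
3. **Align** each retained unique read to the target window with an
   affine-gap Smith–Waterman/Gotoh local aligner in both orientations
   (match +2, mismatch −3, gap open 5, gap extend 2; a gap of length *L*
   costs `open + extend·L`).
4. **Signature**: extract the read's indels, left-normalize each to its
   smallest equivalent position (the VCF convention), and form the
   position-sorted indel set. Substitutions never enter signatures, so
   point errors cannot split an allele.
5. **Call**: sum supporting reads per signature; a signature is a **major
   genotype** when its support is ≥ 1 % of the sample's total processed
   reads (inclusive). The wild-type (empty) signature is callable like any
   other. The **read contribution to major genotypes** — reads supporting
   majors divided by reads retained — tells you whether the cutoff removed
   only error reads (contribution ≈ 1).

Outputs per run: a summary TSV, one VCF per sample (multi-indel signatures
linked via the `SIGID` INFO key), a per-sample genotype plot, a text
alignment of each major genotype against the wild-type sequence, and a
samples × genotypes proportion matrix for the cohort.

A ground-truth simulator (`amplicall.simulate`) generates clones as
mixtures of edited haplotypes with realistic substitution and spurious
1-bp-indel errors, so every pipeline stage is testable without downloads.

## Worked example

`python examples/01_genotype_one_clone.py` simulates a 296-bp amplicon, a
clone with three edited alleles at 40/35/25 %, and 20,000 reads with
0.3 %/base substitution error, then genotypes it:

```
sample clone: 20000 reads, 6871 unique, 8366 retained at cutoff 30
3 major genotypes (signatures supported by >= 1% of total reads):
  chrS-1146-GAC-G                          3339 reads   16.7%
  chrS-1143-AGAGACCTGGCCTT-A               3003 reads   15.0%
  chrS-1148-C-CT                           2024 reads   10.1%
read contribution to major genotypes: 1.000
```

The three called signatures are exactly the three simulated alleles (a
2-bp deletion, a 13-bp deletion, a 1-bp insertion, each left-normalized).
Proportions are fractions of *total* reads supported by *retained* unique
reads: at cutoff 30 only exact haplotype copies recur often enough to be
retained, so proportions equal allele dosage scaled by the error-free read
fraction (here ≈ 0.42); their ratios still track relative dosage, and a
read contribution of 1.000 shows the cutoff discarded only error reads.
See `docs/methods.md` for this and other conventions.

Other examples: `02_cutoff_sweep.py` (how retained reads, genotype counts
and read contribution move with the cutoff), `03_cohort_matrix.py` (the
cross-sample matrix), `04_paired_end_joining.py` (paired-end input).

The same pipeline is available from a shell:

```bash
amplicall simulate --out sim --seed 1 --n-clones 4 --reads 5000 8000
amplicall genotype --reference sim/reference.fasta --region chrS:1000-1295 \
    --fastq-dir sim --cutoff 30 --out results
```

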