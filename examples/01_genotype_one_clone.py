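"""Genotype one simulated CRISPR-edited clone end to end.

Builds a synthetic 296-bp amplicon, defines three edited alleles (two
deletions, one insertion) near the cut site, sequences the clone to 20,000
reads with realistic error rates, and runs the full pipeline: collapse ->
cutoff 30 -> align -> signatures -> major calls at >= 1 % of total reads.
"""

import tempfile
from pathlib import Path

from amplicall import GenotypeSignature
from amplicall.pipeline import PipelineConfig, genotype_files
from amplicall.simulate import (
    SimSpec,
    deletion_variant,
    insertion_variant,
    random_region,
    simulate_clone_fastq,
)

region = random_region(length=296, seed=11)
alleles = (
    (GenotypeSignature((deletion_variant(region, 148, 2),)), 0.40),
    (GenotypeSignature((deletion_variant(region, 145, 13),)), 0.35),
    (GenotypeSignature((insertion_variant(region, 150, "T"),)), 0.25),
)
spec = SimSpec(region=region, alleles=alleles, n_reads=20_000,
               error_rate=0.003, error_indel_rate=0.005, seed=7)

with tempfile.TemporaryDirectory() as td:
    sim = simulate_clone_fastq(spec, Path(td) / "clone.fastq")
    report = genotype_files(sim.fastq_paths, region, PipelineConfig(cutoff=30))

print(f"sample {report.sample_id}: {report.n_total_reads} reads, "
      f"{report.n_unique_reads} unique, {report.n_retained_reads} retained at cutoff {report.cutoff}")
print(f"{len(report.major_calls)} major genotypes "
      f"(signatures supported by >= 1% of total reads):")
for call in report.major_calls:
    print(f"  {call.signature.key:38s} {call.n_supporting:6d} reads  "
          f"{call.proportion * 100:5.1f}%")
print(f"read contribution to major genotypes: {report.read_contribution:.3f}")
print()
print("Each major signature is one edited allele in VCF CHR-POS-REF-ALT form;")
print("proportions track allele dosage scaled by the fraction of error-free")
print("reads, and a read contribution near 1 means the cutoff removed only")
print("error reads, not real alleles.")
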