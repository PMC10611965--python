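"""How the read-count cutoff shapes genotyping.

Sweeps the cutoff over one simulated clone and prints, per cutoff: the
fraction of reads retained, the number of distinct genotypes called, and
the read contribution to major genotypes. Error reads occur at low copy
number, so raising the cutoff prunes artifact genotypes (hundreds -> a
handful) while the major-genotype set never changes.
"""

import tempfile
from pathlib import Path

from amplicall import GenotypeSignature
from amplicall.pipeline import cutoff_sweep
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
spec = SimSpec(region=region, alleles=alleles, n_reads=20_000, seed=123)

with tempfile.TemporaryDirectory() as td:
    sim = simulate_clone_fastq(spec, Path(td) / "clone.fastq")
    reports = cutoff_sweep(sim.fastq_paths, region, [0, 1, 5, 10, 30, 50])

print("cutoff  retained%  genotypes  majors  read_contribution")
for cutoff, rep in reports.items():
    print(f"{cutoff:6d}  {100 * rep.n_retained_reads / rep.n_total_reads:8.1f}"
          f"  {len(rep.calls):9d}  {len(rep.major_calls):6d}"
          f"  {rep.read_contribution:17.4f}")
print()
print("Retained reads and genotype counts fall monotonically with the cutoff;")
print("the majors are invariant, and by cutoff 30 essentially every retained")
print("read supports a major genotype (contribution ~ 1).")
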