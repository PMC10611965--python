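"""A multi-clone cohort and its samples x genotypes matrix.

Simulates a small cohort of edited clones (allele signatures drawn partly
from a shared pool, so independent clones can carry the same repair
outcome), genotypes every clone, and prints the cohort proportion matrix —
the at-a-glance view used to pick clones with genotypes of interest.
"""

import tempfile
from pathlib import Path

from amplicall.pipeline import PipelineConfig, genotype_files
from amplicall.reporting import build_matrix
from amplicall.simulate import simulate_cohort

with tempfile.TemporaryDirectory() as td:
    cohort = simulate_cohort(Path(td) / "sim", seed=5, n_clones=6,
                             reads_range=(4000, 6000))
    config = PipelineConfig(cutoff=10)
    reports = [
        genotype_files(sim.fastq_paths, cohort.region, config, sample_id=name)
        for name, sim in sorted(cohort.clones.items())
    ]

matrix = build_matrix(reports, majors_only=True)
df = matrix.to_dataframe()
print(f"{len(matrix.sample_ids)} samples x {len(matrix.genotype_keys)} distinct major genotypes")
print(df.round(3).to_string())
print()
shared = [k for k in df.columns if (df[k] > 0).sum() > 1]
print(f"genotypes seen in more than one clone: {len(shared)}")
print("A nonzero cell is that sample's supporting-read proportion for the")
print("genotype; zero means the genotype was not called in that sample.")
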