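import numpy as np
import pytest

from amplicall.errors import SimSpecError
from amplicall.genotyping import GenotypeSignature, IndelVariant
from amplicall.pipeline import PipelineConfig, genotype_files
from amplicall.read_prep import collapse_unique, join_pairs, read_fastq
from amplicall.reference_io import ReferenceRegion
from amplicall.simulate import (
    SimSpec,
    apply_signature,
    deletion_variant,
    insertion_variant,
    random_region,
    simulate_clone_fastq,
    simulate_cohort,
)


class TestApplySignature:
    def test_empty_signature_is_reference(self, tiny_region):
        assert apply_signature(tiny_region, GenotypeSignature()) == tiny_region.sequence

    def test_deletion_example(self, tiny_region):
        v = IndelVariant("chrT", 2, "CA", "C")
        assert apply_signature(tiny_region, GenotypeSignature((v,))) == "GCAAT"

    def test_overlapping_variants_rejected(self, region296):
        a = deletion_variant(region296, 150, 5)
        b = deletion_variant(region296, 152, 2)
        with pytest.raises(SimSpecError):
            apply_signature(region296, GenotypeSignature(tuple(sorted((a, b)))))

    def test_ref_mismatch_rejected(self, tiny_region):
        with pytest.raises(SimSpecError):
            apply_signature(
                tiny_region, GenotypeSignature((IndelVariant("chrT", 2, "CT", "C"),))
            )

    def test_pipeline_round_trip_at_zero_error(self, region296, tmp_path):
        """Apply signatures, sequence without error, re-genotype: exact recovery."""
        sigs = (
            GenotypeSignature((deletion_variant(region296, 148, 2),)),
            GenotypeSignature((insertion_variant(region296, 150, "TAG"),)),
            GenotypeSignature(
                (deletion_variant(region296, 120, 1), deletion_variant(region296, 170, 4))
            ),
        )
        spec = SimSpec(
            region=region296,
            alleles=tuple(zip(sigs, (0.5, 0.3, 0.2))),
            n_reads=5000,
            error_rate=0.0,
            error_indel_rate=0.0,
            seed=7,
        )
        result = simulate_clone_fastq(spec, tmp_path / "c.fastq")
        report = genotype_files(result.fastq_paths, region296, PipelineConfig(cutoff=30))
        assert sorted(c.signature.key for c in report.major_calls) == sorted(
            s.key for s in sigs
        )
        by_key = {c.signature.key: c for c in report.calls}
        for sig, realized in zip(sigs, result.realized_counts):
            assert by_key[sig.key].n_supporting == realized


class TestSimulateClone:
    def test_seed_determinism_byte_identical(self, region296, tmp_path):
        sigs = (GenotypeSignature((deletion_variant(region296, 148, 2),)),)
        spec = SimSpec(region=region296, alleles=((sigs[0], 1.0),), n_reads=500, seed=7)
        a = simulate_clone_fastq(spec, tmp_path / "a.fastq")
        b = simulate_clone_fastq(spec, tmp_path / "b.fastq")
        assert a.fastq_paths[0].read_bytes() == b.fastq_paths[0].read_bytes()

    def test_zero_error_wt_reads_identical_to_region(self, region296, tmp_path):
        spec = SimSpec(
            region=region296, alleles=((GenotypeSignature(), 1.0),),
            n_reads=200, error_rate=0.0, error_indel_rate=0.0, seed=7,
        )
        result = simulate_clone_fastq(spec, tmp_path / "wt.fastq")
        seqs = {r.sequence for r in read_fastq(result.fastq_paths[0])}
        assert seqs == {region296.sequence}

    def test_realized_counts_conserve_and_track_targets(self, region296, tmp_path):
        sigs = (
            GenotypeSignature((deletion_variant(region296, 148, 2),)),
            GenotypeSignature((insertion_variant(region296, 150, "T"),)),
        )
        n = 10_000
        spec = SimSpec(
            region=region296, alleles=tuple(zip(sigs, (0.6, 0.4))), n_reads=n, seed=42
        )
        result = simulate_clone_fastq(spec, tmp_path / "c.fastq")
        assert sum(result.realized_counts) == n
        for p, count in zip((0.6, 0.4), result.realized_counts):
            assert abs(count - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_paper_scale_collapse_conserves_reads(self, region296, tmp_path):
        """56,269 reads from 4 haplotypes + errors: unique counts sum exactly."""
        sigs = tuple(
            GenotypeSignature((deletion_variant(region296, 140 + 3 * k, k + 1),))
            for k in range(4)
        )
        spec = SimSpec(
            region=region296,
            alleles=tuple(zip(sigs, (0.25, 0.25, 0.25, 0.20))),
            n_reads=56_269,
            seed=1,
        )
        result = simulate_clone_fastq(spec, tmp_path / "s1.fastq")
        uniques = collapse_unique(read_fastq(result.fastq_paths[0]))
        assert sum(u.count for u in uniques) == 56_269

    def test_major_signatures_recovered_under_sequencing_error(self, region296, tmp_path):
        """With realistic substitution and spurious-indel error, the major
        genotype set at cutoff 30 is exactly the simulated allele set (the
        cutoff absorbs error reads; substitutions never alter signatures)."""
        sigs = (
            GenotypeSignature((deletion_variant(region296, 148, 2),)),
            GenotypeSignature((deletion_variant(region296, 140, 14),)),
            GenotypeSignature((insertion_variant(region296, 150, "TT"),)),
        )
        spec = SimSpec(
            region=region296,
            alleles=tuple(zip(sigs, (0.45, 0.30, 0.25))),
            n_reads=20_000,
            error_rate=0.003,
            error_indel_rate=0.005,
            seed=99,
        )
        result = simulate_clone_fastq(spec, tmp_path / "noisy.fastq")
        report = genotype_files(result.fastq_paths, region296, PipelineConfig(cutoff=30))
        assert sorted(c.signature.key for c in report.major_calls) == sorted(
            s.key for s in sigs
        )
        # ranking by support preserves the allele ranking
        called = [c.signature.key for c in report.major_calls]
        assert called[0] == sigs[0].key

    def test_truth_table_written(self, region296, tmp_path):
        sigs = (GenotypeSignature((deletion_variant(region296, 148, 2),)),)
        spec = SimSpec(region=region296, alleles=((sigs[0], 0.9),), n_reads=100, seed=3)
        result = simulate_clone_fastq(spec, tmp_path / "t.fastq")
        lines = result.truth_path.read_text().splitlines()
        assert lines[0].startswith("allele_id")
        assert lines[1].split("\t")[1] == sigs[0].key

    def test_paired_mates_rejoin_to_fragment(self, region296, tmp_path):
        spec = SimSpec(
            region=region296, alleles=((GenotypeSignature(), 1.0),),
            n_reads=100, error_rate=0.0, error_indel_rate=0.0,
            read_length=250, paired=True, seed=5,
        )
        result = simulate_clone_fastq(spec, tmp_path / "p.fastq")
        r1 = list(read_fastq(result.fastq_paths[0]))
        r2 = list(read_fastq(result.fastq_paths[1]))
        joined, n_unjoined = join_pairs(r1, r2)
        assert n_unjoined == 0
        assert {r.sequence for r in joined} == {region296.sequence}

    def test_single_end_read_shorter_than_haplotype_rejected(self, region296):
        spec = SimSpec(
            region=region296, alleles=((GenotypeSignature(), 1.0),),
            n_reads=10, read_length=100, seed=1,
        )
        with pytest.raises(SimSpecError):
            simulate_clone_fastq(spec, "unused.fastq")

    def test_bad_proportions_rejected(self, region296):
        with pytest.raises(SimSpecError):
            SimSpec(region=region296, alleles=((GenotypeSignature(), 1.2),))
        with pytest.raises(SimSpecError):
            SimSpec(region=region296, alleles=((GenotypeSignature(), -0.1),))


class TestCohort:
    def test_paper_scale_structure_scaled_down(self, tmp_path):
        result = simulate_cohort(
            tmp_path / "cohort", seed=9, n_clones=6, reads_range=(800, 1200)
        )
        assert len(result.clones) == 6
        allele_counts = sorted(len(r.allele_signatures) for r in result.clones.values())
        assert allele_counts[-1] == 10  # the polyclonal outlier clone
        assert all(2 <= k <= 10 for k in allele_counts)
        assert (tmp_path / "cohort" / "reference.fasta").exists()
        # some genotypes recur across clones (shared repair outcomes)
        keys = [s.key for r in result.clones.values() for s in r.allele_signatures]
        assert len(set(keys)) < len(keys)
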