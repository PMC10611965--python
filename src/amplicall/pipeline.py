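"""End-to-end orchestration: FASTQ file(s) -> SampleReport -> cohort outputs.

These functions are the library's front door and what the CLI wraps: the
same steps, in the same order, for one sample, a directory of demultiplexed
samples, or one merged bulk-population FASTQ (a directory holding a single
merged file is processed identically — each file is simply a sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .alignment import AlignmentParams
from .genotyping import SampleReport, call_genotypes
from .read_prep import (
    DEFAULT_MAX_MISMATCH_FRAC,
    DEFAULT_MIN_OVERLAP,
    apply_cutoff,
    collapse_unique,
    find_samples,
    join_pairs,
    read_fastq,
)
from .reference_io import ReferenceRegion
from .reporting import build_matrix, plot_cohort, plot_sample, write_alignment_views, write_matrix, write_summary

logger = logging.getLogger("amplicall")


@dataclass
class PipelineConfig:
    """Everything tunable about a run, echoed into the run log."""

    cutoff: int = 30
    major_threshold: float = 0.01
    params: AlignmentParams = field(default_factory=AlignmentParams)
    min_overlap: int = DEFAULT_MIN_OVERLAP
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC


def genotype_files(
    fastq_paths: Sequence[str | Path],
    region: ReferenceRegion,
    config: PipelineConfig = PipelineConfig(),
    sample_id: Optional[str] = None,
) -> SampleReport:
    """Genotype one sample from its FASTQ file (or R1/R2 file pair).

    The total-read denominator is the number of successfully processed
    reads: all reads for single-end data, joined pairs for paired-end
    (unjoined pairs are dropped and logged).
    """
    paths = [Path(p) for p in fastq_paths]
    if sample_id is None:
        sample_id = paths[0].name.split(".")[0]
    if len(paths) == 1:
        reads = list(read_fastq(paths[0]))
    elif len(paths) == 2:
        r1 = list(read_fastq(paths[0]))
        r2 = list(read_fastq(paths[1]))
        reads, n_unjoined = join_pairs(
            r1, r2, min_overlap=config.min_overlap, max_mismatch_frac=config.max_mismatch_frac
        )
        if n_unjoined:
            logger.info("%s: %d pairs failed to join and were dropped", sample_id, n_unjoined)
    else:
        raise ValueError("expected one FASTQ or an R1/R2 pair")
    uniques = collapse_unique(reads)
    retained = apply_cutoff(uniques, config.cutoff)
    return call_genotypes(
        retained,
        n_total_reads=len(reads),
        region=region,
        params=config.params,
        major_threshold=config.major_threshold,
        sample_id=sample_id,
        n_unique_reads=len(uniques),
        cutoff=config.cutoff,
    )


def cutoff_sweep(
    fastq_paths: Sequence[str | Path],
    region: ReferenceRegion,
    cutoffs: Sequence[int],
    config: PipelineConfig = PipelineConfig(),
    sample_id: Optional[str] = None,
) -> dict[int, SampleReport]:
    """Genotype one sample at several read-count cutoffs.

    Reads are parsed and collapsed once and each unique sequence is aligned
    once (the alignment does not depend on the cutoff), so sweeping adds
    almost nothing over a single low-cutoff run. Useful for judging how the
    cutoff trades retained reads against artifact genotypes.
    """
    paths = [Path(p) for p in fastq_paths]
    if sample_id is None:
        sample_id = paths[0].name.split(".")[0]
    if len(paths) == 2:
        reads, _ = join_pairs(
            list(read_fastq(paths[0])),
            list(read_fastq(paths[1])),
            min_overlap=config.min_overlap,
            max_mismatch_frac=config.max_mismatch_frac,
        )
    else:
        reads = list(read_fastq(paths[0]))
    uniques = collapse_unique(reads)
    cache: dict = {}
    out: dict[int, SampleReport] = {}
    for cutoff in cutoffs:
        retained = apply_cutoff(uniques, cutoff)
        out[cutoff] = call_genotypes(
            retained,
            n_total_reads=len(reads),
            region=region,
            params=config.params,
            major_threshold=config.major_threshold,
            sample_id=sample_id,
            n_unique_reads=len(uniques),
            cutoff=cutoff,
            alignment_cache=cache,
        )
    return out


def genotype_directory(
    fastq_dir: str | Path,
    region: ReferenceRegion,
    config: PipelineConfig = PipelineConfig(),
    strict: bool = False,
) -> list[SampleReport]:
    """Genotype every sample discovered in a directory of FASTQ files."""
    reports = []
    for sample, files in find_samples(fastq_dir).items():
        try:
            reports.append(genotype_files(files, region, config, sample_id=sample))
        except Exception:
            if strict:
                raise
            logger.exception("sample %s failed; continuing (use strict mode to abort)", sample)
    return reports


def write_outputs(
    reports: Sequence[SampleReport],
    region: ReferenceRegion,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> Path:
    """Write all per-sample and cohort outputs into ``out_dir``.

    Per sample: VCF, plot, alignment-vs-WT text; cohort: summary TSV,
    major-genotype matrix TSV, overview plot, and a run log with versions,
    parameters and per-sample totals (no timestamps — identical runs are
    byte-identical).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_summary(reports, out_dir, region)
    for rep in reports:
        plot_sample(rep, out_dir / f"{rep.sample_id}.png", region)
        write_alignment_views(rep, region, out_dir / f"{rep.sample_id}.alignment.txt")
    matrix = build_matrix(reports, majors_only=True)
    write_matrix(matrix, out_dir / "matrix.tsv")
    plot_cohort(matrix, out_dir / "cohort.png")
    log_lines = [
        f"amplicall {__version__}",
        f"region\t{region.label}",
        f"genome_label\t{region.genome_label}",
        f"cutoff\t{config.cutoff}",
        f"major_threshold\t{config.major_threshold}",
        f"match\t{config.params.match_score}",
        f"mismatch\t{config.params.mismatch_score}",
        f"gap_open\t{config.params.gap_open}",
        f"gap_extend\t{config.params.gap_extend}",
        f"min_aligned_frac\t{config.params.min_aligned_frac}",
        f"min_identity\t{config.params.min_identity}",
        "",
        "sample\tn_total\tn_unique\tn_retained\tn_majors\tread_contribution",
    ]
    for rep in reports:
        log_lines.append(
            f"{rep.sample_id}\t{rep.n_total_reads}\t{rep.n_unique_reads}\t"
            f"{rep.n_retained_reads}\t{len(rep.major_calls)}\t{rep.read_contribution:.4f}"
        )
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out_dir
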