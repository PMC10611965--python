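"""The four pipeline outputs: summary + VCF, genotype plot, alignment view, matrix.

VCF output is v4.2 with anchored pure indels. The VCF record model has no
native haplotype call, so the variants of a multi-indel signature share a
``SIGID`` INFO key linking them back to their genotype; ``SUPP`` and
``PROP`` carry the supporting read count and the proportion of total reads.
Proportions are printed with 4 decimal places in tables and 1 decimal in
plot percentage labels. All writers are deterministic: identical reports
produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .errors import ParameterError
from .genotyping import GenotypeCall, IndelVariant, SampleReport
from .reference_io import ReferenceRegion

SUMMARY_COLUMNS = [
    "sample",
    "n_total_reads",
    "n_unique_reads",
    "cutoff",
    "n_retained_reads",
    "signature",
    "n_supporting",
    "proportion",
    "is_major",
    "read_contribution",
]


@dataclass
class CohortMatrix:
    """Samples x genotypes grid of proportions (0 where absent)."""

    sample_ids: list[str]
    genotype_keys: list[str]
    proportions: np.ndarray  # shape (n_samples, n_genotypes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=self.sample_ids, columns=self.genotype_keys
        )


# ---------------------------------------------------------------------------
# Summary TSV + per-sample VCF
# ---------------------------------------------------------------------------


def summary_frame(reports: Sequence[SampleReport]) -> pd.DataFrame:
    """One row per genotype call across all samples (all calls, not just majors)."""
    rows = []
    for rep in reports:
        for call in rep.calls:
            rows.append(
                {
                    "sample": rep.sample_id,
                    "n_total_reads": rep.n_total_reads,
                    "n_unique_reads": rep.n_unique_reads,
                    "cutoff": rep.cutoff,
                    "n_retained_reads": rep.n_retained_reads,
                    "signature": call.signature.key,
                    "n_supporting": call.n_supporting,
                    "proportion": f"{call.proportion:.4f}",
                    "is_major": call.is_major,
                    "read_contribution": f"{rep.read_contribution:.4f}",
                }
            )
        if not rep.calls:
            rows.append(
                {
                    "sample": rep.sample_id,
                    "n_total_reads": rep.n_total_reads,
                    "n_unique_reads": rep.n_unique_reads,
                    "cutoff": rep.cutoff,
                    "n_retained_reads": rep.n_retained_reads,
                    "signature": "NA",
                    "n_supporting": 0,
                    "proportion": f"{0.0:.4f}",
                    "is_major": False,
                    "read_contribution": f"{rep.read_contribution:.4f}",
                }
            )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_vcf(report: SampleReport, region: ReferenceRegion, path: str | Path) -> Path:
    """Write the major genotypes of one sample as a VCFv4.2 file.

    One record per :class:`IndelVariant`; records sorted by POS (ties by
    REF, ALT). A WT-only sample yields a header with zero records.
    """
    path = Path(path)
    records: list[tuple[IndelVariant, str, GenotypeCall]] = []
    for idx, call in enumerate(report.major_calls, start=1):
        sigid = f"G{idx}"
        for v in call.signature.variants:
            records.append((v, sigid, call))
    records.sort(key=lambda t: (t[0].pos, t[0].ref, t[0].alt))
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={region.genome_label or 'unspecified'}",
        f"##contig=<ID={region.chrom}>",
        f"##amplicall_region={region.label}",
        f"##amplicall_sample={report.sample_id}",
        '##INFO=<ID=SIGID,Number=1,Type=String,Description="Genotype signature this variant belongs to">',
        '##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Reads supporting the signature">',
        '##INFO=<ID=PROP,Number=1,Type=Float,Description="Supporting reads / total processed reads">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v, sigid, call in records:
        info = f"SIGID={sigid};SUPP={call.n_supporting};PROP={call.proportion:.4f}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_summary(
    reports: Sequence[SampleReport], out_dir: str | Path, region: ReferenceRegion
) -> dict[str, Path]:
    """Write the cross-sample summary TSV and one VCF per sample."""
    if not reports:
        raise ParameterError("write_summary needs at least one report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    summary_path = out_dir / "summary.tsv"
    summary_frame(reports).to_csv(summary_path, sep="\t", index=False)
    paths["summary"] = summary_path
    for rep in reports:
        paths[f"vcf:{rep.sample_id}"] = write_vcf(
            rep, region, out_dir / f"{rep.sample_id}.vcf"
        )
    return paths


# ---------------------------------------------------------------------------
# Alignment-vs-WT text view
# ---------------------------------------------------------------------------


def render_alignment_text(
    call: GenotypeCall, region: ReferenceRegion, flank: int = 20
) -> str:
    """Two-row gapped alignment of one genotype against the WT sequence.

    Deletions appear as dashes in the genotype row, insertions as dashes in
    the WT row; a ruler line marks genomic coordinates every 10 reference
    columns. The window covers all of the genotype's variants plus
    ``flank`` reference bases on each side (whole region for WT).
    """
    seq = region.sequence
    variants = call.signature.variants
    if variants:
        lo = min(v.pos for v in variants)
        hi = max(v.footprint()[1] for v in variants)
        w0 = max(1, region.genomic_to_local(lo) - flank)
        w1 = min(len(seq), region.genomic_to_local(hi) + flank)
    else:
        w0, w1 = 1, len(seq)
    deleted: set[int] = set()  # local positions removed by deletions
    inserted: dict[int, str] = {}  # inserted bases shown after this local position
    for v in variants:
        if v.kind == "deletion":
            first = region.genomic_to_local(v.pos) + (0 if v.right_anchored else 1)
            for p in range(first, first + v.length):
                deleted.add(p)
        else:
            anchor = region.genomic_to_local(v.pos)
            ins = v.alt[:-1] if v.right_anchored else v.alt[1:]
            inserted[anchor - 1 if v.right_anchored else anchor] = ins
    wt_row: list[str] = []
    gt_row: list[str] = []
    ruler: list[str] = []
    ref_col = 0  # count of reference columns emitted, for ruler ticks
    if 0 in inserted:  # insertion before the first region base
        ins = inserted[0]
        wt_row.append("-" * len(ins))
        gt_row.append(ins.lower())
        ruler.append(" " * len(ins))
    for p in range(w0, w1 + 1):
        wt_row.append(seq[p - 1])
        gt_row.append("-" if p in deleted else seq[p - 1])
        ref_col += 1
        if ref_col % 10 == 1:
            tick = str(region.local_to_genomic(p))
            ruler.append("|" + tick)
        else:
            ruler.append(" ")
        if p in inserted:
            ins = inserted[p]
            wt_row.append("-" * len(ins))
            gt_row.append(ins.lower())
            ruler.append(" " * len(ins))
    # flatten ruler so labels overwrite following blanks instead of shifting
    wt_line = "".join(wt_row)
    gt_line = "".join(gt_row)
    ruler_line = _flatten_ruler(ruler, len(wt_line))
    header = (
        f"signature: {call.signature.key}  supporting reads: {call.n_supporting}  "
        f"proportion: {call.proportion * 100:.1f}%"
    )
    return "\n".join([header, ruler_line, "WT  " + wt_line, "GT  " + gt_line, ""])


def _flatten_ruler(cells: list[str], width: int) -> str:
    """Place tick marks and coordinate labels by column; labels overhang blanks."""
    pos_line = [" "] * (width + 16)
    col = 0
    for cell in cells:
        if cell.startswith("|"):
            label = cell[1:]
            pos_line[col] = "|"
            for k, ch in enumerate(label):
                if col + 1 + k < len(pos_line):
                    pos_line[col + 1 + k] = ch
            col += 1
        else:
            col += len(cell)
    return ("pos " + "".join(pos_line)).rstrip()


def write_alignment_views(
    report: SampleReport, region: ReferenceRegion, path: str | Path, flank: int = 20
) -> Path:
    """All major genotypes of a sample as stacked text alignment blocks."""
    path = Path(path)
    blocks = [f"# sample {report.sample_id}  region {region.label}", ""]
    for call in report.major_calls:
        blocks.append(render_alignment_text(call, region, flank=flank))
    if not report.major_calls:
        blocks.append("no major genotypes")
    path.write_text("\n".join(blocks) + "\n")
    return path


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------


def plot_sample(
    report: SampleReport, out_path: str | Path, region: ReferenceRegion | None = None
) -> Path:
    """Static per-sample plot: one horizontal glyph per major genotype.

    Deletions are bars spanning their footprint, insertions downward
    markers at their anchor; each row is labeled with its proportion.
    Layout is deterministic for a given report.
    """
    out_path = Path(out_path)
    majors = report.major_calls
    fig = Figure(figsize=(9, max(2.0, 0.6 * len(majors) + 1.2)), dpi=100)
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    if region is not None:
        ax.set_xlim(region.start - 1, region.end + 1)
    ax.set_title(f"{report.sample_id}: major genotypes (>= {report.major_threshold * 100:.0f}% of reads)")
    ax.set_xlabel("genomic position")
    if not majors:
        ax.annotate(
            "no major genotypes",
            xy=(0.5, 0.5),
            xycoords="axes fraction",
            ha="center",
            va="center",
        )
        ax.set_yticks([])
    else:
        labels = []
        for row, call in enumerate(majors):
            y = len(majors) - row
            label = f"{call.proportion * 100:.1f}%"
            labels.append(f"{call.signature.key}" if len(call.signature.key) < 48 else f"G{row + 1}")
            if call.signature.is_wt:
                if region is not None:
                    ax.plot([region.start, region.end], [y, y], lw=2, color="#888888")
                ax.annotate(f"WT {label}", xy=(0.01, y + 0.18), xycoords=("axes fraction", "data"), fontsize=8)
                continue
            for v in call.signature.variants:
                if v.kind == "deletion":
                    lo, hi = v.footprint()
                    ax.plot([lo + 1, hi], [y, y], lw=6, color="#c0392b", solid_capstyle="butt")
                else:
                    ax.plot([v.pos], [y], marker="v", ms=8, color="#2980b9")
            ax.annotate(label, xy=(0.01, y + 0.18), xycoords=("axes fraction", "data"), fontsize=8)
        ax.set_yticks(range(1, len(majors) + 1))
        ax.set_yticklabels(reversed(labels), fontsize=7)
        ax.set_ylim(0.3, len(majors) + 0.9)
    fig.savefig(out_path, format=out_path.suffix.lstrip(".") or "png", metadata=None)
    return out_path


def plot_cohort(matrix: CohortMatrix, out_path: str | Path) -> Path:
    """Cohort overview: samples x genotypes proportion heatmap."""
    out_path = Path(out_path)
    df = matrix.to_dataframe()
    fig = Figure(
        figsize=(max(4.0, 0.45 * len(matrix.genotype_keys) + 2), max(3.0, 0.3 * len(matrix.sample_ids) + 1.5)),
        dpi=100,
    )
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    im = ax.imshow(df.values, aspect="auto", cmap="viridis", vmin=0.0, vmax=max(1e-9, df.values.max()))
    ax.set_yticks(range(len(matrix.sample_ids)))
    ax.set_yticklabels(matrix.sample_ids, fontsize=7)
    ax.set_xticks(range(len(matrix.genotype_keys)))
    ax.set_xticklabels(matrix.genotype_keys, rotation=90, fontsize=6)
    ax.set_title("major genotype proportions per sample")
    fig.colorbar(im, ax=ax, label="proportion of total reads")
    fig.savefig(out_path, format=out_path.suffix.lstrip(".") or "png", metadata=None)
    return out_path


# ---------------------------------------------------------------------------
# Cohort matrix
# ---------------------------------------------------------------------------


def build_matrix(
    reports: Sequence[SampleReport], majors_only: bool = True
) -> CohortMatrix:
    """Union the (major) signatures across samples into a proportion grid.

    Genotype columns are ordered by total supporting reads descending (ties
    by key); samples keep their input order. Cells are 0 where a sample did
    not call the genotype.
    """
    if not reports:
        raise ParameterError("build_matrix needs at least one report")
    ids = [r.sample_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ParameterError(f"duplicate sample ids: {ids}")
    support: dict[str, int] = {}
    for rep in reports:
        for call in rep.major_calls if majors_only else rep.calls:
            support[call.signature.key] = support.get(call.signature.key, 0) + call.n_supporting
    keys = sorted(support, key=lambda k: (-support[k], k))
    grid = np.zeros((len(reports), len(keys)), dtype=float)
    col = {k: j for j, k in enumerate(keys)}
    for i, rep in enumerate(reports):
        for call in rep.major_calls if majors_only else rep.calls:
            grid[i, col[call.signature.key]] = call.proportion
    return CohortMatrix(ids, keys, grid)


def write_matrix(matrix: CohortMatrix, path: str | Path) -> Path:
    """Matrix as TSV, samples as rows, proportions with 4 decimals."""
    path = Path(path)
    df = matrix.to_dataframe()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.4f")
    return path
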