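"""Indel extraction, VCF left-normalization, signatures, major-genotype calls.

The genotype unit is the per-read *indel signature*: the complete,
left-normalized, position-sorted set of insertions/deletions carried by one
read. Substitutions never enter signatures, which makes calls robust to the
random point errors that polymerases introduce during amplification; within
the amplicon a signature preserves phasing, so a clone's signatures
correspond to its edited alleles (their count tracks locus copy number).

A signature is *major* when its supporting retained reads amount to at
least ``major_threshold`` (default 1%, boundary inclusive) of the sample's
total processed reads — the total, not the post-cutoff retained subset, so
proportions are comparable across cutoffs. The wild-type (empty) signature
is callable like any other, which keeps insufficiently edited clones
visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

from .alignment import (
    AlignmentParams,
    AlignmentResult,
    align_read,
    alignment_passes_filter,
)
from .errors import ParameterError
from .read_prep import UniqueRead
from .reference_io import ReferenceRegion


class RawIndel(NamedTuple):
    """An un-normalized indel in region-local coordinates.

    For deletions ``local_pos`` is the 1-based region position of the first
    deleted base and ``seq`` the deleted bases. For insertions ``local_pos``
    is the 1-based region position *before which* the bases sit and ``seq``
    the inserted bases.
    """

    kind: str  # "insertion" | "deletion"
    local_pos: int
    seq: str


@dataclass(frozen=True, order=True)
class IndelVariant:
    """One insertion or deletion in anchored VCF CHR-POS-REF-ALT form.

    The shorter allele is always the single anchor base; ``pos`` is the
    1-based genomic coordinate of the anchor. Variants are left-normalized:
    no equivalent representation exists at a smaller ``pos``. An indel at
    the region's left boundary, where no left anchor base exists, is
    emitted with a right anchor and ``right_anchored=True``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    right_anchored: bool = False

    @property
    def kind(self) -> str:
        return "deletion" if len(self.ref) > len(self.alt) else "insertion"

    @property
    def length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def key(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    def footprint(self) -> tuple[int, int]:
        """Genomic interval of reference bases the variant touches."""
        return self.pos, self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class GenotypeSignature:
    """Ordered set of indels on one read; empty tuple denotes wild type."""

    variants: tuple[IndelVariant, ...] = ()
    is_complex: bool = False  # overlapping indels kept verbatim, flagged

    @property
    def key(self) -> str:
        if not self.variants:
            return "WT"
        return ";".join(v.key for v in self.variants)

    @property
    def is_wt(self) -> bool:
        return not self.variants


@dataclass(frozen=True)
class GenotypeCall:
    """A signature with its read support within one sample."""

    signature: GenotypeSignature
    n_supporting: int
    proportion: float  # n_supporting / sample total processed reads
    is_major: bool


@dataclass
class SampleReport:
    """Per-sample genotyping result.

    ``n_total_reads`` counts processed reads (for paired-end data, pairs
    that joined); ``n_retained_reads`` counts reads in unique sequences at
    or above the cutoff, including reads whose alignment later failed the
    quality filter. ``read_contribution`` is the fraction of retained reads
    supporting major genotypes.
    """

    sample_id: str
    n_total_reads: int
    n_unique_reads: int
    cutoff: int
    n_retained_reads: int
    calls: list[GenotypeCall] = field(default_factory=list)
    read_contribution: float = 0.0
    major_threshold: float = 0.01
    n_filtered_reads: int = 0  # retained reads whose alignment failed filters

    @property
    def major_calls(self) -> list[GenotypeCall]:
        return [c for c in self.calls if c.is_major]


# ---------------------------------------------------------------------------
# Indel extraction and normalization
# ---------------------------------------------------------------------------


def extract_indels(aln: AlignmentResult, region: ReferenceRegion) -> list[RawIndel]:
    """One raw indel per insertion/deletion op; substitutions are ignored.

    Inserted bases come from the oriented read, deleted bases from the
    region. Coordinates are region-local and 1-based (genomic conversion
    happens during normalization).
    """
    raw: list[RawIndel] = []
    oriented = aln.oriented_sequence
    for op in aln.ops:
        if op.kind == "insertion":
            seq = oriented[op.read_offset : op.read_offset + op.length]
            raw.append(RawIndel("insertion", op.region_offset + 1, seq))
        elif op.kind == "deletion":
            seq = region.sequence[op.region_offset : op.region_offset + op.length]
            raw.append(RawIndel("deletion", op.region_offset + 1, seq))
    return raw


def left_normalize(raw: RawIndel, region: ReferenceRegion) -> IndelVariant:
    """Shift an indel to its leftmost equivalent placement and anchor it.

    Standard VCF left-alignment: while the base preceding the event equals
    the last base of the event, the event slides one base left (the classic
    homopolymer/repeat ambiguity). The record is then anchored on the base
    before the event. Idempotent: normalizing an already-normalized indel
    changes nothing.
    """
    seq = region.sequence
    if raw.kind == "deletion":
        i = raw.local_pos - 1  # 0-based first deleted base
        L = len(raw.seq)
        if not (0 <= i and i + L <= len(seq)):
            raise ParameterError(f"deletion at {raw.local_pos} outside region")
        if seq[i : i + L] != raw.seq:
            raise ParameterError(
                f"deletion sequence {raw.seq!r} does not match region at {raw.local_pos}"
            )
        while i > 0 and seq[i - 1] == seq[i + L - 1]:
            i -= 1
        if i > 0:
            return IndelVariant(
                chrom=region.chrom,
                pos=region.local_to_genomic(i),
                ref=seq[i - 1 : i + L],
                alt=seq[i - 1],
            )
        # deletion abuts the region's left edge: right-anchor instead
        return IndelVariant(
            chrom=region.chrom,
            pos=region.local_to_genomic(1),
            ref=seq[: L + 1],
            alt=seq[L],
            right_anchored=True,
        )
    if raw.kind == "insertion":
        i = raw.local_pos - 1  # 0-based region index the bases are inserted before
        ins = raw.seq
        if not (0 <= i <= len(seq)) or not ins:
            raise ParameterError(f"invalid insertion at {raw.local_pos}")
        while i > 0 and seq[i - 1] == ins[-1]:
            ins = seq[i - 1] + ins[:-1]
            i -= 1
        if i > 0:
            return IndelVariant(
                chrom=region.chrom,
                pos=region.local_to_genomic(i),
                ref=seq[i - 1],
                alt=seq[i - 1] + ins,
            )
        return IndelVariant(
            chrom=region.chrom,
            pos=region.local_to_genomic(1),
            ref=seq[0],
            alt=ins + seq[0],
            right_anchored=True,
        )
    raise ParameterError(f"unknown indel kind {raw.kind!r}")


def signature_of_read(aln: AlignmentResult, region: ReferenceRegion) -> GenotypeSignature:
    """Normalize and sort a read's indels into its genotype signature.

    Two reads from the same edited allele that differ only by substitution
    errors produce identical signatures. Overlapping normalized indels on
    one read are kept verbatim and the signature flagged complex.
    """
    variants = sorted(
        (left_normalize(raw, region) for raw in extract_indels(aln, region)),
        key=lambda v: (v.pos, v.ref, v.alt),
    )
    is_complex = any(
        a.footprint()[1] >= b.footprint()[0]
        for a, b in zip(variants, variants[1:])
    )
    return GenotypeSignature(tuple(variants), is_complex)


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


def call_genotypes(
    uniques_retained: Sequence[UniqueRead],
    n_total_reads: int,
    region: ReferenceRegion,
    params: AlignmentParams = AlignmentParams(),
    major_threshold: float = 0.01,
    *,
    sample_id: str = "sample",
    n_unique_reads: Optional[int] = None,
    cutoff: Optional[int] = None,
    alignment_cache: Optional[dict[str, AlignmentResult]] = None,
) -> SampleReport:
    """Align retained unique reads, group by signature, call majors.

    Counts of unique reads sharing a signature are summed into one
    :class:`GenotypeCall`; ``proportion = summed count / n_total_reads`` and
    ``is_major`` is True iff proportion >= ``major_threshold`` (inclusive).
    Calls are sorted by descending proportion, ties by signature text. Zero
    retained reads yields an empty-call report, not an error.

    ``alignment_cache`` (sequence -> AlignmentResult) lets callers running
    the same reads at several cutoffs align each unique sequence only once;
    the alignment is deterministic, so caching cannot change any result.
    """
    if not 0.0 < major_threshold <= 1.0:
        raise ParameterError(f"major_threshold must be in (0, 1], got {major_threshold}")
    n_retained = sum(u.count for u in uniques_retained)
    if n_total_reads < n_retained:
        raise ParameterError(
            f"n_total_reads ({n_total_reads}) < retained read count ({n_retained})"
        )
    support: dict[GenotypeSignature, int] = {}
    n_filtered = 0
    for u in uniques_retained:
        if alignment_cache is not None and u.sequence in alignment_cache:
            aln = alignment_cache[u.sequence]
        else:
            aln = align_read(u.sequence, region, params)
            if alignment_cache is not None:
                alignment_cache[u.sequence] = aln
        if aln.is_empty or not alignment_passes_filter(aln, params):
            n_filtered += u.count
            continue
        sig = signature_of_read(aln, region)
        support[sig] = support.get(sig, 0) + u.count
    calls = [
        GenotypeCall(
            signature=sig,
            n_supporting=n,
            proportion=n / n_total_reads if n_total_reads else 0.0,
            is_major=n_total_reads > 0 and n / n_total_reads >= major_threshold,
        )
        for sig, n in support.items()
    ]
    calls.sort(key=lambda c: (-c.proportion, c.signature.key))
    report = SampleReport(
        sample_id=sample_id,
        n_total_reads=n_total_reads,
        n_unique_reads=n_unique_reads if n_unique_reads is not None else len(uniques_retained),
        cutoff=cutoff if cutoff is not None else 0,
        n_retained_reads=n_retained,
        calls=calls,
        major_threshold=major_threshold,
        n_filtered_reads=n_filtered,
    )
    report.read_contribution = read_contribution(report)
    return report


def read_contribution(report: SampleReport) -> float:
    """Reads supporting all major genotypes / reads retained for genotyping.

    0.0 when no reads were retained.
    """
    if report.n_retained_reads == 0:
        return 0.0
    return sum(c.n_supporting for c in report.major_calls) / report.n_retained_reads
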