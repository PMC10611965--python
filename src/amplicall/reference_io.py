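"""Load and validate the reference sequence for the genomic region of interest.

Coordinates are 1-based inclusive everywhere at module boundaries, matching
both the conventional region notation (e.g. ``chr21:34715869-34716164``) and
VCF. Regions are amplicon-scale; the whole region sequence is held in memory.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from ._dna import validate_dna
from .errors import (
    MissingChromosomeError,
    ReferenceIOError,
    RegionBoundsError,
    RegionFormatError,
)

#: Hard ceiling on region width; amplicons are a few hundred bp, and nothing
#: in this package is designed for chromosome-scale windows.
DEFAULT_MAX_REGION_LENGTH = 100_000

# CHR:START-END with optional whitespace; hyphen, en-dash or em-dash.
_REGION_RE = re.compile(r"^\s*(\S+?)\s*:\s*(\d+)\s*[-–—]\s*(\d+)\s*$")


@dataclass(frozen=True)
class ReferenceRegion:
    """The extracted genomic window reads are genotyped against.

    Attributes
    ----------
    chrom : str
        Chromosome (FASTA record) name.
    start, end : int
        1-based inclusive genomic coordinates of the window.
    sequence : str
        Uppercase DNA of length ``end - start + 1``.
    genome_label : str
        Free-text provenance label (e.g. ``"GRCh37"``); carried into reports.
    """

    chrom: str
    start: int
    end: int
    sequence: str
    genome_label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise RegionFormatError(
                f"invalid coordinates {self.chrom}:{self.start}-{self.end}"
            )
        object.__setattr__(self, "sequence", validate_dna(self.sequence, what="region"))
        if len(self.sequence) != self.end - self.start + 1:
            raise ReferenceIOError(
                f"sequence length {len(self.sequence)} != span "
                f"{self.end - self.start + 1} for {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def local_to_genomic(self, local_pos: int) -> int:
        """Map a 1-based offset within the region to a genomic coordinate."""
        return self.start + local_pos - 1

    def genomic_to_local(self, genomic_pos: int) -> int:
        """Inverse of :meth:`local_to_genomic`."""
        return genomic_pos - self.start + 1

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_region_string(region_text: str) -> tuple[str, int, int]:
    """Parse ``CHR:START-END`` into ``(chrom, start, end)``, 1-based inclusive.

    Accepts surrounding whitespace and hyphen/en-dash/em-dash separators.

    >>> parse_region_string("chr21:34715869-34716164")
    ('chr21', 34715869, 34716164)
    """
    m = _REGION_RE.match(region_text)
    if not m:
        raise RegionFormatError(
            f"region {region_text!r} does not match CHR:START-END"
        )
    chrom, start_s, end_s = m.groups()
    start, end = int(start_s), int(end_s)
    if start < 1:
        raise RegionFormatError(f"START must be positive, got {start_s!r}")
    if end < start:
        raise RegionFormatError(
            f"END ({end_s!r}) precedes START ({start_s!r}) in {region_text!r}"
        )
    return chrom, start, end


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_region(
    fasta_path: str | Path,
    chrom: str,
    start: int,
    end: int,
    *,
    genome_label: str | None = None,
    max_region_length: int = DEFAULT_MAX_REGION_LENGTH,
) -> ReferenceRegion:
    """Extract ``chrom:start-end`` (1-based inclusive) from a FASTA file.

    The FASTA may be plain or gzipped, multi-record, with wrapped or
    unwrapped lines. Record identity is the first whitespace-delimited token
    of the header and must match ``chrom`` exactly ("chr21" and "21" are
    different names). Soft-masked (lowercase) bases are uppercased.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise ReferenceIOError(f"FASTA file not found: {fasta_path}")
    if start < 1 or end < start:
        raise RegionFormatError(f"invalid coordinates {chrom}:{start}-{end}")
    if end - start + 1 > max_region_length:
        raise RegionBoundsError(
            f"region {chrom}:{start}-{end} exceeds the "
            f"{max_region_length} bp limit; this tool targets amplicon-scale windows"
        )
    with _open_maybe_gzip(fasta_path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id != chrom:
                continue
            if end > len(record.seq):
                raise RegionBoundsError(
                    f"end {end} beyond {chrom} length {len(record.seq)} "
                    f"in {fasta_path}"
                )
            seq = str(record.seq[start - 1 : end])
            return ReferenceRegion(
                chrom=chrom,
                start=start,
                end=end,
                sequence=seq,
                genome_label=genome_label if genome_label is not None else fasta_path.stem,
            )
    raise MissingChromosomeError(f"no record named {chrom!r} in {fasta_path}")
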