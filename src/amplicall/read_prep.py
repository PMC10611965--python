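"""FASTQ ingest, overlap-based pair joining, unique-read collapsing, cutoff.

Deep amplicon sequencing of a CRISPR-edited locus yields tens of thousands
of reads per clone, most of which are exact copies of a handful of allele
haplotypes. The preparation strategy is therefore: collapse reads by exact
full-length string identity, count occurrences, and discard unique reads
below a count cutoff (default 30). The cutoff — not quality trimming — is
what absorbs polymerase/sequencer error reads, which are spread thinly over
many distinct sequences and rarely recur 30 times.
"""

from __future__ import annotations

import gzip
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import revcomp
from .errors import FastqParseError, PairingError, ParameterError

#: fastq-join-style defaults for overlap merging of paired-end mates.
DEFAULT_MIN_OVERLAP = 6
DEFAULT_MAX_MISMATCH_FRAC = 0.08


class RawRead(NamedTuple):
    """One sequencing read; ``quality`` is Phred+33 text or None."""

    read_id: str
    sequence: str
    quality: str | None = None


class UniqueRead(NamedTuple):
    """A distinct read sequence with its occurrence count and rank.

    ``rank`` is the 1-based position when unique reads are sorted by
    descending count (ties broken lexicographically by sequence).
    """

    sequence: str
    count: int
    rank: int


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Yield reads from a FASTQ or gzipped FASTQ file in file order.

    N bases are preserved; sequences are uppercased. Truncated records and
    sequence/quality length mismatches raise :class:`FastqParseError`
    naming the 1-based record index.
    """
    path = Path(path)
    index = 0
    with _open_maybe_gzip(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ at record {index + 1}: {exc}"
                ) from exc
            index += 1
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: sequence/quality length mismatch at record {index}"
                )
            yield RawRead(title.split()[0] if title else f"read{index}", seq.upper(), qual)


def _best_overlap(
    s1: np.ndarray, s2: np.ndarray, min_overlap: int, max_mismatch_frac: float
) -> tuple[int, float] | None:
    """Best no-indel overlap of the tail of s1 with the head of s2.

    Returns (overlap_length, mismatch_fraction) minimising mismatch fraction,
    ties resolved toward the longest overlap; None when no overlap of length
    >= min_overlap satisfies the mismatch ceiling.
    """
    best: tuple[float, int] | None = None  # (frac, -overlap)
    max_o = min(len(s1), len(s2))
    for o in range(min_overlap, max_o + 1):
        mism = int(np.count_nonzero(s1[-o:] != s2[:o]))
        frac = mism / o
        if frac > max_mismatch_frac:
            continue
        key = (frac, -o)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return -best[1], best[0]


def join_pairs(
    r1: Sequence[RawRead],
    r2: Sequence[RawRead],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[list[RawRead], int]:
    """Merge mate pairs by 3' overlap, fastq-join style.

    Mate 2 is reverse-complemented; the overlap alignment (no indels inside
    the overlap) between the mate-1 3' end and the reverse-complemented
    mate-2 5' end is accepted when its length is >= ``min_overlap`` and its
    mismatch fraction is <= ``max_mismatch_frac``; among acceptable overlaps
    the one with the lowest mismatch fraction wins, ties going to the longest
    overlap. At overlap mismatches the higher-quality base is taken (mate-1
    when qualities tie or are absent). Pairs with no acceptable overlap are
    dropped and counted in ``n_unjoined``.
    """
    if len(r1) != len(r2):
        raise PairingError(
            f"mate files disagree: {len(r1)} R1 records vs {len(r2)} R2 records"
        )
    joined: list[RawRead] = []
    n_unjoined = 0
    for m1, m2 in zip(r1, r2):
        s2 = revcomp(m2.sequence)
        q2 = m2.quality[::-1] if m2.quality is not None else None
        a1 = np.frombuffer(m1.sequence.encode(), dtype=np.uint8)
        a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
        hit = _best_overlap(a1, a2, min_overlap, max_mismatch_frac)
        if hit is None:
            n_unjoined += 1
            continue
        o, _ = hit
        prefix = m1.sequence[:-o] if o < len(m1.sequence) else ""
        suffix = s2[o:]
        ov1, ov2 = m1.sequence[len(prefix):], s2[:o]
        qv1 = m1.quality[len(prefix):] if m1.quality is not None else None
        mid = []
        midq = []
        for k in range(o):
            b1, b2 = ov1[k], ov2[k]
            if b1 == b2:
                mid.append(b1)
                midq.append(qv1[k] if qv1 is not None else "I")
                continue
            q1c = qv1[k] if qv1 is not None else None
            q2c = q2[k] if q2 is not None else None
            if q1c is not None and q2c is not None and q2c > q1c:
                mid.append(b2)
                midq.append(q2c)
            else:
                mid.append(b1)
                midq.append(q1c if q1c is not None else "I")
        quality = None
        if m1.quality is not None and m2.quality is not None:
            quality = m1.quality[: len(prefix)] + "".join(midq) + q2[o:]
        joined.append(RawRead(m1.read_id, prefix + "".join(mid) + suffix, quality))
    return joined, n_unjoined


def collapse_unique(reads: Iterable[RawRead]) -> list[UniqueRead]:
    """Collapse reads to unique sequences with counts.

    Uniqueness is exact full-length string identity (quality ignored, no
    trimming, no N-masking, no reverse-complement collapsing — orientation is
    resolved later at alignment time). Output is sorted by descending count,
    ties broken lexicographically by sequence; ranks run 1..K. The sum of
    counts equals the number of input reads.
    """
    counts = Counter(r.sequence for r in reads)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [UniqueRead(seq, n, rank) for rank, (seq, n) in enumerate(ordered, start=1)]


def apply_cutoff(uniques: Sequence[UniqueRead], cutoff: int = 30) -> list[UniqueRead]:
    """Retain unique reads with ``count >= cutoff`` (inclusive), order kept.

    Cutoff 0 retains everything.
    """
    if cutoff < 0:
        raise ParameterError(f"read-count cutoff must be >= 0, got {cutoff}")
    return [u for u in uniques if u.count >= cutoff]


# ---------------------------------------------------------------------------
# Sample discovery (directory of demultiplexed per-sample FASTQ files)
# ---------------------------------------------------------------------------

_FASTQ_SUFFIXES = (".fastq", ".fq", ".fastq.gz", ".fq.gz")
_MATE_TAGS = (("_R1", "_R2"), ("_1", "_2"))


def _strip_fastq_suffix(name: str) -> str | None:
    for suf in _FASTQ_SUFFIXES:
        if name.endswith(suf):
            return name[: -len(suf)]
    return None


def find_samples(fastq_dir: str | Path) -> dict[str, tuple[Path, ...]]:
    """Map sample names to their FASTQ file(s) in a directory.

    Sample identity is the file stem; mates pair by the ``_R1``/``_R2`` or
    ``_1``/``_2`` suffix convention. An R1 without its R2 (or vice versa) is
    a :class:`PairingError`, never a guess.
    """
    fastq_dir = Path(fastq_dir)
    stems: dict[str, Path] = {}
    for p in sorted(fastq_dir.iterdir()):
        stem = _strip_fastq_suffix(p.name)
        if stem is not None:
            if stem in stems:
                raise PairingError(f"duplicate sample file stem {stem!r} in {fastq_dir}")
            stems[stem] = p
    samples: dict[str, tuple[Path, ...]] = {}
    used: set[str] = set()
    for stem, path in stems.items():
        if stem in used:
            continue
        mate = None
        base = None
        for tag1, tag2 in _MATE_TAGS:
            if stem.endswith(tag1):
                base = stem[: -len(tag1)]
                mate_stem = base + tag2
                if mate_stem not in stems:
                    raise PairingError(f"{stem}: mate file {mate_stem!r} not found")
                mate = stems[mate_stem]
                break
            if stem.endswith(tag2):
                base = stem[: -len(tag2)]
                if base + tag1 not in stems:
                    raise PairingError(f"{stem}: mate file {base + tag1!r} not found")
                mate = "skip"  # handled from the R1 side
                break
        if mate == "skip":
            continue
        if mate is None:
            samples[stem] = (path,)
            used.add(stem)
        else:
            samples[base] = (path, mate)
            used.add(stem)
    return dict(sorted(samples.items()))
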