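"""Affine-gap local alignment of unique reads against the reference region.

Each retained unique read is aligned to the amplicon window with a
Smith–Waterman / Gotoh local aligner in both orientations; the
higher-scoring orientation wins. A gap of length L costs
``gap_open + gap_extend * L``. Defaults (match +2, mismatch -3, open 5,
extend 2) are the classic nucleotide-BLAST scoring, the role this step
plays in the pipeline; the aligner is implemented in-repo so results are
bit-reproducible with no external binary.

Among equal-scoring optimal alignments the traceback prefers, in order,
fewer gap openings (tracked exactly per DP state), then gaps placed
leftmost on the reference (the end cell with the smallest reference
coordinate is chosen; residual placement ambiguity is canonicalized
downstream by VCF left-normalization), then diagonal moves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from numba import njit

from ._dna import revcomp
from .errors import ParameterError
from .reference_io import ReferenceRegion

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and filtering knobs for read-vs-region alignment.

    match_score : reward per identical column (> 0)
    mismatch_score : penalty per substitution column (< 0)
    gap_open, gap_extend : affine gap penalties (>= 0); a gap of length L
        costs ``gap_open + gap_extend * L``
    min_aligned_frac : fraction of the read that must sit inside the local
        alignment for the read to be genotyped
    min_identity : fraction of non-gap columns that must match
    """

    match_score: int = 2
    mismatch_score: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    min_aligned_frac: float = 0.5
    min_identity: float = 0.7

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ParameterError("match_score must be positive")
        if self.mismatch_score >= 0:
            raise ParameterError("mismatch_score must be negative")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ParameterError("gap penalties must be non-negative")
        for name in ("min_aligned_frac", "min_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")


class AlignmentOp(NamedTuple):
    """One run of identical alignment columns.

    ``read_offset``/``region_offset`` are 0-based offsets of the first
    column of the run in the oriented read / the region. For insertions the
    region offset is the index of the region base *before which* the
    inserted bases sit; for deletions the read offset is the index of the
    next read base.
    """

    kind: str  # "match" | "mismatch" | "insertion" | "deletion"
    length: int
    read_offset: int
    region_offset: int


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of one read against the region.

    ``ops`` refer to the *oriented* read sequence (reverse complement of
    ``read_sequence`` when ``strand`` is "-"). ``region_span`` and
    ``read_span`` are 1-based inclusive; both are None for an empty
    (score 0) alignment.
    """

    read_sequence: str
    strand: str
    score: int
    ops: tuple[AlignmentOp, ...]
    region_span: Optional[tuple[int, int]]
    read_span: Optional[tuple[int, int]]
    identity: float
    aligned_frac: float

    @property
    def oriented_sequence(self) -> str:
        return self.read_sequence if self.strand == "+" else revcomp(self.read_sequence)

    @property
    def is_empty(self) -> bool:
        return not self.ops


def _encode(seq: str) -> np.ndarray:
    # anything outside ACGT (including ambiguity codes) aligns like N
    return np.fromiter((_CODE.get(c, _N_CODE) for c in seq), dtype=np.int8, count=len(seq))


@njit(cache=True)
def _gotoh_fill(read, region, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = read.shape[0]
    m = region.shape[0]
    NEG = -(2 ** 30)
    M = np.zeros((n + 1, m + 1), np.int32)
    X = np.full((n + 1, m + 1), NEG, np.int32)  # gap in region (read insertion)
    Y = np.full((n + 1, m + 1), NEG, np.int32)  # gap in read (deletion)
    OM = np.zeros((n + 1, m + 1), np.int32)  # gap openings on the best path
    OX = np.zeros((n + 1, m + 1), np.int32)
    OY = np.zeros((n + 1, m + 1), np.int32)
    PM = np.zeros((n + 1, m + 1), np.int8)  # 0 start, 1 M, 2 X, 3 Y
    PX = np.zeros((n + 1, m + 1), np.int8)  # 1 opened from M, 2 extended
    PY = np.zeros((n + 1, m + 1), np.int8)  # 1 opened from M, 3 extended

    best = 0
    besti = 0
    bestj = 0
    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, m + 1):
            # X: consume a read base against a gap in the region
            open_v = M[i - 1, j] - gap_open - gap_extend
            ext_v = X[i - 1, j] - gap_extend
            if ext_v > open_v or (ext_v == open_v and OX[i - 1, j] <= OM[i - 1, j] + 1):
                X[i, j] = ext_v
                OX[i, j] = OX[i - 1, j]
                PX[i, j] = 2
            else:
                X[i, j] = open_v
                OX[i, j] = OM[i - 1, j] + 1
                PX[i, j] = 1
            # Y: consume a region base against a gap in the read
            open_v = M[i, j - 1] - gap_open - gap_extend
            ext_v = Y[i, j - 1] - gap_extend
            if ext_v > open_v or (ext_v == open_v and OY[i, j - 1] <= OM[i, j - 1] + 1):
                Y[i, j] = ext_v
                OY[i, j] = OY[i, j - 1]
                PY[i, j] = 3
            else:
                Y[i, j] = open_v
                OY[i, j] = OM[i, j - 1] + 1
                PY[i, j] = 1
            # M: diagonal; tie order M > X > Y > fresh start
            s = match if (ri == region[j - 1] and ri != 4) else mismatch
            bv = M[i - 1, j - 1]
            bo = OM[i - 1, j - 1]
            bp = 1
            if X[i - 1, j - 1] > bv or (X[i - 1, j - 1] == bv and OX[i - 1, j - 1] < bo):
                bv = X[i - 1, j - 1]
                bo = OX[i - 1, j - 1]
                bp = 2
            if Y[i - 1, j - 1] > bv or (Y[i - 1, j - 1] == bv and OY[i - 1, j - 1] < bo):
                bv = Y[i - 1, j - 1]
                bo = OY[i - 1, j - 1]
                bp = 3
            # a zero-score predecessor contributes nothing: always prefer a
            # fresh local start there, so tracebacks stop at the first column
            if 0 > bv or 0 == bv:
                bv = 0
                bo = 0
                bp = 0
            v = s + bv
            if v <= 0:
                # local floor: a non-positive prefix never helps an optimum
                M[i, j] = 0
                OM[i, j] = 0
                PM[i, j] = 0
            else:
                M[i, j] = v
                OM[i, j] = bo
                PM[i, j] = bp
                if v > best or (
                    v == best and (j < bestj or (j == bestj and i < besti))
                ):
                    best = v
                    besti = i
                    bestj = j
    return best, besti, bestj, PM, PX, PY


def _traceback(
    oriented: str, region_seq: str, besti: int, bestj: int, PM, PX, PY
) -> list[tuple[str, int, int]]:
    """Walk pointers back from the best cell; return forward-ordered columns."""
    steps: list[tuple[str, int, int]] = []
    i, j = besti, bestj
    state = 1  # M
    while True:
        if state == 1:
            a, b = oriented[i - 1], region_seq[j - 1]
            kind = "match" if (a == b and a != "N") else "mismatch"
            steps.append((kind, i - 1, j - 1))
            p = PM[i, j]
            i -= 1
            j -= 1
            if p == 0:
                break
            state = p
        elif state == 2:
            steps.append(("insertion", i - 1, j))
            p = PX[i, j]
            i -= 1
            state = 1 if p == 1 else 2
        else:
            steps.append(("deletion", i, j - 1))
            p = PY[i, j]
            j -= 1
            state = 1 if p == 1 else 3
    steps.reverse()
    return steps


def _merge_steps(steps: list[tuple[str, int, int]]) -> tuple[AlignmentOp, ...]:
    ops: list[AlignmentOp] = []
    for kind, r0, g0 in steps:
        if ops and ops[-1].kind == kind:
            prev = ops[-1]
            ops[-1] = AlignmentOp(kind, prev.length + 1, prev.read_offset, prev.region_offset)
        else:
            ops.append(AlignmentOp(kind, 1, r0, g0))
    return tuple(ops)


def _align_one_orientation(
    oriented: str, region_seq: str, params: AlignmentParams
) -> tuple[int, tuple[AlignmentOp, ...], Optional[tuple[int, int]], Optional[tuple[int, int]]]:
    best, besti, bestj, PM, PX, PY = _gotoh_fill(
        _encode(oriented),
        _encode(region_seq),
        np.int32(params.match_score),
        np.int32(params.mismatch_score),
        np.int32(params.gap_open),
        np.int32(params.gap_extend),
    )
    if best <= 0:
        return 0, (), None, None
    steps = _traceback(oriented, region_seq, besti, bestj, PM, PX, PY)
    ops = _merge_steps(steps)
    read_start = min(s[1] for s in steps if s[0] != "deletion") + 1
    region_start = min(s[2] for s in steps if s[0] != "insertion") + 1
    return int(best), ops, (region_start, bestj), (read_start, besti)


def align_read(
    read: str, region: ReferenceRegion, params: AlignmentParams = AlignmentParams()
) -> AlignmentResult:
    """Best local alignment of ``read`` against the region, either strand.

    Both the given orientation and its reverse complement are scored; the
    higher-scoring orientation is returned (ties go to "+"). A read that
    aligns nowhere returns score 0 with empty ops — never an error.
    """
    if not read:
        raise ParameterError("cannot align an empty read")
    read = read.upper()
    fwd = _align_one_orientation(read, region.sequence, params)
    rc = _align_one_orientation(revcomp(read), region.sequence, params)
    if rc[0] > fwd[0]:
        strand, (score, ops, region_span, read_span) = "-", rc
    else:
        strand, (score, ops, region_span, read_span) = "+", fwd
    n_match = sum(o.length for o in ops if o.kind == "match")
    n_mismatch = sum(o.length for o in ops if o.kind == "mismatch")
    n_ins = sum(o.length for o in ops if o.kind == "insertion")
    diag = n_match + n_mismatch
    identity = n_match / diag if diag else 0.0
    aligned_frac = (diag + n_ins) / len(read) if ops else 0.0
    return AlignmentResult(
        read_sequence=read,
        strand=strand,
        score=score,
        ops=ops,
        region_span=region_span,
        read_span=read_span,
        identity=identity,
        aligned_frac=aligned_frac,
    )


def recompute_score(aln: AlignmentResult, params: AlignmentParams) -> int:
    """Score implied by ``aln.ops`` under ``params`` (consistency check)."""
    score = 0
    for op in aln.ops:
        if op.kind == "match":
            score += params.match_score * op.length
        elif op.kind == "mismatch":
            score += params.mismatch_score * op.length
        else:
            score -= params.gap_open + params.gap_extend * op.length
    return score


def alignment_passes_filter(aln: AlignmentResult, params: AlignmentParams) -> bool:
    """True iff the alignment is good enough for the read to be genotyped.

    Failing reads contribute no genotype but stay in the sample's total-read
    and retained-read denominators.
    """
    return aln.aligned_frac >= params.min_aligned_frac and aln.identity >= params.min_identity
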