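"""Independent brute-force oracles used only by tests.

These deliberately share no code with the package: the alignment oracle is
a direct, explicit-gap-length dynamic program (O(n*m*(n+m))), and the
indel-normalization oracle enumerates the full equivalence class of an
indel by string equality. They exist so the fast implementations can be
checked against something too simple to be wrong.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_force_local_score(
    read: str,
    region: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> int:
    """Optimal local alignment score with affine gaps, by explicit gap lengths.

    G[i][j] is the best score of a local alignment ending with the aligned
    pair (read[i-1], region[j-1]); every interior gap of length g costs
    gap_open + gap_extend*g and is flanked by aligned pairs; alignments
    start and end with an aligned pair (a terminal gap can never raise the
    score). The empty alignment scores 0.
    """
    n, m = len(read), len(region)
    G = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        a = read[i - 1]
        for j in range(1, m + 1):
            b = region[j - 1]
            s = match if (a == b and a != "N") else mismatch
            cand = 0
            if G[i - 1][j - 1] > cand:
                cand = G[i - 1][j - 1]
            for g in range(1, i - 1 + 1):  # skip g read bases (gap in region)
                v = G[i - 1 - g][j - 1] - gap_open - gap_extend * g
                if v > cand:
                    cand = v
            for g in range(1, j - 1 + 1):  # skip g region bases (gap in read)
                v = G[i - 1][j - 1 - g] - gap_open - gap_extend * g
                if v > cand:
                    cand = v
            G[i][j] = s + cand
            if G[i][j] > best:
                best = G[i][j]
    return best


def delete_at(seq: str, i: int, length: int) -> str:
    return seq[:i] + seq[i + length :]


def insert_at(seq: str, i: int, ins: str) -> str:
    return seq[:i] + ins + seq[i:]


def deletion_equivalence_class(seq: str, i0: int, length: int) -> list[int]:
    """All 0-based offsets whose length-bp deletion yields the same string."""
    target = delete_at(seq, i0, length)
    return [
        i
        for i in range(len(seq) - length + 1)
        if delete_at(seq, i, length) == target
    ]


def insertion_equivalence_class(seq: str, i0: int, ins: str) -> list[tuple[int, str]]:
    """All (offset, bases) pairs producing the same inserted string."""
    target = insert_at(seq, i0, ins)
    out = []
    for i in range(len(seq) + 1):
        cand = target[i : i + len(ins)]
        if insert_at(seq, i, cand) == target:
            out.append((i, cand))
    return out


def oracle_normalize_deletion(
    seq: str, start: int, i0: int, length: int
) -> tuple[int, str, str]:
    """Leftmost-equivalent anchored (pos, ref, alt) for a deletion.

    ``start`` is the genomic coordinate of seq[0]; returns the minimum-pos
    member of the enumerated equivalence class, anchored VCF-style (right
    anchor when the leftmost placement touches the sequence start).
    """
    i = min(deletion_equivalence_class(seq, i0, length))
    if i > 0:
        return start + i - 1, seq[i - 1 : i + length], seq[i - 1]
    return start, seq[: length + 1], seq[length]


def oracle_normalize_insertion(
    seq: str, start: int, i0: int, ins: str
) -> tuple[int, str, str]:
    """Leftmost-equivalent anchored (pos, ref, alt) for an insertion."""
    i, bases = min(insertion_equivalence_class(seq, i0, ins))
    if i > 0:
        return start + i - 1, seq[i - 1], seq[i - 1] + bases
    return start, seq[0], bases + seq[0]
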