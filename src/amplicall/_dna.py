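"""Small DNA helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N, case preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase ``seq`` and verify it only uses A,C,G,T,N."""
    up = seq.upper()
    bad = set(up) - DNA_ALPHABET
    if bad:
        from .errors import InvalidSequenceError

        raise InvalidSequenceError(
            f"{what} contains non-ACGTN characters: {sorted(bad)!r}"
        )
    return up
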