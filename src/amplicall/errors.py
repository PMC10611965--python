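"""Exception hierarchy for amplicall.

Every user-facing failure derives from :class:`AmplicallError` so the CLI can
distinguish processing errors (exit 1) from usage errors (exit 2, raised by
click itself).
"""


class AmplicallError(Exception):
    """Base class for all amplicall errors."""


class RegionFormatError(AmplicallError):
    """Malformed CHR:START-END region string."""


class ReferenceIOError(AmplicallError):
    """Problems locating or slicing the reference sequence."""


class MissingChromosomeError(ReferenceIOError):
    """The FASTA file has no record matching the requested chromosome."""


class RegionBoundsError(ReferenceIOError):
    """Requested coordinates fall outside the FASTA record."""


class InvalidSequenceError(AmplicallError):
    """Sequence contains characters outside the A,C,G,T,N alphabet."""


class FastqParseError(AmplicallError):
    """Truncated or inconsistent FASTQ record."""


class PairingError(AmplicallError):
    """Mate files disagree in record count, or sample pairing is ambiguous."""


class ParameterError(AmplicallError):
    """Out-of-range analysis parameter (negative cutoff, bad threshold...)."""


class SimSpecError(AmplicallError):
    """Inconsistent simulation specification."""
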