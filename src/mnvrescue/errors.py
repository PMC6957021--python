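"""Exception hierarchy.

Input/usage problems (bad files, inconsistent contigs, out-of-range
coordinates) derive from :class:`InputError`; logic bugs surface as plain
exceptions so they are never swallowed by CLI error handling.
"""


class MnvRescueError(Exception):
    """Base class for all package errors."""


class InputError(MnvRescueError):
    """A problem with user-supplied inputs (files, coordinates, thresholds)."""


class NonCodingError(InputError):
    """A genomic position does not fall inside the CDS of a transcript."""

    def __init__(self, transcript_id: str, position) -> None:
        super().__init__(
            f"position {position} is not within the CDS of transcript {transcript_id}"
        )
        self.transcript_id = transcript_id
        self.position = position


class NotAVariantError(InputError):
    """An edit whose alternate base equals the reference base."""


class OrderingError(InputError):
    """Variant calls supplied out of sort order."""


class MergeRefusedError(MnvRescueError):
    """A cluster whose phase does not support merging (trans/ambiguous/unphased)."""


class ConsistencyError(InputError):
    """Cross-file inconsistency (e.g. merged members absent from the input VCF)."""


class FixtureSpecError(InputError):
    """An impossible simulated-fixture layout (codon overlap, CDS not a multiple of 3)."""
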