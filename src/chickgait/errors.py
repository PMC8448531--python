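"""Exception hierarchy used across the pipeline."""


class ChickGaitError(Exception):
    """Base class for all package errors."""


class FormatError(ChickGaitError):
    """A file does not match the expected tabular dialect (e.g. missing column)."""


class StructureError(ChickGaitError):
    """A file parses but violates a structural invariant (e.g. duplicate frames)."""


class ValidationError(ChickGaitError):
    """Parsed values violate a domain invariant (e.g. negative volume)."""


class InsufficientDataError(ChickGaitError):
    """Too little data for the requested operation (e.g. < 2 toe-offs)."""


class ResolutionError(ChickGaitError):
    """Temporal sampling too coarse for the requested operation."""


class NoGaitError(ChickGaitError):
    """No gait events detectable in a trajectory."""
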