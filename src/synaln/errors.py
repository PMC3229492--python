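"""Exception hierarchy.

Everything raised on bad user input derives from :class:`SynalnError` so the
CLI can map data problems to a single exit code.
"""


class SynalnError(Exception):
    """Base class for all package errors."""


class FormatError(SynalnError):
    """A file does not conform to its declared format."""


class ParameterError(SynalnError):
    """A parameter value is out of its admissible range."""


class ConsistencyError(SynalnError):
    """Inputs that must agree with each other do not."""


class LookupFailure(SynalnError):
    """A requested record (chain, sequence id, pair) is absent."""


class UndefinedResultError(SynalnError):
    """The requested quantity is undefined for these inputs (e.g. RMSD with
    zero usable residue pairs)."""
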