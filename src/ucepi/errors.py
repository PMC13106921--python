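"""Exception hierarchy for ucepi.

All package errors derive from :class:`UcepiError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class UcepiError(Exception):
    """Base class for all ucepi errors."""


class MalformedAlignmentError(UcepiError, ValueError):
    """An alignment file violates the aligned-FASTA contract
    (ragged rows, duplicate individual IDs, ...)."""


class EmptyInputError(UcepiError, ValueError):
    """An input file or collection contained no usable records."""


class NoDataError(UcepiError, ValueError):
    """All data was removed by filtering; nothing left to estimate from."""


class ParameterError(UcepiError, ValueError):
    """A model or configuration parameter is outside its valid domain."""


class UndefinedSiteError(UcepiError, ValueError):
    """Per-site diversity requested for a site with coverage < 2."""
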