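"""Exception hierarchy for the toolkit.

User-facing errors (bad input files, bad configuration) derive from
:class:`TwnError`; anything else escaping the pipeline is an internal bug.
"""


class TwnError(Exception):
    """Base class for all user-facing toolkit errors."""


class TrajectoryParseError(TwnError):
    """A coordinate file could not be parsed."""


class LigandError(TwnError):
    """A ligand structure or its region annotation is invalid."""


class TriclinicBoxError(TwnError):
    """Only orthorhombic simulation boxes are supported."""


class OverlapError(TwnError):
    """Two water molecules overlap (O-O below the sanity cutoff)."""


class ConfigError(TwnError):
    """Configuration file failed validation; message lists all problems."""


class GenerationError(TwnError):
    """A synthetic fixture failed its build-time self-check."""
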