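"""Exception hierarchy.

Everything raised on purpose derives from :class:`TriomicsError` so callers
can catch package errors without catching programming mistakes. The leaf
classes also derive from ``ValueError`` because they all signal bad input.
"""


class TriomicsError(Exception):
    """Base class for all errors raised by triomics."""


class ConfigError(TriomicsError, ValueError):
    """A simulation or pipeline configuration violates an invariant."""


class FormatError(TriomicsError, ValueError):
    """An on-disk file does not conform to the expected format."""


class DomainError(TriomicsError, ValueError):
    """A numeric argument is outside the operation's domain."""


class AlignmentError(TriomicsError, ValueError):
    """Two paired inputs do not share the required sample alignment."""


class ValidationError(TriomicsError, ValueError):
    """Planted-truth validation was asked about features that do not exist."""


class RankError(TriomicsError, ValueError):
    """More latent components requested than the data can support."""
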