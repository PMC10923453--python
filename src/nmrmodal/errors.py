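"""Exception hierarchy for the nmrmodal package.

Every error raised on bad user input derives from :class:`NMRModalError`
(and from :class:`ValueError`, so generic callers can catch either).
"""


class NMRModalError(Exception):
    """Base class for all nmrmodal errors."""


class InvalidParameterError(NMRModalError, ValueError):
    """A numeric parameter violates its documented domain."""


class AliasingError(InvalidParameterError):
    """A resonance frequency falls at or beyond the Nyquist band edge."""


class ConfigurationError(NMRModalError, ValueError):
    """A cohort design or pipeline configuration is internally inconsistent."""


class ParseError(NMRModalError, ValueError):
    """A text or binary input file could not be parsed."""


class InputTooShortError(NMRModalError, ValueError):
    """A signal is shorter than one analysis window."""


class ShapeError(NMRModalError, ValueError):
    """An array's shape is incompatible with the expected grid."""


class AssemblyError(NMRModalError, ValueError):
    """Spectrograms cannot be combined into one feature matrix."""


class ZeroVarianceError(NMRModalError, ValueError):
    """A row (sample) has zero variance and cannot be SNV-normalized."""


class RankError(NMRModalError, ValueError):
    """More components/factors requested than the data can support."""


class ClassCountError(NMRModalError, ValueError):
    """PLS-DA requires exactly two class labels."""


class DegenerateScoresError(NMRModalError, ValueError):
    """A score vector is constant; correlations are undefined."""
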