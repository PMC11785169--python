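"""Exception hierarchy for ringstate.

Everything derives from :class:`RingstateError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure modes of the pipeline (bad labels, malformed tables,
ambiguous trace-back, statistics on empty spectra, non-identifiable fits).
"""


class RingstateError(Exception):
    """Base class for all ringstate errors."""


class InvalidLabelError(RingstateError, ValueError):
    """A subunit state label is not part of the declared alphabet."""


class RingSizeError(RingstateError, ValueError):
    """Ring size / alphabet combination outside supported bounds."""


class FormatError(RingstateError, ValueError):
    """A particle or spectrum table does not conform to the expected layout."""


class AmbiguityError(RingstateError, ValueError):
    """Conflicting subunit records for the same (tetramer, position) slot."""


class EmptySpectrumError(RingstateError, ValueError):
    """A statistic was requested on a spectrum with no intact tetramers."""


class BoundaryError(RingstateError, ValueError):
    """Equilibrium quantities requested at p in {0, 1}; use interval bounds."""


class NonIdentifiableError(RingstateError, ValueError):
    """The coupled ring model cannot be fitted (e.g. single occupied class)."""


class FoldChangeError(RingstateError, ZeroDivisionError):
    """Fold change undefined because the reference statistic is zero."""


class ConfigError(RingstateError, ValueError):
    """Invalid configuration value (unknown method, rate out of range, ...)."""
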