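"""Exception hierarchy for rapmad."""


class RapmadError(Exception):
    """Base class for all rapmad errors."""


class FormatError(RapmadError):
    """Malformed input file (bad ATF header, unreadable table)."""


class ConfigError(RapmadError):
    """Invalid configuration value (missing column name, bad alpha, B < 2)."""


class DataError(RapmadError):
    """Inconsistent or degenerate data (duplicate addresses, mismatched
    address sets, non-finite or constant values where variation is required)."""


class BoundsError(RapmadError):
    """Spot index outside the array layout."""


class PeptideLookupError(RapmadError):
    """Peptide absent from every subarray of an array."""


class FitError(RapmadError):
    """Linear-model fit cannot proceed (a needle or subarray without controls)."""


class CorrectionError(RapmadError):
    """A spot addresses a factor level the fitted model has never seen."""


class StateError(RapmadError):
    """Operation on an unfitted or otherwise unready object."""


class QCError(RapmadError):
    """Quality-control stage error (degenerate regression, empty class,
    too few training spots, feature mismatch)."""


class EvaluationError(RapmadError):
    """Call/truth mismatch during evaluation."""
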