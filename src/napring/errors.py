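"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI: ConfigError -> 2, FormatError family -> 3,
SolverError family -> 4.
"""


class NapringError(Exception):
    """Base class for all package errors."""


class ConfigError(NapringError):
    """Invalid or incomplete run configuration."""


class FormatError(NapringError):
    """Unreadable or malformed input file."""


class EmptyStructureError(FormatError):
    """A coordinate file yielded zero atoms."""


class DegenerateInputError(NapringError):
    """Input too small or degenerate for the requested computation."""


class BuriedSiteError(NapringError):
    """Accessible-volume sampling left no unclashed label positions."""


class RangeError(NapringError):
    """A grid does not cover the observed values."""


class TopologyError(NapringError):
    """Spin topology and supplied distance components are inconsistent."""


class SolverError(NapringError):
    """An iterative solver failed to converge."""


class InsufficientTailError(NapringError):
    """Background-fit window contains too few points."""


class SingularRestraintError(NapringError):
    """Coincident label positions make the r^-3 average singular."""


class AlignmentError(NapringError):
    """Too few paired atoms for a least-squares superposition."""


class DockingFailure(NapringError):
    """No docked model passed the violation acceptance threshold."""

    def __init__(self, message, best_score=None):
        super().__init__(message)
        self.best_score = best_score


class FitQualityError(SolverError):
    """A curve fit did not converge or hit parameter bounds."""


class AlphabetError(NapringError):
    """Sequence contains a letter outside the standard amino-acid alphabet."""
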