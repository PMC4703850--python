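"""Exception hierarchy for couplekit.

All package errors derive from :class:`CouplekitError` so callers can catch
one base class at pipeline boundaries (the CLI maps them to exit code 1).
"""


class CouplekitError(Exception):
    """Base class for all couplekit errors."""


class InvalidParameterError(CouplekitError, ValueError):
    """A model, noise or estimator parameter violates its domain."""


class NoSteadyBackgroundError(CouplekitError):
    """k_out = 0 with nonzero nonspecific influx: background grows without bound."""


class IntegrationError(CouplekitError):
    """The ODE integrator failed or produced a non-finite state."""


class InsufficientDataError(CouplekitError):
    """Too few observations (distinct shells, cells, group members) to proceed."""


class UnidentifiableFitError(CouplekitError):
    """The profile is flat at background level; the decay constant is unidentifiable."""


class NoProbeFoundError(CouplekitError):
    """Probe identification could not split cells into probe / non-probe classes."""


class InsufficientNeighborsError(CouplekitError):
    """Fewer than six candidate neighbor cells are available for a probe."""


class UndefinedStrengthError(CouplekitError):
    """Probe intensity does not exceed background; the neighbor ratio is undefined."""


class SceneError(CouplekitError):
    """A labeled scene is malformed (shape mismatch, empty mask, no background)."""


class MosaicError(CouplekitError):
    """Mosaic generation failed (e.g. probe placement infeasible)."""
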