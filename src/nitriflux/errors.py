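"""Exception hierarchy shared across the analysis stages."""


class NitrifluxError(Exception):
    """Base class for all package errors."""


class ValidationError(NitrifluxError, ValueError):
    """An input violated a documented invariant; the message names the field."""


class UndefinedMixtureError(NitrifluxError, ValueError):
    """A pooled mixture has zero total concentration, so its atom% is undefined."""


class WindowUncoveredError(NitrifluxError, ValueError):
    """A flux window endpoint has no sample within the interpolation tolerance."""


class DegenerateFitError(NitrifluxError, ValueError):
    """A regression was requested on data with no variance in the predictor."""


class NoReciprocalHitsError(NitrifluxError, ValueError):
    """No bidirectional best hits survived the coverage filters.

    Carries a tally of how many hits each filter removed, for diagnostics.
    """

    def __init__(self, message: str, tally: dict | None = None):
        super().__init__(message)
        self.tally = dict(tally or {})


class NoAlignmentError(NitrifluxError, ValueError):
    """No genome fragments were retained above the identity floor."""


class SimulationError(NitrifluxError, RuntimeError):
    """A forward simulation left its physical domain (e.g. a pool went negative)."""
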