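"""Exception types shared across the planning pipeline."""


class IPDTError(Exception):
    """Base class for package errors."""


class UnknownTissueError(IPDTError, KeyError):
    """A voxel label is not registered in the tissue table."""

    def __init__(self, label: int):
        super().__init__(f"tissue label {label!r} is not registered in the tissue table")
        self.label = label


class GeometryError(IPDTError, ValueError):
    """A fiber trajectory, segment or point violates a geometric precondition."""


class OutOfGridError(GeometryError):
    """A world point falls outside the voxel grid."""


class FitError(IPDTError, RuntimeError):
    """Emission-profile fitting failed to converge."""


class PhantomSpecError(IPDTError, ValueError):
    """A synthetic phantom specification is internally inconsistent."""


class PlanNotValidatedError(IPDTError, RuntimeError):
    """A report or simulation was requested for a plan that still carries alerts."""

    def __init__(self, alerts):
        kinds = ", ".join(a.kind for a in alerts)
        super().__init__(
            f"plan has {len(alerts)} unresolved alert(s) [{kinds}]; "
            "resolve them before continuing"
        )
        self.alerts = list(alerts)
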