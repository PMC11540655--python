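"""Exception hierarchy for brachysim.

All errors raised by the package derive from :class:`BrachySimError` so callers
can catch simulation failures without catching programming errors.
"""


class BrachySimError(Exception):
    """Base class for all brachysim errors."""


class GeometryError(BrachySimError):
    """Invalid or degenerate geometry (ellipsoid outside block, coplanar points...)."""


class ResolutionError(BrachySimError):
    """Discretisation too coarse for the requested geometry."""


class CapacityError(BrachySimError):
    """More needles requested than template holes available over the target."""


class InputError(BrachySimError):
    """Invalid user input (empty mask, malformed config...)."""


class DiscretisationError(BrachySimError):
    """Support construction or mass lumping failed for a specific point."""


class NumericalError(BrachySimError):
    """Numerical failure in shape-function or constitutive evaluation."""


class InvertedElementError(NumericalError):
    """det F <= 0 at an integration point during assembly.

    Attributes
    ----------
    ip_index : int
        Offending integration point.
    event : str | None
        Insertion event during which the inversion occurred, if known.
    """

    def __init__(self, ip_index, det_f, event=None):
        self.ip_index = int(ip_index)
        self.det_f = float(det_f)
        self.event = event
        msg = f"deformation gradient inverted at integration point {ip_index} (det F = {det_f:.3e})"
        if event is not None:
            msg += f" during event '{event}'"
        super().__init__(msg)


class DivergenceError(NumericalError):
    """NaN/Inf encountered during explicit time stepping; reduce the time step."""
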