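"""Exception hierarchy for the quantification pipeline.

All pipeline errors derive from :class:`MTQuantError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal
invalid inputs rather than internal faults.
"""


class MTQuantError(Exception):
    """Base class for all mtquant errors."""


class ParameterError(MTQuantError, ValueError):
    """A generator or measurement parameter violates its invariants."""


class EmptyROIError(MTQuantError, ValueError):
    """An operation requiring a non-empty region of interest got an empty one."""


class DegenerateHistogramError(MTQuantError, ValueError):
    """A cutoff cannot be derived because the intensity histogram is constant."""

    def __init__(self, constant_value: float):
        self.constant_value = float(constant_value)
        super().__init__(
            f"cannot derive a cutoff from a constant image (value={constant_value!r})"
        )


class PairingError(MTQuantError, ValueError):
    """Measurements that must be paired (P/S lanes, same-ROI channels) are not."""


class EmptyConeError(MTQuantError, ValueError):
    """Both structural channels of a growth cone are fully sub-threshold."""


class DegenerateVarianceError(MTQuantError, ValueError):
    """A statistical test cannot run because within-group variance is zero."""


class EmptyTableError(MTQuantError, ValueError):
    """Every row of a table was excluded by validity filters."""
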