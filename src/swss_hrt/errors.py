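"""Exception hierarchy for the SWSS HRT model.

Stagnation (zero cumulative flow somewhere on a tap's supply path) is a
recoverable condition: profile-level code catches :class:`StagnantFlowError`
and marks the affected tap as undefined instead of reporting an infinite
retention time.
"""


class SWSSError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(SWSSError):
    """Non-positive pipe diameter or negative pipe length."""


class InvalidDemandError(SWSSError):
    """Negative water-consumption rate."""


class OutOfZoneError(SWSSError):
    """Floor queried against a zone that does not serve it."""


class DanglingTankError(SWSSError):
    """Tank that feeds no zone, directly or through downstream tanks."""


class TopologyValidationError(SWSSError):
    """Aggregated topology violations; carries the full list."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid topology: " + "; ".join(self.violations)
        )


class StagnantFlowError(SWSSError):
    """Zero cumulative demand on a traversed element; HRT undefined."""


class StagnantRiserError(StagnantFlowError):
    """Riser leg with zero total downstream demand."""


class StagnantSegmentError(StagnantFlowError):
    """Down-feed storey segment with zero cumulative demand."""

    def __init__(self, floor_j, message=None):
        self.floor_j = floor_j
        super().__init__(message or f"zero cumulative flow through floor {floor_j}")


class StagnantTapError(StagnantFlowError):
    """Tap whose own demand is zero; horizontal travel time undefined."""


class UnmodeledFloorError(SWSSError):
    """Floor outside the SWSS (mains-direct or not in any zone)."""


class DegenerateInputError(SWSSError):
    """Constant vector, mismatched lengths, or too few pairs for association."""


class CalibrationError(SWSSError):
    """Noise calibration impossible (constant HRT or target R2 outside (0,1))."""


class GenerationError(SWSSError):
    """Synthetic observation generation impossible (e.g. all taps stagnant)."""


class ConfigError(SWSSError):
    """Malformed run or topology configuration."""
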