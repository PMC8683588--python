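"""Exception types shared across the pipeline."""


class AortiqError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(AortiqError):
    """Lumen mask violates the tube-topology assumptions (components, loops, blobs)."""


class DegenerateGeometryError(AortiqError):
    """Geometric fit is ill-posed (e.g. near-straight centerline for a circle fit)."""


class SelfIntersectionError(AortiqError):
    """Phantom tube would self-intersect for the requested parameters."""


class AliasingError(AortiqError):
    """Requested velocities exceed the velocity sensitivity (venc)."""


class WaveformError(AortiqError):
    """A velocity waveform has no detectable systolic upstroke."""


class FlowFieldError(AortiqError):
    """A through-plane flow field cannot support the requested measurement."""


class CohortError(AortiqError):
    """Cohort table or model specification is invalid."""
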