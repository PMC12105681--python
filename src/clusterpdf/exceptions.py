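"""Exception hierarchy shared across the pipeline."""


class ClusterPDFError(Exception):
    """Base class for all package errors."""


class ParseError(ClusterPDFError):
    """A file could not be parsed under its declared format."""


class ValidationError(ClusterPDFError):
    """Input violates a documented contract (bad tag, non-monotone grid, ...)."""


class EmptySelectionError(ClusterPDFError):
    """A structure selection matched no atoms."""


class DegenerateGeometryError(ClusterPDFError):
    """Coincident atoms or otherwise unusable geometry."""


class UndefinedCoherenceError(ClusterPDFError):
    """PDF signal never exceeds the noise floor; coherence length undefined."""


class PairingError(ClusterPDFError):
    """Two models could not be matched site-by-site by label."""


class OptimizationError(ClusterPDFError):
    """An optimisation problem was unbounded or otherwise failed fatally."""


class EnsembleError(ClusterPDFError):
    """Too many ensemble members failed to refine."""
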