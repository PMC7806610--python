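"""Typed exceptions raised across the pipeline.

Every reader/operation either succeeds on well-formed input or raises one of
these; nothing is silently truncated or coerced.
"""


class ImsiqError(Exception):
    """Base class for all package errors."""


class SchemaError(ImsiqError):
    """A file is structurally readable but lacks a required column/field."""


class FormatError(ImsiqError):
    """A file violates the declared dialect (non-numeric cells, bad ordering)."""


class MetadataError(ImsiqError):
    """Required sidecar metadata is missing or inconsistent."""


class GeometryError(ImsiqError):
    """Acquisition/image geometry is inconsistent (extent, orthogonality, ragged lines)."""


class SizingError(ImsiqError):
    """A phantom extent cannot accommodate the requested structure."""


class ConfigError(ImsiqError):
    """Run configuration contains unknown keys or out-of-range values."""


class UnitError(ImsiqError):
    """An image carries the wrong unit for the requested operation."""


class FitError(ImsiqError):
    """Calibration fit is impossible or invalid (too few standards, bad slope)."""


class DegenerateInputError(ImsiqError):
    """Input admits no meaningful result (constant image for Otsu, k > distinct values)."""


class NumericalError(ImsiqError):
    """An iterative computation produced non-finite intermediates."""
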