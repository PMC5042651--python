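"""Exception hierarchy used across the package."""


class GastruMorphError(Exception):
    """Base class for all errors raised by gastrumorph."""


class ParameterError(GastruMorphError, ValueError):
    """Invalid generator or analysis parameter."""


class FormatError(GastruMorphError, ValueError):
    """Malformed input file (stack, table, mesh, channel layout)."""


class ConfigError(GastruMorphError, ValueError):
    """Unknown key or type mismatch in a configuration file."""


class GeometryError(GastruMorphError, ValueError):
    """Degenerate geometry: collinear/coplanar clouds, open surfaces, ..."""


class SegmentationError(GastruMorphError, RuntimeError):
    """Segmentation produced no usable object."""


class AnalysisError(GastruMorphError, RuntimeError):
    """Downstream quantification cannot proceed (empty ROI, missing mesh)."""
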