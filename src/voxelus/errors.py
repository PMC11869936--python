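"""Exception hierarchy shared across the toolbox."""


class VoxelusError(Exception):
    """Base class for all toolbox errors."""


class SchemaError(VoxelusError):
    """A sidecar or config file is missing required fields or is malformed."""


class ValidationError(VoxelusError):
    """Loaded data violates a type invariant (NaN, negative intensity, ...)."""


class LookupError_(VoxelusError):
    """An acronym, condition, subject or cluster id is not present."""


class ParameterError(VoxelusError):
    """A numeric parameter is outside its documented domain."""


class ShapeError(VoxelusError):
    """Array shapes are inconsistent between inputs."""


class EmptyRegionError(VoxelusError):
    """An operation was asked to summarize a region with no voxels."""


class DegenerateBaselineError(VoxelusError):
    """Baseline mean is nonpositive, so a percent-change trace is undefined."""


class ComparabilityError(VoxelusError):
    """Two maps do not cover the same analyzed-voxel set."""
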