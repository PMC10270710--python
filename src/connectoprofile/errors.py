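"""Exception hierarchy for connectome profiling."""


class ConnectomeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ConnectomeError):
    """A file could not be parsed into the expected tabular shape."""


class SymmetryError(ConnectomeError):
    """A connectivity matrix is asymmetric beyond the repairable tolerance."""


class DimensionError(ConnectomeError):
    """Matrices or tables in a cohort disagree on the number of nodes."""


class CohortError(ConnectomeError):
    """The cohort composition is invalid (e.g., fewer than two controls)."""


class MetricUndefinedError(ConnectomeError):
    """A graph metric is undefined for the given input (e.g., empty graph)."""


class ConfigError(ConnectomeError):
    """Invalid or inconsistent run configuration."""
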