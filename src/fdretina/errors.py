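"""Exception hierarchy used across the pipeline."""


class FdretinaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FdretinaError, ValueError):
    """Invalid parameter or configuration value."""


class InputError(FdretinaError, ValueError):
    """Invalid input data (wrong shape, empty structure, missing cells)."""


class GenerationError(FdretinaError, RuntimeError):
    """Synthetic generation produced a degenerate result."""


class ProcessingError(FdretinaError, RuntimeError):
    """A pipeline stage failed its post-condition (e.g. continuity check)."""


class DegenerateInputError(InputError):
    """Statistically degenerate input (zero variance)."""
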