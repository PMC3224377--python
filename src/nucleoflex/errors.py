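"""Exception types shared across the package."""


class NucleoflexError(Exception):
    """Base class for all package-specific errors."""


class InvalidSequenceError(NucleoflexError, ValueError):
    """A DNA string contains characters outside {A, C, G, T} (N is handled
    separately by operations that tolerate ambiguity)."""


class IllConditionedError(NucleoflexError, ValueError):
    """A matrix input is singular, non-symmetric or otherwise unusable."""


class DimensionError(NucleoflexError, ValueError):
    """An array or sequence has the wrong length/shape for the operation."""


class ConfigError(NucleoflexError, ValueError):
    """Inconsistent or out-of-range analysis parameters."""
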