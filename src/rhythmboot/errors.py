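"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class RaggedDatasetError(ValidationError):
    """A probe-level table is missing at least one (gene, probe, time) cell."""


class DegreesOfFreedomError(ValueError):
    """Too few rows/columns/replicates for the requested statistic."""


class AlignmentError(ValueError):
    """Score or expression objects do not share the same gene set/order."""


class RegistryError(KeyError):
    """Unknown normalization or detector name."""


class StateError(RuntimeError):
    """An operation was called before a required quantity was computed."""
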