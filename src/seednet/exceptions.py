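"""Package-wide exception types."""


class SeednetError(Exception):
    """Base class for errors raised by seednet."""


class UndefinedMetricError(SeednetError):
    """A metric or statistic is undefined for the given input.

    Raised, e.g., for an empty matrix, a degenerate shape, or a test in
    which every paired difference is zero.  Callers that aggregate over
    ensembles (``delta_transform``) catch this and skip the sample.
    """


class EdgeListError(SeednetError):
    """Malformed or inconsistent edge-list input."""
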