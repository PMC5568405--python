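"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when an argument violates a documented precondition."""


class DegenerateGeometryError(ValueError):
    """Raised when two interacting agents coincide exactly.

    The unit vector between coincident agents is undefined, so the force
    on each cannot be oriented.  With the default lower repulsion bound of
    zero the repulsive branch diverges as the separation shrinks, which
    keeps moving agents apart; exact coincidence can therefore only be
    produced by a pathological initial configuration.
    """


class UndefinedMetricError(ValueError):
    """Raised when a network metric is undefined for the given graph size."""


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its documented schema."""
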