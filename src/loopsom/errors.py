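"""Exception hierarchy shared across the package."""


class LoopsomError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(LoopsomError):
    """Degenerate or inconsistent coordinate geometry (collinear torsion,
    missing backbone atom, subset mismatch between frames)."""


class UndefinedStatisticError(LoopsomError):
    """A statistic is undefined for the given input (e.g. circular mean of a
    near-uniform angle set, sample SD of a single value)."""


class ValidationError(LoopsomError):
    """Invalid domain-object construction or operation arguments."""
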