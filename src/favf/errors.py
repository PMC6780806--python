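"""Exception hierarchy shared across the package."""


class FavfError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FavfError, ValueError):
    """A parameter violates a documented precondition."""


class GenerationError(FavfError):
    """Synthetic scene generation could not satisfy its constraints."""


class NoCellError(FavfError):
    """An operation that requires a cell found an empty foreground."""


class EstimationError(FavfError):
    """A measurement could not be derived from the data (e.g. no profile
    intersections when estimating the focused diameter)."""


class DegenerateGeometryError(FavfError):
    """Blur diameters at consecutive planes coincide; the depth equation
    has a vanishing denominator."""


class NegativeBlurError(FavfError):
    """A measured blur diameter fell below the focused diameter, which is
    inconsistent with the defocus model."""
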