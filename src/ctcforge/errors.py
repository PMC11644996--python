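"""Exception taxonomy shared across the toolkit."""


class ConfigurationError(ValueError):
    """A configuration value violates its documented invariant."""


class CapacityError(RuntimeError):
    """Requested object placement cannot be satisfied within bounded retries."""


class PlacementError(RuntimeError):
    """No valid paste position found within the attempt budget."""


class EmptyMaskError(ValueError):
    """A mask with zero foreground pixels where foreground is required."""


class BackendError(RuntimeError):
    """A segmentation backend is unavailable."""


class DegenerateBoxError(ValueError):
    """A box with non-positive width or height."""


class ShapeError(ValueError):
    """Mismatched shapes between paired inputs."""
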