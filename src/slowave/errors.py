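"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A parameter or input violates a documented precondition."""


class ChannelLookupError(KeyError):
    """A channel label is not present in the recording or montage."""


class RangeError(ValueError):
    """An event or window lies outside the recording bounds."""


class UndefinedMPFError(ValueError):
    """Median power frequency is undefined (zero power in the band)."""


class PlacementError(RuntimeError):
    """Random event placement could not satisfy the overlap constraints."""
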