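"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class DegenerateImageError(ValidationError):
    """The intensity histogram cannot support the requested operation
    (e.g. thresholding a constant image)."""


class CapacityError(RuntimeError):
    """A synthetic scene could not be placed within the bounded retry budget.

    Raised with a hint to request fewer or smaller objects.
    """
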