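"""Exception types shared across the toolkit."""


class MritexError(Exception):
    """Base class for all toolkit errors."""


class ImageIOError(MritexError):
    """An image or mask file could not be read or written."""


class ShapeMismatchError(MritexError):
    """Image and mask (or pred and truth) shapes disagree."""


class EmptyMaskError(MritexError):
    """An operation that needs in-mask pixels received an empty mask."""


class DegenerateMatrixError(MritexError):
    """A texture matrix could not be built (e.g. no valid pixel pair)."""


class PhantomSpecError(MritexError):
    """A phantom specification is invalid or unsatisfiable."""


class TrainingError(MritexError):
    """Model training failed (e.g. NaN loss)."""
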