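"""Exception types shared across the package."""


class LeafscapeError(Exception):
    """Base class for all package errors."""


class ParameterError(LeafscapeError, ValueError):
    """A parameter is outside its documented domain."""


class ShapeError(LeafscapeError, ValueError):
    """An input image/contour/matrix is degenerate or malformed."""


class TreeExcludedError(LeafscapeError):
    """A tree fails an inclusion rule (e.g. leaf count outside 8-10).

    This is a control-flow signal, not a crash: batch summarizers catch it
    and drop the tree.
    """


class ConvergenceError(LeafscapeError, RuntimeError):
    """An iterative fit failed to converge."""
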