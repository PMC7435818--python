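"""Exception hierarchy for the monitoring pipeline.

Every failure mode that a caller may want to branch on has its own class;
all inherit from :class:`IeamscError` so batch drivers can catch the whole
family while letting programming errors propagate.
"""


class IeamscError(Exception):
    """Base class for all pipeline errors."""


class EmptyInputError(IeamscError):
    """Raised when an image (or image list) contains no pixels."""


class DegenerateHistogramError(IeamscError):
    """Raised when the luma histogram cannot support trough detection.

    Covers all-zero histograms, histograms with all mass in a single bin
    (e.g. a flat single-colour image), and threshold pairs that leave no
    retained band between them.
    """


class EmptyBandError(IeamscError):
    """Raised when a channel has no energy inside the retained band."""


class UntrainedModelError(IeamscError):
    """Raised when a decision is requested from a degenerate model
    (non-positive standard distance sum)."""


class ConfigMismatchError(IeamscError):
    """Raised when feature points produced under different configurations
    are mixed, or a model is applied under a different configuration."""
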