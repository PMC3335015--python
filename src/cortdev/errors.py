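"""Exception hierarchy for cortdev."""


class CortdevError(Exception):
    """Base class for all cortdev errors."""


class InvalidArgumentError(CortdevError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateDesignError(CortdevError, ValueError):
    """The design matrix (or data) cannot support the requested fit."""


class InsufficientDataError(CortdevError, ValueError):
    """Too few subjects remain after filtering to run the analysis."""


class CollinearityError(CortdevError, ValueError):
    """The regression design is rank deficient; names the aliased terms."""


class ConfigurationError(CortdevError, ValueError):
    """A configuration object is internally inconsistent."""


class AlignmentError(CortdevError, ValueError):
    """Two tables that must share row order / subjects do not."""
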