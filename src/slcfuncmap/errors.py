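"""Exception hierarchy shared across the pipeline stages."""


class SlcFuncmapError(Exception):
    """Base class for all package errors."""


class ParameterError(SlcFuncmapError, ValueError):
    """An argument is outside its valid range or inconsistent with the data."""


class ValidationError(SlcFuncmapError, ValueError):
    """An input file or in-memory structure violates a structural invariant."""


class TermLookupError(SlcFuncmapError, KeyError):
    """A term/feature id is not registered where it is required to be."""


class AssignmentError(SlcFuncmapError, RuntimeError):
    """Internal-standard assignment could not be completed for some metabolite."""
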