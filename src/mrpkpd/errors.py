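"""Exception hierarchy."""


class MrpkpdError(Exception):
    """Base class for all package errors."""


class ValidationError(MrpkpdError, ValueError):
    """Invalid input data, parameters, or configuration."""


class EstimationError(MrpkpdError, RuntimeError):
    """A fit could not be performed (e.g. under-determined data)."""


class DatasetError(MrpkpdError, ValueError):
    """A dataset file violates the expected schema or semantics."""
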