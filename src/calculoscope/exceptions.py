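"""Exception types shared across the pipeline."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal.

    Raised for constant images passed to threshold selection, empty
    co-occurrence accumulations, all-zero matrices, and similar cases
    where no meaningful result exists.
    """


class ContractViolationError(ValueError):
    """A documented precondition of an operation was violated.

    Distinct from ``DegenerateInputError``: the caller passed data that
    breaks an explicit contract (e.g. non-positive gray values fed to the
    entropy transform, an unnormalized matrix fed to the texture
    statistics), rather than data that is merely uninformative.
    """
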