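"""Exception types shared across the package."""


class ParameterDomainError(ValueError):
    """A model parameter violates its domain (e.g. non-positive diffusion SD)."""


class DataIntegrityError(ValueError):
    """Input data violate a structural invariant (e.g. RT on a withheld trial)."""


class NumericalError(RuntimeError):
    """A numerical routine failed to reach its accuracy target."""
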