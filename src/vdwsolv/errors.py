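"""Exception types for invalid thermodynamic inputs."""


class DomainError(ValueError):
    """An input is outside the physical domain of a formula."""


class OverpackedLiquidError(DomainError):
    """The packing product ρ₁b₁ reached or exceeded 1: no free volume left."""
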