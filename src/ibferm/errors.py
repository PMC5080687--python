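"""Exception hierarchy.

``ValidationError`` marks bad inputs (files, records, configs); ``ComputationError``
marks metric computations whose preconditions fail on otherwise valid data
(zero consumption, zero NAD(P)H requirement). The CLI maps these to exit
codes 2 and 3 respectively.
"""


class IBFermError(Exception):
    """Base class for all package errors."""


class ValidationError(IBFermError, ValueError):
    """Invalid input data or configuration."""


class UnknownSpeciesError(ValidationError):
    """Species id not present in the registry."""

    def __init__(self, species_id: str, registered: tuple[str, ...]):
        self.species_id = species_id
        self.registered = registered
        super().__init__(
            f"unknown species {species_id!r}; registered ids: {', '.join(registered)}"
        )


class ComputationError(IBFermError):
    """A metric's precondition fails on otherwise valid data."""


class CoefficientError(ComputationError):
    """A required NAD(P)H coefficient is unset or not enabled for a species."""
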