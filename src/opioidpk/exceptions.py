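"""Exception hierarchy shared across the package."""


class OpioidPKError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OpioidPKError, ValueError):
    """An input violated a domain invariant (non-positive rate, bad window...)."""


class OpioidNotFoundError(OpioidPKError, KeyError):
    """Requested opioid (or phase) is not present in the parameter table."""

    def __str__(self) -> str:  # KeyError quotes its message by default
        return self.args[0] if self.args else ""


class NotApplicableError(OpioidPKError):
    """Operation requires data the parameter entry does not carry (e.g. k_a)."""


class DesignInfeasibleError(OpioidPKError):
    """No practical dosing interval satisfies the constraints.

    Raised e.g. when tau_max falls below the smallest practical interval;
    the message recommends a constant infusion or a controlled-release form.
    """


class InsufficientDataError(OpioidPKError):
    """Too few study values to resample (bootstrap needs at least two)."""
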