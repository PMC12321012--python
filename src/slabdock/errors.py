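"""Exception hierarchy shared across the package."""


class SlabdockError(Exception):
    """Base class for all package errors."""


class ValidationError(SlabdockError):
    """An input object violates a structural invariant."""


class InputFileError(SlabdockError):
    """A file could not be read or parsed."""


class MissingElementError(ValidationError):
    """A data table lacks an entry for an element in the structure."""


class ChargeMismatchError(ValidationError):
    """Per-atom charges disagree with the declared net charge or atom count."""


class AtomOverlapError(ValidationError):
    """A pair distance fell below the hard minimum-distance guard."""


class ChargeAssignmentError(SlabdockError):
    """No charge-neutral oxidation-state assignment exists."""


class AdapterError(SlabdockError):
    """An external partial-charge adapter failed; never silently zeroed."""
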