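"""Exception hierarchy shared across the package."""


class CanopyGrowthError(Exception):
    """Base class for all package errors."""


class SchemaError(CanopyGrowthError):
    """A raw CSV table does not conform to its documented schema."""


class IntegrityError(CanopyGrowthError):
    """Cross-table referential integrity is broken (orphan rows, missing links)."""


class DomainError(CanopyGrowthError):
    """A derivation was asked to operate outside its mathematical domain."""


class InversionError(CanopyGrowthError):
    """A trait combination cannot be realised by any physical measurement set."""


class InferenceError(CanopyGrowthError):
    """A statistical model could not be estimated (rank deficiency, no data)."""
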