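"""Exception hierarchy.

Every error raised by the package derives from :class:`EquipanelError` so
callers can catch the whole family; the subclasses distinguish schema
problems (wrong columns), value-level validation, and the degenerate inputs
the index formulas cannot handle.
"""


class EquipanelError(Exception):
    """Base class for all equipanel errors."""


class SchemaError(EquipanelError):
    """An input table is missing required columns or has malformed ones."""


class PanelValidationError(EquipanelError):
    """A record violates a panel invariant (non-positive population/area,
    negative counts, unbalanced panel, duplicate keys)."""


class UnsupportedCombinationError(EquipanelError):
    """A (tier, kind) combination that does not exist, e.g. village-clinic beds."""


class YearRangeError(EquipanelError):
    """A requested year lies outside the panel's year range."""


class DegenerateAllocationError(EquipanelError):
    """All resource quantities in a cross-section are zero; Lorenz/Gini undefined."""


class ZeroResourceError(EquipanelError):
    """A region has zero resources where the Theil log term diverges."""


class SeriesTooShortError(EquipanelError):
    """A trend test needs at least two observations."""


class DegenerateVarianceError(EquipanelError):
    """Mann-Kendall variance is zero while S is non-zero (corrupt input)."""


class GrowthRateError(EquipanelError):
    """Growth rate undefined (zero or non-positive base value)."""


class ConfigError(EquipanelError):
    """Invalid synthetic-generator configuration."""
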