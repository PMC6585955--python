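"""Exception hierarchy.

Plain ``ValueError``/``KeyError``/``IndexError`` are used for simple
argument mistakes; the classes here mark failures with domain meaning
so callers can catch them selectively.
"""


class CagecraftError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CagecraftError, ValueError):
    """A molecular file or line notation could not be parsed."""


class SchemaError(CagecraftError, ValueError):
    """JSON persistence payload is malformed or foreign."""


class StateError(CagecraftError, RuntimeError):
    """Operation requires state the molecule does not have (e.g. a conformer)."""


class TopicityError(CagecraftError, ValueError):
    """A building block has the wrong number of functional groups for the task."""


class ConfigurationError(CagecraftError, ValueError):
    """No functional group could be resolved for a building block."""


class DegenerateGeometryError(CagecraftError, ValueError):
    """A geometric construction is undefined for this arrangement of atoms."""


class PlacementError(CagecraftError, ValueError):
    """A building block cannot be placed at a topology position."""


class ApplicabilityError(CagecraftError, TypeError):
    """Operation does not apply to this kind of object."""


class ContractViolationError(CagecraftError, RuntimeError):
    """A refinement plug-in broke the atom-identity contract."""
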