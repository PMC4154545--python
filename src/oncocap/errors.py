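"""Exception hierarchy for the planning pipeline."""


class OncocapError(Exception):
    """Base class for all package errors."""


class DomainError(OncocapError, ValueError):
    """An input is outside the domain an operation is defined on."""


class ConfigurationError(OncocapError, ValueError):
    """Required configuration (population, fraction record, norm) is missing or inconsistent."""


class FormatError(OncocapError, ValueError):
    """A data file is malformed (missing columns, unparseable cells)."""
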