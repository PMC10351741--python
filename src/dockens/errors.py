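"""Exception hierarchy shared by all dockens modules."""


class DockensError(Exception):
    """Base class for all toolkit errors."""


class FormatError(DockensError, ValueError):
    """Malformed input text or structure file."""


class ShapeError(DockensError, ValueError):
    """Coordinate arrays or chain lengths do not match."""


class DataError(DockensError, KeyError):
    """A required atom or residue is missing from a structure."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return self.args[0] if self.args else ""


class ConfigurationError(DockensError, ValueError):
    """Inconsistent or impossible run configuration."""


class DomainCheckError(DockensError, ValueError):
    """An operation was called outside its mathematical domain (e.g. M < 2)."""


class NoContactsError(DockensError, RuntimeError):
    """A cleavage call was requested on an all-zero contact histogram."""
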