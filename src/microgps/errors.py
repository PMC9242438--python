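"""Exception hierarchy shared across the toolkit.

Validation failures (bad coordinates, inconsistent schedules, malformed
input files) raise :class:`ValidationError`; the CLI maps these to exit
code 2.  Truly structural problems with binary records raise
:class:`FormatError`.  :class:`MemoryFullError` signals that the EEPROM
image has no room for another record — the simulator uses it to stop
recording.
"""


class MicroGpsError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(MicroGpsError, ValueError):
    """An input violates a documented precondition."""


class FormatError(MicroGpsError, ValueError):
    """A binary record or file does not match the documented layout."""


class MemoryFullError(MicroGpsError):
    """The memory image cannot hold another fix record."""
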