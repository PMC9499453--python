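"""Exception hierarchy.

Parameter-validation problems raise plain :class:`ValueError` (usage errors);
anything wrong with *data* (files, spectra, databases) derives from
:class:`ThzSsmError` so the CLI can map the two classes to distinct exit codes.
"""


class ThzSsmError(Exception):
    """Base class for data and format errors."""


class SpectrumParseError(ThzSsmError):
    """A spectrum file could not be parsed.

    ``line`` carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class InputTooShortError(ThzSsmError):
    """A spectrum has fewer samples than the minimum of 8."""


class NoOverlapError(ThzSsmError):
    """Two spectra share no frequency range."""


class DatabaseError(ThzSsmError):
    """A spectral database is malformed (duplicate names, empty, ...)."""


class CorpusTooSmallError(DatabaseError):
    """A database search needs at least two entries."""


class EmptyPeakListError(ThzSsmError):
    """An operation needed spectral feature points but the peak list is empty."""
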