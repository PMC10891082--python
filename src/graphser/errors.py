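"""Exception hierarchy for the graphser pipeline.

Every stage raises a subclass of :class:`GraphserError` so callers (and the
CLI) can distinguish bad parameters from degenerate signals that should be
skipped and logged rather than abort a whole corpus run.
"""


class GraphserError(Exception):
    """Base class for all graphser errors."""


class ParameterError(GraphserError, ValueError):
    """An argument value violates an operation's contract."""


class AudioFormatError(GraphserError):
    """A file could not be read as PCM WAV."""


class DegenerateSignalError(GraphserError):
    """A signal is too short / constant for the requested transform.

    Corpus-level drivers catch this per utterance, log the reason, and skip
    the utterance instead of failing the run.
    """


class SchemaError(GraphserError):
    """A CSV table is missing required columns or rows."""


class ConfigurationError(GraphserError):
    """The run configuration is inconsistent with the data (e.g. a LOSO fold
    whose training set has fewer than two emotion classes)."""
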