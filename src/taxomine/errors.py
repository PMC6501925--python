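"""Exception hierarchy shared across the pipeline."""


class TaxomineError(Exception):
    """Base class for all pipeline errors."""


class GazetteerError(TaxomineError):
    """Malformed or inconsistent gazetteer input."""


class IntervalLookupError(TaxomineError, KeyError):
    """An interval name is absent from the gazetteer (input was well-formed)."""


class ConlluParseError(TaxomineError):
    """A CoNLL-U file violates the sentence-block format."""


class ParserUnavailableError(TaxomineError):
    """No live dependency parser hook is registered."""


class ParserHookError(TaxomineError):
    """A registered parser hook raised while parsing a document."""


class PathFailure(TaxomineError):
    """No dependency path connects the two spans (disconnected parse)."""


class TrainingError(TaxomineError):
    """Classifier training could not proceed or diverged."""
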