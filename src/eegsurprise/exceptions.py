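"""Exception hierarchy for pipeline-specific failure modes."""


class EEGSurpriseError(Exception):
    """Base class for all package-specific errors."""


class DesignInfeasibleError(EEGSurpriseError):
    """Stimulus-set or sequence constraints cannot be satisfied."""


class DegenerateInputError(EEGSurpriseError):
    """Input is numerically degenerate (zero variance, zero vector, ...)."""


class SequencingError(EEGSurpriseError):
    """Trial-order constraint unsatisfiable within the retry budget."""


class AlignmentError(EEGSurpriseError):
    """Item orders or time axes of combined objects do not match."""


class ItemLookupError(EEGSurpriseError, KeyError):
    """Requested item/word/channel is unknown."""


class CollinearityError(EEGSurpriseError):
    """Regression design is rank deficient."""


class InferenceError(EEGSurpriseError):
    """Group-level statistic is undefined for the given data."""


class GeneratorError(EEGSurpriseError):
    """Synthetic-data construction failed to meet its target."""
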