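"""Exception hierarchy.

Every error raised by the library derives from :class:`SeqSCMError`, so
callers (and the CLI) can separate domain failures from programming errors.
"""


class SeqSCMError(Exception):
    """Base class for all seqscm errors."""


class FastaError(SeqSCMError):
    """Unreadable or invalid FASTA input."""


class DatasetError(SeqSCMError):
    """Invalid two-class dataset (empty class, duplicated identifiers)."""


class FeatureError(SeqSCMError):
    """Sequence unusable for the requested composition feature."""


class CardError(SeqSCMError):
    """Invalid scoring card (range violation, missing pairs, bad file)."""


class ConfigError(SeqSCMError):
    """Invalid optimizer / run configuration."""


class EvaluationError(SeqSCMError):
    """Invalid evaluation input (empty score list, degenerate fold)."""


class AnalysisError(SeqSCMError):
    """Invalid analysis input (zero-variance vector, bad property table)."""
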