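"""Exception hierarchy for hedgescope.

Readers raise :class:`FormatError` for malformed input syntax,
:class:`AlignmentError` when parallel annotation layers disagree on token
counts, and :class:`TreeError` for ill-formed dependency structures.
Pipeline-level misconfiguration maps to :class:`ConfigError` (CLI exit
code 2); data problems map to the others (exit code 3).
"""


class HedgescopeError(Exception):
    """Base class for all hedgescope errors."""


class FormatError(HedgescopeError):
    """Malformed input syntax (unbalanced tags/parens, bad columns)."""


class AnnotationError(HedgescopeError):
    """Inconsistent cue/scope annotation (e.g. cue outside any scope)."""


class TreeError(HedgescopeError):
    """Ill-formed dependency tree (cycle, multiple roots, bad head)."""


class AlignmentError(HedgescopeError):
    """Annotation layers disagree with the token sequence."""


class FeaturizationError(HedgescopeError):
    """Instance lacks a feature view required by the kernel mode."""


class TrainingError(HedgescopeError):
    """Training input cannot produce a classifier (e.g. single class)."""


class ProtocolError(HedgescopeError):
    """Evaluation protocol violated (e.g. missing prediction for a cue)."""


class ConfigError(HedgescopeError):
    """Invalid or inconsistent run configuration."""
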