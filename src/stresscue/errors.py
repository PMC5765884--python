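"""Exception hierarchy used across the package."""


class StressCueError(Exception):
    """Base class for all package errors."""


class NotDisyllabicError(StressCueError):
    """The letter string does not contain exactly two vowel groups."""


class InvalidInputError(StressCueError):
    """Empty or otherwise malformed input string."""


class UnknownVowelError(StressCueError):
    """A vowel group is not in the letter inventory."""


class TransformNotApplicableError(StressCueError):
    """A matching transform cannot be applied to this spelling."""


class GenerationError(StressCueError):
    """Stimulus or lexicon generation failed within the retry budget."""


class DegenerateProbabilityError(StressCueError):
    """A probability argument sits at 0 or 1 where the update is undefined."""


class ParameterError(StressCueError):
    """Missing or inconsistent model parameters."""


class EncodingError(StressCueError):
    """A spelling does not fit the orthographic slot template."""


class EvaluationError(StressCueError):
    """Mismatched or degenerate inputs to an evaluation routine."""
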