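"""Exception hierarchy.

Every failure mode a caller may want to branch on gets its own class;
all inherit from :class:`HeckRegioError` so CLI code can catch one type.
"""


class HeckRegioError(Exception):
    """Base class for all package-specific errors."""


class InputError(HeckRegioError):
    """A SMILES string or input file could not be parsed."""


class SubstrateError(HeckRegioError):
    """Inputs parsed but do not constitute a valid Heck substrate pair."""


class AmbiguousSubstrateError(SubstrateError):
    """More than one distinct monosubstituted alkene unit was found."""


class EnumerationError(HeckRegioError):
    """A rewrite template failed to apply to a valid substrate pair."""

    def __init__(self, message: str, pattern: str | None = None):
        super().__init__(message)
        self.pattern = pattern


class TemplateError(HeckRegioError):
    """A catalyst-core template asset is missing or malformed."""


class EmbeddingError(HeckRegioError):
    """Constrained 3D embedding could not be set up for a complex."""


class PipelineError(HeckRegioError):
    """A stage of the energy-refinement pipeline could not be configured."""


class CurationError(HeckRegioError):
    """Reaction-record curation or scoring failed."""
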