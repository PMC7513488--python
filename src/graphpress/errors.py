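"""Exception hierarchy.

Every error raised by the library derives from :class:`GraphPressError` so
callers (and the CLI's per-record skip logic) can catch one base class.
"""


class GraphPressError(Exception):
    """Base class for all library errors."""


class ParseError(GraphPressError):
    """Input string/record could not be parsed as a molecule."""


class DomainError(GraphPressError):
    """An atom or edge feature lies outside the encodable feature domains."""


class FragmentError(GraphPressError):
    """Molecule contains more than one disconnected fragment."""


class ConfigError(GraphPressError):
    """Malformed pattern-registry configuration."""


class DecompressError(GraphPressError):
    """Compressed graph is inconsistent with the pattern registry."""


class MalformedTensorError(GraphPressError):
    """Tensor violates symmetry/diagonal/one-hot structural invariants."""


class GenerationError(GraphPressError):
    """Synthetic molecule generation failed after bounded retries."""


class EmptyInputError(GraphPressError):
    """A metric was requested over an empty collection."""
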