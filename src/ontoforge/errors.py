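"""Exception hierarchy shared across the package."""


class OntoforgeError(Exception):
    """Base class for all errors raised by this package."""


class XmlParseError(OntoforgeError):
    """Malformed XML; message carries the line number when known."""


class UnsupportedConstructError(OntoforgeError):
    """An input uses a construct outside the supported subset."""


class DanglingReferenceError(OntoforgeError):
    """A declaration references something that was never declared."""


class PathSyntaxError(OntoforgeError):
    """An attribute path expression is syntactically invalid."""


class CoercionError(OntoforgeError):
    """A value does not conform to its declared value kind."""


class StrictReadError(OntoforgeError):
    """Instance data violates the schema under strict reading."""


class MappingSyntaxError(OntoforgeError):
    """A mapping document is not well-formed in the dialect."""


class PatternSyntaxError(OntoforgeError):
    """A pattern source uses constructs outside the supported grammar."""


class UnknownTermError(OntoforgeError):
    """An axiom references an undeclared ontology term."""


class AmbiguousIdentityError(OntoforgeError):
    """A multi-valued identity property makes the key equivocal."""


class SerializationRefusedError(OntoforgeError):
    """The knowledge base has open violations and no override was given."""


class RefuseToRunError(OntoforgeError):
    """Preconditions for a transformation or integration run failed."""


class ClassificationError(OntoforgeError):
    """A pattern variable cannot be classified as creating or referencing."""
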