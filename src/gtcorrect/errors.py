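"""Exception hierarchy."""


class GtCorrectError(Exception):
    """Base class for all errors raised by this package."""


class NewickFormatError(GtCorrectError):
    """Malformed or unsupported Newick input (non-binary vertex, empty label...)."""


class LabelError(GtCorrectError):
    """A gene-tree leaf label is absent from the species tree."""


class TreeDomainError(GtCorrectError):
    """An operation was applied outside its domain (e.g. removing the last leaf)."""


class ResourceError(GtCorrectError):
    """An exhaustive search exceeded its configured cap."""
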