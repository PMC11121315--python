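"""Exception hierarchy for tmhc."""


class TmhcError(Exception):
    """Base class for all tmhc errors."""


class ChainNotFoundError(TmhcError):
    """Requested chain id is absent from the structure file."""


class PdbFormatError(TmhcError):
    """Structure file could not be parsed, or violates assumptions
    (e.g. insertion codes, which the integer-position model rejects)."""


class AnnotationError(TmhcError):
    """Helix annotation violates its invariants (overlap, start > end, ...)."""


class MissingAtomsError(TmhcError):
    """A residue lacks atoms required for the requested computation."""


class MissingResidueError(TmhcError):
    """A referenced residue position is absent from the chain."""


class AxisUndefinedError(TmhcError):
    """Helix segment too short or lacking O(i)/N(i+4) pairs for an axis."""


class DegeneratePlaneError(TmhcError):
    """Residue plane vectors are collinear; no normal exists."""


class ModelConfigError(TmhcError):
    """Invalid classifier configuration."""


class ModelFormatError(TmhcError):
    """Model archive is corrupt, incomplete or of an incompatible version."""


class GenerationError(TmhcError):
    """Synthetic bundle generation produced an invalid structure."""


class EvaluationError(TmhcError):
    """A metric is undefined for the given inputs."""
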