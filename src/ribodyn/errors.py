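"""Exception hierarchy for ribodyn.

Every error raised by the library derives from :class:`RibodynError`, so
callers (and the CLI) can catch one type at the pipeline boundary.
"""


class RibodynError(Exception):
    """Base class for all ribodyn errors."""


class FormatError(RibodynError):
    """A structure or annotation file could not be parsed."""


class EmptyStructureError(RibodynError):
    """A PDB model contained no atoms."""


class TopologyMismatchError(RibodynError):
    """A trajectory frame does not match its topology's atom list."""


class EmptySelectionError(RibodynError):
    """An atom selection descriptor matched no atoms."""


class AnnotationError(RibodynError):
    """A substructure annotation referenced residues absent from the topology."""


class DegenerateFitError(RibodynError):
    """Too few (or collinear) points for a least-squares superposition."""


class InsufficientFramesError(RibodynError):
    """The operation needs more trajectory frames than were provided."""


class SelectionError(RibodynError):
    """An atom identifier could not be resolved against the topology."""


class HBondDefinitionError(RibodynError):
    """A donor atom has no attached hydrogen."""


class ZeroVarianceError(RibodynError):
    """A node or the whole selection has no positional variance."""


class ParameterError(RibodynError):
    """A numeric parameter is out of its valid range."""


class UndefinedSipError(RibodynError):
    """SIP requested for a zero-length or all-zero profile."""


class NetworkError(RibodynError):
    """A residue network is empty or inconsistent with its inputs."""


class SyntheticSpecError(RibodynError):
    """A synthetic-trajectory specification is infeasible."""


class PipelineError(RibodynError):
    """A pipeline stage failed; the message names the stage."""
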