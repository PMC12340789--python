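"""Exception hierarchy for treevar."""


class TreevarError(Exception):
    """Base class for all treevar errors."""


class GfaParseError(TreevarError):
    """A GFA line could not be parsed; the message names the line number."""


class ReferentialIntegrityError(TreevarError):
    """A record references a segment that does not exist."""


class ConfigurationError(TreevarError):
    """Invalid run configuration (e.g. reference sample absent from walks)."""


class EmptyGraphError(TreevarError):
    """An operation required a non-empty graph."""


class WalkConsistencyError(TreevarError):
    """A walk step pair has no corresponding bidirected edge."""


class ConsistencyError(TreevarError):
    """Tree/graph/catalog objects do not belong together."""


class NotApplicableError(TreevarError):
    """The operation is undefined for this input (e.g. inversion edges)."""


class NoWalkError(TreevarError):
    """No walk realises the requested genotype."""


class AmbiguousWalkError(TreevarError):
    """More than one walk realises the requested genotype."""


class SortOrderError(TreevarError):
    """VCF records were not sorted by (CHROM, POS)."""


class PlacementError(TreevarError):
    """Simulated events could not be placed without breakpoint collisions."""
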