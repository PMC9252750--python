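"""Exception hierarchy.

Every error raised on a violated input contract derives from
:class:`DeseError` so callers can catch the whole family.
"""


class DeseError(Exception):
    """Base class for all package errors."""


class ZeroLibrarySize(DeseError):
    """A counts column has zero total and cannot be CPM-normalized."""


class NotEnoughSamples(DeseError):
    """An operation needs at least two columns (e.g. TMM factors)."""


class NotEnoughColumns(DeseError):
    """Selective-expression scoring needs at least three panel columns."""


class MissingTissueLabel(DeseError):
    """A bulk sample has no tissue assignment in the sample map."""


class MissingAnnotation(DeseError):
    """A cell in the counts matrix has no annotation row."""


class FormatError(DeseError):
    """A file is structurally unreadable (header, delimiter, VCF)."""


class RowError(DeseError):
    """A single data row is invalid; message carries the line number."""


class MissingVariant(DeseError):
    """A requested variant id is absent from the reference panel."""


class EmptyGene(DeseError):
    """A gene-based test was requested on an empty variant set."""


class DegenerateGroups(DeseError):
    """Enrichment groups are empty or exhaust all genes."""


class EmptyAnalysis(DeseError):
    """No genes are shared between association results and the panel."""


class EmptySubset(DeseError):
    """Organ filtering left no cell-type columns."""


class InvalidCounts(DeseError):
    """Hypergeometric counts violate 0 <= k <= min(M, n), n <= N, M <= N."""
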