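"""Exception hierarchy.

All package errors derive from :class:`MultiLocusError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""


class MultiLocusError(Exception):
    """Base class for all errors raised by this package."""


class AlphabetMismatchError(MultiLocusError):
    """Loci with different alphabets were combined."""


class AlphabetError(MultiLocusError):
    """A residue is illegal under the declared alphabet, or an operation
    requires a different alphabet."""


class DuplicateLabelError(MultiLocusError):
    """Two rows of one locus share an individual label."""


class IncompleteDataError(MultiLocusError):
    """Harmonization without gap-padding requires identical label sets."""


class AlignmentError(MultiLocusError):
    """Sequences of unequal length where an alignment is required."""


class SelectorError(MultiLocusError):
    """Unknown label, out-of-range index, or malformed selector."""


class EmptySelectionError(SelectorError):
    """A selector resolved to nothing."""


class RenameError(MultiLocusError):
    """Locus renaming with wrong length or duplicate names."""


class ParseError(MultiLocusError):
    """A sequence or tree file could not be parsed."""


class ConversionError(MultiLocusError):
    """A nucleotide-only operation was applied to amino-acid data."""


class IncompleteDistanceError(MultiLocusError):
    """A distance matrix contains undefined (or saturated) pairs where a
    complete matrix is required."""


class ComparisonError(MultiLocusError):
    """Tree comparison is impossible (too few shared leaves)."""


class NewickParseError(ParseError):
    """Malformed Newick text."""


class FixtureSpecError(MultiLocusError):
    """A simulation specification is contradictory."""
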