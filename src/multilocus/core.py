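"""Core data model: per-locus alignments and the harmonized multi-locus container.

The central idea is *harmonization*: given one alignment per locus, every
individual seen in at least one locus is enumerated, the union of labels is
sorted alphanumerically (plain code-point order), and each locus is padded
with gap-only rows (``'-' * n_cols``) for the individuals it lacks.  After
harmonization every locus carries exactly the same individuals in exactly the
same order, so per-locus analyses (distances, trees) can be compared directly
and loci can be concatenated into a supermatrix row by row.

Bookkeeping mirrors the slot semantics of multi-gene containers in the
phylogenetics literature: ``n_ind`` individuals, ``n_seq = n_ind * n_loci``
total sequences including padding, and ``n_seq_miss`` gap-only sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlphabetError,
    AlphabetMismatchError,
    DuplicateLabelError,
    EmptySelectionError,
    IncompleteDataError,
    AlignmentError,
    RenameError,
    SelectorError,
)

NUCLEOTIDE = "nucleotide"
AMINO_ACID = "amino-acid"

GAP = "-"
#: determinate nucleotide states (everything else is ambiguous/missing)
NUC_STATES = "ACGT"
#: IUPAC nucleotide ambiguity codes, including N
NUC_AMBIGUOUS = "RYSWKMBDHVN"
AA_STATES = "ACDEFGHIKLMNPQRSTVWY"
AA_EXTRA = "BZJUOX*"

_NUC_ALLOWED = frozenset(NUC_STATES + NUC_AMBIGUOUS + GAP + "?")
_AA_ALLOWED = frozenset(AA_STATES + AA_EXTRA + GAP + "?")


def _allowed(alphabet: str) -> frozenset:
    if alphabet == NUCLEOTIDE:
        return _NUC_ALLOWED
    if alphabet == AMINO_ACID:
        return _AA_ALLOWED
    raise AlphabetError(f"unknown alphabet tag: {alphabet!r}")


def is_gap_only(seq: str) -> bool:
    """A row is gap-only iff every character is '-'.

    Rows of all-'N' or all-'?' are *not* gap-only: ambiguity codes record an
    observed but unresolved site, whereas '-' records absence.
    """
    return len(seq) > 0 and set(seq) == {GAP}


class LocusAlignment:
    """One gene's aligned sequences: an ordered map label -> residue string.

    Residues are uppercased on construction and validated against the declared
    alphabet (determinate states, IUPAC ambiguity codes, '-' and '?').  'U' is
    normalized to 'T' for nucleotide data.  All rows must share one length,
    ``n_cols``.
    """

    def __init__(
        self,
        name: str,
        sequences: Mapping[str, str],
        alphabet: str = NUCLEOTIDE,
    ):
        if not sequences:
            raise AlignmentError(f"locus {name!r}: empty alignment")
        allowed = _allowed(alphabet)
        seqs: dict[str, str] = {}
        n_cols = None
        for label, seq in sequences.items():
            if label in seqs:
                raise DuplicateLabelError(
                    f"locus {name!r}: duplicate label {label!r}"
                )
            s = str(seq).upper()
            if alphabet == NUCLEOTIDE:
                s = s.replace("U", "T")
            if n_cols is None:
                n_cols = len(s)
            elif len(s) != n_cols:
                raise AlignmentError(
                    f"locus {name!r}: sequence {label!r} has length "
                    f"{len(s)}, expected {n_cols}"
                )
            bad = set(s) - allowed
            if bad:
                raise AlphabetError(
                    f"locus {name!r}, sequence {label!r}: illegal "
                    f"{alphabet} residue(s) {sorted(bad)}"
                )
            seqs[label] = s
        self.name = str(name)
        self._seqs = seqs
        self.n_cols = int(n_cols)
        self.alphabet = alphabet
        #: for concatenated alignments: list of (locus_name, start, end),
        #: 1-based closed column intervals
        self.partitions: list[tuple[str, int, int]] | None = None

    # -- mapping-style access ------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return list(self._seqs)

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __contains__(self, label: str) -> bool:
        return label in self._seqs

    def __getitem__(self, label: str) -> str:
        return self._seqs[label]

    def __iter__(self):
        return iter(self._seqs.items())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LocusAlignment)
            and self.name == other.name
            and self.alphabet == other.alphabet
            and self._seqs == other._seqs
        )

    def __repr__(self) -> str:
        return (
            f"<LocusAlignment {self.name!r}: {len(self)} x {self.n_cols} "
            f"({self.alphabet})>"
        )

    def gap_only_labels(self) -> list[str]:
        return [l for l, s in self._seqs.items() if is_gap_only(s)]

    def column(self, j: int) -> tuple:
        """Site pattern at 1-based column ``j`` (tuple over row order)."""
        if not 1 <= j <= self.n_cols:
            raise SelectorError(f"column {j} out of range 1..{self.n_cols}")
        return tuple(s[j - 1] for s in self._seqs.values())

    def slice_columns(self, start: int, end: int) -> "LocusAlignment":
        """Sub-alignment of the 1-based closed column interval [start, end]."""
        if not (1 <= start <= end <= self.n_cols):
            raise SelectorError(
                f"column range {start}..{end} out of 1..{self.n_cols}"
            )
        return LocusAlignment(
            self.name,
            {l: s[start - 1 : end] for l, s in self._seqs.items()},
            self.alphabet,
        )

    def reordered(self, labels: Sequence[str]) -> "LocusAlignment":
        missing = [l for l in labels if l not in self._seqs]
        if missing:
            raise SelectorError(f"locus {self.name!r}: unknown labels {missing}")
        return LocusAlignment(
            self.name, {l: self._seqs[l] for l in labels}, self.alphabet
        )

    def to_array(self) -> np.ndarray:
        """Rows x columns character array (dtype '<U1')."""
        return np.array([list(s) for s in self._seqs.values()], dtype="<U1")


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def resolve_selector(selector, universe: Sequence[str], *, what: str) -> list[str]:
    """Resolve an index / label / boolean selector against ``universe``.

    ``None`` (or the string ``"all"``) selects everything.  Integer indices
    are 0-based; labels must exist; a boolean mask must match the universe
    length.  The result preserves *universe* order and drops duplicates, so
    composed selections obey an intersection law.
    """
    if selector is None or (isinstance(selector, str) and selector == "all"):
        return list(universe)
    if isinstance(selector, (str, int, np.integer)):
        selector = [selector]
    selector = list(selector)
    if len(selector) == 0:
        raise EmptySelectionError(f"empty {what} selection")
    if all(isinstance(s, (bool, np.bool_)) for s in selector):
        if len(selector) != len(universe):
            raise SelectorError(
                f"{what} boolean mask has length {len(selector)}, "
                f"expected {len(universe)}"
            )
        picked = [u for u, keep in zip(universe, selector) if keep]
    elif all(isinstance(s, (int, np.integer)) for s in selector):
        picked = []
        for i in selector:
            if not 0 <= int(i) < len(universe):
                raise SelectorError(
                    f"{what} index {i} out of range 0..{len(universe) - 1}"
                )
            picked.append(universe[int(i)])
    elif all(isinstance(s, str) for s in selector):
        unknown = [s for s in selector if s not in universe]
        if unknown:
            raise SelectorError(f"unknown {what} label(s): {unknown}")
        picked = list(selector)
    else:
        raise SelectorError(f"mixed-type {what} selector: {selector!r}")
    # preserve universe (canonical) order, drop duplicates
    picked_set = set(picked)
    result = [u for u in universe if u in picked_set]
    if not result:
        raise EmptySelectionError(f"empty {what} selection")
    return result


# ---------------------------------------------------------------------------
# the container
# ---------------------------------------------------------------------------

class MultiLocusContainer:
    """Ordered loci harmonized to one canonical, sorted individual list.

    Do not call the constructor with un-harmonized loci; use
    :func:`build_container` (or :func:`multilocus.io.read_multi`), which pads
    and re-orders.  Attributes:

    loci
        ordered list of :class:`LocusAlignment`, all over the same labels.
    labels
        the canonical individual list (sorted, unique).
    ind_info, gene_info
        optional :class:`pandas.DataFrame` metadata keyed by individual /
        locus name; may cover a subset of rows.
    """

    def __init__(
        self,
        loci: Sequence[LocusAlignment],
        ind_info: pd.DataFrame | None = None,
        gene_info: pd.DataFrame | None = None,
    ):
        loci = list(loci)
        if not loci:
            raise EmptySelectionError("container needs at least one locus")
        alphabet = loci[0].alphabet
        for loc in loci:
            if loc.alphabet != alphabet:
                raise AlphabetMismatchError(
                    f"locus {loc.name!r} is {loc.alphabet}, "
                    f"expected {alphabet}"
                )
        names = [loc.name for loc in loci]
        if len(set(names)) != len(names):
            raise DuplicateLabelError(f"duplicate locus names in {names}")
        labels = loci[0].labels
        for loc in loci[1:]:
            if loc.labels != labels:
                raise IncompleteDataError(
                    f"locus {loc.name!r} labels differ from "
                    f"locus {loci[0].name!r}; harmonize via build_container"
                )
        self.loci = loci
        self.labels = list(labels)
        self.alphabet = alphabet
        self.ind_info = ind_info
        self.gene_info = gene_info

    # -- derived counts ------------------------------------------------------
    @property
    def n_ind(self) -> int:
        return len(self.labels)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_seq(self) -> int:
        return self.n_ind * self.n_loci

    @property
    def n_seq_miss(self) -> int:
        return sum(len(loc.gap_only_labels()) for loc in self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def locus(self, name: str) -> LocusAlignment:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise SelectorError(f"unknown locus {name!r}")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MultiLocusContainer)
            and self.labels == other.labels
            and self.loci == other.loci
        )

    def __getitem__(self, key) -> "MultiLocusContainer":
        """Matrix-style subsetting ``c[ids, loci]``."""
        if not isinstance(key, tuple):
            key = (key, None)
        ids, loci = key
        if isinstance(ids, slice) and ids == slice(None):
            ids = None
        if isinstance(loci, slice) and loci == slice(None):
            loci = None
        return subset(self, individuals=ids, loci=loci)

    def __repr__(self) -> str:
        return (
            f"<MultiLocusContainer: {self.n_ind} individuals, "
            f"{self.n_loci} loci, {self.n_seq_miss} gap-only>"
        )

    def __str__(self) -> str:
        kind = "DNA" if self.alphabet == NUCLEOTIDE else "amino-acid"
        shown = " ".join(self.labels[:4])
        if self.n_ind > 4:
            shown += " ..."
        lines = [
            "=== MultiLocusContainer ===",
            f"[{self.n_seq} {kind} sequences in {self.n_loci} genes]",
            f"@n.ind: {self.n_ind} individuals",
            f"@n.seq: {self.n_seq} sequences in total",
            f"@n.seq.miss: {self.n_seq_miss} gap-only (missing) sequences",
            f"@labels: {shown}",
            "@loci: " + " ".join(self.locus_names),
        ]
        return "\n".join(lines)


def build_container(
    loci: Sequence[LocusAlignment],
    add_gaps: bool = True,
    ind_info: pd.DataFrame | None = None,
    gene_info: pd.DataFrame | None = None,
) -> MultiLocusContainer:
    """Harmonize per-locus alignments into a :class:`MultiLocusContainer`.

    All individuals with at least one sequence are enumerated, sorted
    alphanumerically (plain code-point order), and each locus receives
    gap-only rows for every individual it lacks; rows are re-ordered to the
    canonical order.  With ``add_gaps=False`` no padding is performed and all
    loci must already carry identical label sets.
    """
    loci = list(loci)
    if not loci:
        raise EmptySelectionError("build_container needs at least one locus")
    alphabet = loci[0].alphabet
    for loc in loci:
        if loc.alphabet != alphabet:
            raise AlphabetMismatchError(
                f"locus {loc.name!r} is {loc.alphabet}, expected {alphabet}"
            )
    union: set[str] = set()
    for loc in loci:
        union.update(loc.labels)
    canonical = sorted(union)
    if not add_gaps:
        for loc in loci:
            if set(loc.labels) != union:
                missing = sorted(union - set(loc.labels))
                raise IncompleteDataError(
                    f"add_gaps is off but locus {loc.name!r} lacks "
                    f"individuals {missing}"
                )
        harmonized = [loc.reordered(canonical) for loc in loci]
    else:
        harmonized = []
        for loc in loci:
            rows = dict(loc.sequences)
            pad = GAP * loc.n_cols
            for label in canonical:
                rows.setdefault(label, pad)
            harmonized.append(
                LocusAlignment(
                    loc.name, {l: rows[l] for l in canonical}, alphabet
                )
            )
    return MultiLocusContainer(harmonized, ind_info=ind_info, gene_info=gene_info)


def _slice_info(info: pd.DataFrame | None, keys: list[str]) -> pd.DataFrame | None:
    if info is None:
        return None
    keep = [k for k in keys if k in info.index]
    return info.loc[keep]


def subset(
    c: MultiLocusContainer,
    individuals=None,
    loci=None,
) -> MultiLocusContainer:
    """Restrict a container to selected individuals and loci.

    Selectors may be index vectors (0-based), label vectors or boolean masks;
    ``None`` keeps everything.  The canonical order is preserved (selection
    never re-sorts), no re-harmonization happens, and loci that become
    entirely gap-only are retained.  Metadata tables are sliced to match.
    """
    keep_ids = resolve_selector(individuals, c.labels, what="individual")
    keep_loci = resolve_selector(loci, c.locus_names, what="locus")
    new_loci = [c.locus(name).reordered(keep_ids) for name in keep_loci]
    return MultiLocusContainer(
        new_loci,
        ind_info=_slice_info(c.ind_info, keep_ids),
        gene_info=_slice_info(c.gene_info, keep_loci),
    )


def concatenate_loci(c: MultiLocusContainer, loci=None) -> LocusAlignment:
    """Juxtapose selected loci into one supermatrix alignment.

    Per individual, the row is the concatenation of that individual's rows
    across the selected loci (container order by default, selector order when
    an explicit label list is given).  Gap-padded rows are concatenated
    as-is.  The result records 1-based closed partition boundaries in its
    ``partitions`` attribute.
    """
    if isinstance(loci, (list, tuple)) and loci and all(
        isinstance(s, str) for s in loci
    ):
        unknown = [s for s in loci if s not in c.locus_names]
        if unknown:
            raise SelectorError(f"unknown locus label(s): {unknown}")
        names = list(dict.fromkeys(loci))  # keep selector order
    else:
        names = resolve_selector(loci, c.locus_names, what="locus")
    picked = [c.locus(n) for n in names]
    rows = {
        label: "".join(loc[label] for loc in picked) for label in c.labels
    }
    out = LocusAlignment("concatenated", rows, c.alphabet)
    partitions = []
    start = 1
    for loc in picked:
        partitions.append((loc.name, start, start + loc.n_cols - 1))
        start += loc.n_cols
    out.partitions = partitions
    return out


def partition_block(a: LocusAlignment) -> str:
    """RAxML-style partition text for a concatenated alignment."""
    if not a.partitions:
        raise SelectorError("alignment carries no partition metadata")
    kind = "DNA" if a.alphabet == NUCLEOTIDE else "WAG"
    return "\n".join(
        f"{kind}, {name} = {start}-{end}" for name, start, end in a.partitions
    )


def count_sequences(
    c: MultiLocusContainer, loci=None, exclude_gap_only: bool = True
) -> dict[str, int]:
    """Per-locus sequence counts.

    By default only rows not composed entirely of gaps are counted; with
    ``exclude_gap_only=False`` every locus reports ``n_ind``.
    """
    names = resolve_selector(loci, c.locus_names, what="locus")
    out = {}
    for name in names:
        loc = c.locus(name)
        if exclude_gap_only:
            out[name] = len(loc) - len(loc.gap_only_labels())
        else:
            out[name] = len(loc)
    return out


def sequence_names(
    c: MultiLocusContainer, loci=None, exclude_gap_only: bool = True
) -> dict[str, list[str]]:
    """Per-locus row labels, optionally dropping gap-only padding rows."""
    names = resolve_selector(loci, c.locus_names, what="locus")
    out = {}
    for name in names:
        loc = c.locus(name)
        if exclude_gap_only:
            gap = set(loc.gap_only_labels())
            out[name] = [l for l in loc.labels if l not in gap]
        else:
            out[name] = loc.labels
    return out


def get_sequences(
    c: MultiLocusContainer, ids=None, loci=None, simplify: bool = True
):
    """Filtered alignments by individual and locus.

    Returns a map locus -> :class:`LocusAlignment`; if exactly one locus is
    selected and ``simplify`` is true, the bare alignment is returned.
    """
    keep_ids = resolve_selector(ids, c.labels, what="individual")
    keep_loci = resolve_selector(loci, c.locus_names, what="locus")
    result = {name: c.locus(name).reordered(keep_ids) for name in keep_loci}
    if simplify and len(result) == 1:
        return next(iter(result.values()))
    return result


def num_loci(c: MultiLocusContainer) -> int:
    return c.n_loci


def locus_names(c: MultiLocusContainer) -> list[str]:
    return c.locus_names


def set_locus_names(
    c: MultiLocusContainer, new_names: Sequence[str]
) -> MultiLocusContainer:
    """Rename loci (and gene_info keys) consistently; content untouched."""
    new_names = list(new_names)
    if len(new_names) != c.n_loci:
        raise RenameError(
            f"{len(new_names)} names for {c.n_loci} loci"
        )
    if len(set(new_names)) != len(new_names):
        raise RenameError(f"duplicate locus names: {new_names}")
    renamed = [
        LocusAlignment(new, loc.sequences, loc.alphabet)
        for new, loc in zip(new_names, c.loci)
    ]
    gene_info = c.gene_info
    if gene_info is not None:
        mapping = dict(zip(c.locus_names, new_names))
        gene_info = gene_info.rename(index=mapping)
    return MultiLocusContainer(renamed, ind_info=c.ind_info, gene_info=gene_info)


# ---------------------------------------------------------------------------
# site-pattern compression
# ---------------------------------------------------------------------------

@dataclass
class SitePatternTable:
    """Unique site patterns of one locus with integer multiplicities.

    ``patterns[k]`` is the residue tuple across individuals (in row order) of
    the k-th distinct column, first-appearance ordered; ``weights[k]`` is how
    many columns show that pattern.  Weights sum to the source ``n_cols``.
    """

    locus_name: str
    labels: list[str]
    patterns: list[tuple]
    weights: list[int]
    alphabet: str = NUCLEOTIDE

    def __post_init__(self):
        if len(self.patterns) != len(self.weights):
            raise AlignmentError("patterns and weights differ in length")
        if len(set(self.patterns)) != len(self.patterns):
            raise AlignmentError("site patterns must be pairwise distinct")
        if any(w <= 0 for w in self.weights):
            raise AlignmentError("pattern weights must be positive")

    @property
    def n_cols(self) -> int:
        return sum(self.weights)

    def expand(self, order: Sequence[int] | None = None) -> LocusAlignment:
        """Rebuild an alignment whose column multiset matches the source.

        ``order`` optionally permutes the emitted columns (indices into the
        expanded column list); by default patterns are emitted grouped in
        first-appearance order.
        """
        cols = []
        for pat, w in zip(self.patterns, self.weights):
            cols.extend([pat] * w)
        if order is not None:
            if sorted(order) != list(range(len(cols))):
                raise SelectorError("order must be a permutation of columns")
            cols = [cols[i] for i in order]
        rows = {
            label: "".join(col[i] for col in cols)
            for i, label in enumerate(self.labels)
        }
        return LocusAlignment(self.locus_name, rows, self.alphabet)


def compress_site_patterns(a: LocusAlignment) -> SitePatternTable:
    """Collapse an alignment to its distinct site patterns with weights."""
    counts: dict[tuple, int] = {}
    for j in range(1, a.n_cols + 1):
        col = a.column(j)
        counts[col] = counts.get(col, 0) + 1
    return SitePatternTable(
        locus_name=a.name,
        labels=a.labels,
        patterns=list(counts),
        weights=list(counts.values()),
        alphabet=a.alphabet,
    )
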