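"""Reading and writing per-locus alignment files.

Supported dialects: FASTA (via Biopython), and relaxed Phylip in both
sequential and interleaved layout (whitespace-delimited names; the strict
10-column name field is not assumed, since real-world files rarely honour
it).  One file per locus; the locus name defaults to the file's base name
without extension.

The alphabet may be forced or auto-detected: a file is taken as nucleotide
iff at least 90% of its non-gap, non-'?' residues are A/C/G/T/U/N or IUPAC
nucleotide ambiguity codes, falling back to amino acid otherwise (the
superset alphabet, hence the safe default).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter

from .core import (
    AMINO_ACID,
    GAP,
    NUCLEOTIDE,
    NUC_AMBIGUOUS,
    NUC_STATES,
    LocusAlignment,
    MultiLocusContainer,
    build_container,
)
from .errors import (
    AlphabetError,
    ConversionError,
    DuplicateLabelError,
    EmptySelectionError,
    ParseError,
)

_NUC_LIKE = frozenset(NUC_STATES + "UN" + NUC_AMBIGUOUS)

FASTA = "fasta"
PHYLIP_SEQUENTIAL = "phylip-sequential"
PHYLIP_INTERLEAVED = "phylip-interleaved"

_EXTENSIONS = {
    FASTA: ".fasta",
    PHYLIP_SEQUENTIAL: ".phy",
}


def infer_alphabet(records: Sequence[tuple[str, str]]) -> str:
    """Nucleotide iff >=90% of informative residues look like nucleotides."""
    total = 0
    nuc = 0
    for _, seq in records:
        for ch in seq.upper():
            if ch in (GAP, "?"):
                continue
            total += 1
            if ch in _NUC_LIKE:
                nuc += 1
    if total == 0:
        return NUCLEOTIDE
    return NUCLEOTIDE if nuc / total >= 0.9 else AMINO_ACID


def _records_to_locus(
    records: list[tuple[str, str]], name: str, alphabet: str
) -> LocusAlignment:
    seen = set()
    for label, _ in records:
        if label in seen:
            raise DuplicateLabelError(
                f"locus {name!r}: duplicate sequence label {label!r}"
            )
        seen.add(label)
    if alphabet == "auto":
        alphabet = infer_alphabet(records)
        try:
            return LocusAlignment(name, dict(records), alphabet)
        except AlphabetError:
            if alphabet == NUCLEOTIDE:
                # a minority of residues was protein-only: use the superset
                return LocusAlignment(name, dict(records), AMINO_ACID)
            raise
    return LocusAlignment(name, dict(records), alphabet)


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def _parse_fasta(text: str) -> list[tuple[str, str]]:
    from io import StringIO

    records = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(StringIO(text), "fasta")
    ]
    if not records:
        raise ParseError("no FASTA records found")
    return records


def _phylip_header(lines: list[str]) -> tuple[int, int, list[str]]:
    body = [ln for ln in lines if ln.strip()]
    if not body:
        raise ParseError("empty file")
    head = body[0].split()
    if len(head) < 2:
        raise ParseError(f"malformed Phylip header line: {body[0]!r}")
    try:
        n, m = int(head[0]), int(head[1])
    except ValueError as exc:
        raise ParseError(f"malformed Phylip header line: {body[0]!r}") from exc
    if n <= 0 or m <= 0:
        raise ParseError(f"non-positive Phylip dimensions: {n} x {m}")
    return n, m, body[1:]


def _parse_phylip_sequential(text: str) -> list[tuple[str, str]]:
    n, m, body = _phylip_header(text.splitlines())
    tokens = [tok for ln in body for tok in ln.split()]
    records: list[tuple[str, str]] = []
    i = 0
    for _ in range(n):
        if i >= len(tokens):
            raise ParseError(f"expected {n} sequences, found {len(records)}")
        name = tokens[i]
        i += 1
        seq = ""
        while len(seq) < m:
            if i >= len(tokens):
                raise ParseError(
                    f"sequence {name!r} truncated at {len(seq)}/{m} residues"
                )
            seq += tokens[i]
            i += 1
        if len(seq) != m:
            raise ParseError(
                f"sequence {name!r} has {len(seq)} residues, expected {m}"
            )
        records.append((name, seq))
    if i != len(tokens):
        raise ParseError("trailing data after last Phylip sequence")
    return records


def _parse_phylip_interleaved(text: str) -> list[tuple[str, str]]:
    n, m, body = _phylip_header(text.splitlines())
    if len(body) < n:
        raise ParseError(f"expected {n} taxa, found {len(body)} data lines")
    names: list[str] = []
    seqs: list[str] = []
    for ln in body[:n]:
        parts = ln.split()
        names.append(parts[0])
        seqs.append("".join(parts[1:]))
    for k, ln in enumerate(body[n:]):
        seqs[k % n] += "".join(ln.split())
    for name, seq in zip(names, seqs):
        if len(seq) != m:
            raise ParseError(
                f"sequence {name!r} has {len(seq)} residues, expected {m}"
            )
    return list(zip(names, seqs))


_PARSERS = {
    FASTA: _parse_fasta,
    PHYLIP_SEQUENTIAL: _parse_phylip_sequential,
    PHYLIP_INTERLEAVED: _parse_phylip_interleaved,
}


def _detect_and_parse(text: str) -> list[tuple[str, str]]:
    if text.lstrip().startswith(">"):
        return _parse_fasta(text)
    try:
        return _parse_phylip_sequential(text)
    except ParseError:
        return _parse_phylip_interleaved(text)


def read_locus_file(
    path: str | os.PathLike,
    format: str = "auto",
    alphabet: str = "auto",
    name: str | None = None,
) -> LocusAlignment:
    """Read one alignment file into a :class:`LocusAlignment`.

    ``format`` is ``fasta``, ``phylip-sequential``, ``phylip-interleaved`` or
    ``auto``; ``alphabet`` is ``nucleotide``, ``amino-acid`` or ``auto``.
    """
    path = Path(path)
    text = path.read_text()
    try:
        if format == "auto":
            records = _detect_and_parse(text)
        elif format in _PARSERS:
            records = _PARSERS[format](text)
        else:
            raise ParseError(f"unknown format {format!r}")
        return _records_to_locus(
            records, name if name is not None else path.stem, alphabet
        )
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_multi(
    paths: Sequence[str | os.PathLike],
    format: str = "auto",
    alphabet: str = "auto",
    add_gaps: bool = True,
) -> MultiLocusContainer:
    """Read one file per locus and harmonize into a container.

    Loci keep the given path order.  With ``add_gaps=False`` no gap-padding
    is performed, so all files must document identical individuals.
    """
    if not paths:
        raise EmptySelectionError("read_multi needs at least one path")
    loci = [read_locus_file(p, format=format, alphabet=alphabet) for p in paths]
    names = [loc.name for loc in loci]
    if len(set(names)) != len(names):
        raise DuplicateLabelError(f"duplicate locus names across files: {names}")
    # harmonizing mixed inferred alphabets: if any locus is amino-acid, all are
    if alphabet == "auto" and len({loc.alphabet for loc in loci}) > 1:
        loci = [
            LocusAlignment(loc.name, loc.sequences, AMINO_ACID) for loc in loci
        ]
    return build_container(loci, add_gaps=add_gaps)


def write_container(
    c: MultiLocusContainer,
    directory: str | os.PathLike,
    format: str = FASTA,
    include_gap_only: bool = True,
) -> list[Path]:
    """Write one file per locus (``<locus>.fasta`` / ``<locus>.phy``).

    With ``include_gap_only=False`` the gap-padding rows are omitted, which
    inverts harmonization; a locus left with no record at all is rejected.
    """
    if format not in _EXTENSIONS:
        raise ParseError(f"unsupported output format {format!r}")
    directory = Path(directory)
    per_locus: list[tuple[LocusAlignment, list[tuple[str, str]]]] = []
    for loc in c.loci:
        rows = list(loc.sequences.items())
        if not include_gap_only:
            gap = set(loc.gap_only_labels())
            rows = [(l, s) for l, s in rows if l not in gap]
        if not rows:
            raise EmptySelectionError(
                f"locus {loc.name!r} has no sequence to write "
                "(all rows are gap-only)"
            )
        per_locus.append((loc, rows))
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for loc, rows in per_locus:
        out = directory / f"{loc.name}{_EXTENSIONS[format]}"
        try:
            with open(out, "w") as fh:
                if format == FASTA:
                    from Bio.Seq import Seq
                    from Bio.SeqRecord import SeqRecord

                    writer = FastaWriter(fh, wrap=80)
                    writer.write_file(
                        SeqRecord(Seq(s), id=l, description="") for l, s in rows
                    )
                else:
                    fh.write(f" {len(rows)} {loc.n_cols}\n")
                    for l, s in rows:
                        fh.write(f"{l}  {s}\n")
        except OSError as exc:
            raise ParseError(f"cannot write {out}: {exc}") from exc
        written.append(out)
    return written


def ensure_nucleotide(c: MultiLocusContainer) -> MultiLocusContainer:
    """Gate to the nucleotide-only representation.

    Identity on nucleotide containers; raises :class:`ConversionError` naming
    the first offending locus otherwise.
    """
    if c.alphabet == NUCLEOTIDE:
        return c
    raise ConversionError(
        f"nucleotide-only operation on amino-acid data "
        f"(first locus: {c.locus_names[0]!r})"
    )
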