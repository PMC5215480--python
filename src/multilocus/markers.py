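"""Marker coding: SNP extraction and MLST-style haplotype alleles.

Two routes turn a harmonized container into an individuals x markers
genotype table of integer allele codes:

* :func:`extract_snps` — one marker per polymorphic nucleotide column.  A
  column is a SNP iff at least two distinct determinate states (A/C/G/T)
  occur; gaps, '?', 'N' and the other IUPAC ambiguity codes are treated as
  missing at that site rather than expanded.
* :func:`code_haplotypes` — one marker per locus; each distinct full-length
  sequence string is a separate allele (the multilocus-sequence-typing idea
  generalized to arbitrary loci).  Two sequences differing only by 'N' vs a
  base are distinct alleles: no similarity collapsing.

Sequences are haploid: one allele per individual per marker.  Allele codes
are consecutive integers from 1 in order of first appearance scanning
individuals in canonical order; code 0 is the reserved missing sentinel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GAP, NUC_STATES, NUCLEOTIDE, MultiLocusContainer, is_gap_only
from .errors import AlphabetError, EmptySelectionError, ParseError

#: reserved code for a missing observation; never a legend key
MISSING_CODE = 0

_DETERMINATE = frozenset(NUC_STATES)


@dataclass(frozen=True)
class MarkerDescriptor:
    """A marker is a locus (haplotype coding) or a locus column (SNP)."""

    locus: str
    site: int | None = None  # 1-based column for SNPs, None for haplotypes

    def __str__(self) -> str:
        return self.locus if self.site is None else f"{self.locus}:{self.site}"

    @classmethod
    def parse(cls, text: str) -> "MarkerDescriptor":
        locus, sep, site = text.rpartition(":")
        if sep and site.isdigit():
            return cls(locus, int(site))
        return cls(text, None)


@dataclass
class GenotypeTable:
    """Individuals x markers integer allele codes with a missing sentinel.

    ``codes[i, k]`` is either :data:`MISSING_CODE` or a key of
    ``allele_legend[k]``, the marker's code -> allele-string map.
    """

    individuals: list[str]
    markers: list[MarkerDescriptor]
    codes: np.ndarray
    allele_legend: list[dict[int, str]]

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        for k, legend in enumerate(self.allele_legend):
            keys = sorted(legend)
            if keys != list(range(1, len(keys) + 1)):
                raise ValueError(f"marker {k}: legend codes must be 1..n")
            observed = set(self.codes[:, k]) - {MISSING_CODE}
            if not observed <= set(keys):
                raise ValueError(f"marker {k}: codes outside legend")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def to_frame(self) -> pd.DataFrame:
        """Codes as a DataFrame; missing rendered as pandas NA."""
        df = pd.DataFrame(
            self.codes,
            index=self.individuals,
            columns=[str(m) for m in self.markers],
            dtype="Int64",
        )
        return df.mask(df == MISSING_CODE)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.individuals == other.individuals
            and self.markers == other.markers
            and np.array_equal(self.codes, other.codes)
            and self.allele_legend == other.allele_legend
        )


def _first_appearance_codes(
    observations: Sequence[str | None],
) -> tuple[list[int], dict[int, str]]:
    """Code a column of allele strings by first appearance; None is missing."""
    legend: dict[str, int] = {}
    codes = []
    for obs in observations:
        if obs is None:
            codes.append(MISSING_CODE)
        else:
            if obs not in legend:
                legend[obs] = len(legend) + 1
            codes.append(legend[obs])
    return codes, {v: k for k, v in legend.items()}


def extract_snps(c: MultiLocusContainer) -> GenotypeTable:
    """One marker per polymorphic column across all loci.

    Nucleotide containers only.  Determinate states are A/C/G/T; every other
    symbol is missing at that site.  Marker descriptors record the locus and
    the 1-based column.
    """
    if c.alphabet != NUCLEOTIDE:
        raise AlphabetError("SNP extraction requires nucleotide data")
    markers: list[MarkerDescriptor] = []
    columns: list[list[int]] = []
    legends: list[dict[int, str]] = []
    for loc in c.loci:
        arr = loc.to_array()  # individuals x sites, canonical row order
        for j in range(loc.n_cols):
            col = arr[:, j]
            obs = [ch if ch in _DETERMINATE else None for ch in col]
            states = {ch for ch in obs if ch is not None}
            if len(states) >= 2:
                codes, legend = _first_appearance_codes(obs)
                markers.append(MarkerDescriptor(loc.name, j + 1))
                columns.append(codes)
                legends.append(legend)
    codes = (
        np.array(columns, dtype=int).T
        if columns
        else np.empty((c.n_ind, 0), dtype=int)
    )
    return GenotypeTable(list(c.labels), markers, codes, legends)


def code_haplotypes(
    c: MultiLocusContainer, skip_gap_only: bool = True
) -> GenotypeTable:
    """One marker per locus; exact string equality partitions rows into alleles.

    With ``skip_gap_only`` (default) gap-only padding rows get the missing
    sentinel instead of an allele of their own.
    """
    markers = []
    columns = []
    legends = []
    for loc in c.loci:
        obs: list[str | None] = []
        for label in loc.labels:
            seq = loc[label]
            if skip_gap_only and is_gap_only(seq):
                obs.append(None)
            else:
                obs.append(seq)
        codes, legend = _first_appearance_codes(obs)
        markers.append(MarkerDescriptor(loc.name, None))
        columns.append(codes)
        legends.append(legend)
    return GenotypeTable(
        list(c.labels), markers, np.array(columns, dtype=int).T, legends
    )


# ---------------------------------------------------------------------------
# text round-trip
# ---------------------------------------------------------------------------

def _legend_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".legend")


def export_genotypes(g: GenotypeTable, path: str | os.PathLike) -> Path:
    """Write the table as TSV (missing as "NA") plus a legend sidecar.

    The sidecar (``<path>.legend``) has one line per (marker, code, allele)
    triple, so the export is fully invertible by :func:`read_genotypes`.
    """
    if not g.individuals or not g.markers:
        raise EmptySelectionError("cannot export an empty genotype table")
    path = Path(path)
    df = pd.DataFrame(
        g.codes, index=g.individuals, columns=[str(m) for m in g.markers]
    )
    df = df.astype(object).mask(df == MISSING_CODE, "NA")
    df.to_csv(path, sep="\t", index_label="individual")
    with open(_legend_path(path), "w") as fh:
        fh.write("marker\tcode\tallele\n")
        for m, legend in zip(g.markers, g.allele_legend):
            for code in sorted(legend):
                fh.write(f"{m}\t{code}\t{legend[code]}\n")
    return path


def read_genotypes(path: str | os.PathLike) -> GenotypeTable:
    """Inverse of :func:`export_genotypes` (expects the legend sidecar)."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    markers = [MarkerDescriptor.parse(col) for col in df.columns]
    codes = np.where(df.values == "NA", MISSING_CODE, df.values).astype(int)
    legends: list[dict[int, str]] = [dict() for _ in markers]
    by_name = {str(m): k for k, m in enumerate(markers)}
    legend_file = _legend_path(path)
    if not legend_file.exists():
        raise ParseError(f"missing legend sidecar {legend_file}")
    with open(legend_file) as fh:
        header = fh.readline()
        if not header.startswith("marker"):
            raise ParseError(f"{legend_file}: malformed legend header")
        for line in fh:
            if not line.strip():
                continue
            name, code, allele = line.rstrip("\n").split("\t")
            legends[by_name[name]][int(code)] = allele
    return GenotypeTable(list(df.index), markers, codes, legends)
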