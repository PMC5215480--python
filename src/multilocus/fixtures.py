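"""Synthetic multi-locus data with controlled tree, divergence and missingness.

Sequences evolve down a generating tree under an equal-rate (Jukes–Cantor
style) substitution process over {A, C, G, T}: along a branch of length t
(expected substitutions per site) each site changes with probability
(3/4)(1 - exp(-4t/3)), to one of the three other bases uniformly.  This is
deliberately the simplest model that exercises distances and tree building;
it makes no claim of realism beyond that (no rate heterogeneity, no indels —
gaps only arise from harmonization padding).

Missingness is controlled by per-locus presence sets: an individual absent
from a locus's presence set is simply not written to that locus's file, and
harmonization later pads it with a gap-only row.  Everything is reproducible
from the integer seed.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio.tree import TreeNode

from .core import LocusAlignment, MultiLocusContainer, build_container
from .errors import FixtureSpecError
from .io import read_multi, write_container
from .phylo import PhyloTree

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Recipe for one synthetic multi-locus data set.

    presence[k] lists the individuals sequenced at locus k; everyone else is
    missing there.  ``substitution_rate`` scales the generating tree's branch
    lengths (or, without a tree, is the root-to-tip divergence of an implied
    star tree), in expected substitutions per site.
    """

    labels: list[str]
    locus_lengths: list[int]
    presence: list[list[str]]
    locus_names: list[str] | None = None
    generating_tree: PhyloTree | None = None
    substitution_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.locus_names is None:
            self.locus_names = [
                f"locus{k + 1}" for k in range(len(self.locus_lengths))
            ]
        if len(self.presence) != len(self.locus_lengths):
            raise FixtureSpecError("one presence set per locus required")
        if len(self.locus_names) != len(self.locus_lengths):
            raise FixtureSpecError("one name per locus required")
        if any(l <= 0 for l in self.locus_lengths):
            raise FixtureSpecError("locus lengths must be positive")
        if self.substitution_rate < 0:
            raise FixtureSpecError("substitution rate must be >= 0")
        label_set = set(self.labels)
        for name, pres in zip(self.locus_names, self.presence):
            extra = set(pres) - label_set
            if extra:
                raise FixtureSpecError(
                    f"locus {name!r}: presence labels {sorted(extra)} "
                    "not in the label set"
                )
        if not any(self.presence):
            raise FixtureSpecError("every presence set is empty")
        if self.generating_tree is not None:
            tree_leaves = set(self.generating_tree.leaf_names)
            if not label_set <= tree_leaves:
                raise FixtureSpecError(
                    "generating tree must carry every individual as a leaf"
                )


def random_binary_tree(
    labels: Sequence[str],
    rng: np.random.Generator,
    min_branch: float = 0.05,
    max_branch: float = 1.0,
) -> PhyloTree:
    """Random binary topology over ``labels`` with positive branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees; branch
    lengths are i.i.d. uniform on [min_branch, max_branch].
    """
    if len(labels) < 2:
        raise FixtureSpecError("need at least 2 leaves")
    nodes = [TreeNode(name=l) for l in labels]
    for nd in nodes:
        nd.length = float(rng.uniform(min_branch, max_branch))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(min_branch, max_branch))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = TreeNode(children=nodes)
    return PhyloTree(root, rooted=True)


def _mutate(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes–Cantor transition sampling along a branch of length t."""
    if t <= 0:
        return seq.copy()
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    hit = rng.random(seq.size) < p_diff
    out = seq.copy()
    # a changed site takes one of the three other bases uniformly
    out[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _evolve_locus(
    spec: FixtureSpec, length: int, rng: np.random.Generator
) -> dict[str, str]:
    root_seq = rng.integers(0, 4, size=length)
    seqs: dict[str, np.ndarray] = {}
    if spec.generating_tree is None:
        # star tree: every individual at substitution_rate from the root
        for label in spec.labels:
            seqs[label] = _mutate(root_seq, spec.substitution_rate, rng)
    else:
        def walk(node: TreeNode, state: np.ndarray):
            for child in node.children:
                t = (child.length or 0.0) * spec.substitution_rate
                child_state = _mutate(state, t, rng)
                if child.is_tip():
                    seqs[child.name] = child_state
                else:
                    walk(child, child_state)

        walk(spec.generating_tree.skbio_tree, root_seq)
    return {l: "".join(_BASES[s]) for l, s in seqs.items()}


def simulate_container(
    spec: FixtureSpec, directory: str | Path | None = None
) -> MultiLocusContainer:
    """Simulate, optionally write one FASTA per locus, and harmonize.

    With ``directory`` given, per-locus FASTA files (present individuals
    only) are written there and the container is built by reading them back
    through :func:`multilocus.io.read_multi`, exercising the full import
    path; otherwise the container is built in memory.  Byte-identical output
    for equal seeds.
    """
    rng = np.random.default_rng(spec.seed)
    loci = []
    for name, length, pres in zip(
        spec.locus_names, spec.locus_lengths, spec.presence
    ):
        full = _evolve_locus(spec, length, rng)
        rows = {l: full[l] for l in spec.labels if l in set(pres)}
        if rows:
            loci.append(LocusAlignment(name, rows, "nucleotide"))
        else:
            # an everywhere-absent locus still needs a placeholder row set
            raise FixtureSpecError(f"locus {name!r} has an empty presence set")
    if directory is None:
        return build_container(loci, add_gaps=True)
    container = build_container(loci, add_gaps=True)
    paths = write_container(
        container, directory, format="fasta", include_gap_only=False
    )
    return read_multi(paths, format="fasta", alphabet="nucleotide")


def worked_example_fixture(
    seed: int = 0, directory: str | Path | None = None
) -> MultiLocusContainer:
    """A 4-locus, 8-individual data set shaped like a small multi-gene study.

    Eight individuals typed at four nuclear loci (named patr_poat43/47/48/49)
    with per-locus non-missing counts 5, 6, 8 and 5 — one locus covers every
    individual, the others have sequencing gaps.  After harmonization:
    n_seq = 32 and n_seq_miss = 8.  Which individuals are missing where is
    drawn deterministically from the seed.
    """
    rng = np.random.default_rng(seed)
    labels = [f"taxon_{k + 1:02d}" for k in range(8)]
    tree = random_binary_tree(labels, rng, min_branch=0.005, max_branch=0.05)
    counts = [5, 6, 8, 5]
    presence = [
        sorted(rng.choice(labels, size=k, replace=False).tolist())
        for k in counts
    ]
    spec = FixtureSpec(
        labels=labels,
        locus_lengths=[480, 420, 540, 510],
        presence=presence,
        locus_names=["patr_poat43", "patr_poat47", "patr_poat48", "patr_poat49"],
        generating_tree=tree,
        substitution_rate=1.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return simulate_container(spec, directory=directory)


def random_fixture_spec(
    rng: np.random.Generator,
    n_ind: int = 6,
    n_loci: int = 3,
    min_len: int = 20,
    max_len: int = 60,
    presence_prob: float = 0.8,
    rate: float = 0.1,
) -> FixtureSpec:
    """A random spec for property tests: random lengths and presence masks.

    Each locus keeps each individual with probability ``presence_prob``
    (re-drawn until non-empty), so missingness bookkeeping can be checked
    against the mask itself.
    """
    labels = [f"ind{k + 1:02d}" for k in range(n_ind)]
    lengths = [int(rng.integers(min_len, max_len + 1)) for _ in range(n_loci)]
    presence = []
    for _ in range(n_loci):
        while True:
            mask = rng.random(n_ind) < presence_prob
            if mask.any():
                break
        presence.append([l for l, m in zip(labels, mask) if m])
    tree = random_binary_tree(labels, rng, 0.01, 0.2) if n_ind >= 2 else None
    return FixtureSpec(
        labels=labels,
        locus_lengths=lengths,
        presence=presence,
        generating_tree=tree,
        substitution_rate=rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
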