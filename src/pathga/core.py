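"""Domain types and search-space combinatorics for gene-set based network inference.

A signaling network is modeled as the edge-set union of ``m`` directed
source→sink chains ("active paths").  The observable input is a *gene set*
per path: the unordered vertex set of the chain with only its two terminal
genes identified — by biological prior knowledge the source is typically a
transmembrane receptor and the sink a transcription factor, so the first and
last genes of each set are taken as fixed.  A candidate network assigns each
gene set a permutation of its intermediate genes; the *feasible set* of
candidates (all of which share the true network's degree distribution) has
size ``∏ᵢ (Lᵢ − 2)!`` for sets of lengths ``Lᵢ``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneSet",
    "Compendium",
    "Chromosome",
    "DirectedNetwork",
    "GAConfig",
    "InvalidChromosomeError",
    "Path",
    "Orderings",
    "assemble_network",
    "feasible_space_size",
    "total_orderings",
    "random_feasible_orderings",
    "validate_orderings",
]

#: An ordered gene list, source first and sink last.
Path = tuple[str, ...]
#: One full ordering (terminals fixed) per gene set, aligned with the compendium.
Orderings = tuple[Path, ...]


class InvalidChromosomeError(ValueError):
    """Orderings do not match the compendium's gene sets (wrong genes or terminals)."""


@dataclass(frozen=True)
class GeneSet:
    """The unordered vertex set of one active path, with designated terminals.

    ``genes[0]`` is the source terminal, ``genes[-1]`` the sink terminal; the
    listed order of intermediate genes carries no meaning.
    """

    id: str
    genes: Path

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) < 2:
            raise ValueError(f"gene set {self.id!r}: need at least 2 genes, got {len(self.genes)}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.id!r}: duplicate gene identifiers")

    @property
    def length(self) -> int:
        return len(self.genes)

    @property
    def source(self) -> str:
        return self.genes[0]

    @property
    def sink(self) -> str:
        return self.genes[-1]

    @property
    def intermediates(self) -> frozenset[str]:
        return frozenset(self.genes[1:-1])


@dataclass(frozen=True)
class Compendium:
    """A collection of ``m`` gene sets emitted from one underlying network.

    ``gene_index`` is a stable bijection between the ``n`` distinct genes and
    ``0..n−1``, assigned in order of first appearance.
    """

    gene_sets: tuple[GeneSet, ...]
    gene_index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_sets", tuple(self.gene_sets))
        if not self.gene_sets:
            raise ValueError("a compendium needs at least one gene set")
        index: dict[str, int] = {}
        for gs in self.gene_sets:
            for g in gs.genes:
                if g not in index:
                    index[g] = len(index)
        object.__setattr__(self, "gene_index", index)

    @property
    def m(self) -> int:
        return len(self.gene_sets)

    @property
    def n(self) -> int:
        return len(self.gene_index)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.gene_index)

    def duplicate_set_ids(self) -> list[tuple[str, str]]:
        """Pairs of gene-set ids with identical membership and terminals.

        Duplicates are legal (each occupies its own path slot and contributes
        its own transition counts) but worth surfacing in logs.
        """
        seen: dict[tuple, str] = {}
        dups = []
        for gs in self.gene_sets:
            key = (gs.source, gs.sink, frozenset(gs.genes))
            if key in seen:
                dups.append((seen[key], gs.id))
            else:
                seen[key] = gs.id
        return dups


@dataclass
class Chromosome:
    """A feasible network: one intermediate-gene ordering per gene set.

    ``fitness`` caches the last computed score; any operator that changes
    ``orderings`` must leave it ``None``.
    """

    orderings: Orderings
    fitness: float | None = None

    def copy(self) -> "Chromosome":
        return Chromosome(self.orderings, self.fitness)


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed graph given by explicit node and edge sets."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        nodes = frozenset(self.nodes)
        edges = frozenset(self.edges)
        for u, v in edges:
            if u not in nodes or v not in nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has an endpoint outside the node set")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "DirectedNetwork":
        edges = frozenset(edges)
        nodes = frozenset(u for e in edges for u in e)
        return cls(nodes, edges)

    @classmethod
    def from_paths(cls, paths: Iterable[Sequence[str]]) -> "DirectedNetwork":
        nodes: set[str] = set()
        edges: set[tuple[str, str]] = set()
        for p in paths:
            nodes.update(p)
            edges.update(zip(p, p[1:]))
        return cls(frozenset(nodes), frozenset(edges))


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm parameters.

    Defaults are the settings under which the method's behaviour was
    characterised: population size ``s=50``, crossover probability
    ``p_C=0.25``, per-path mutation probability ``p_M=0.01``, elite
    proportion ``p_E=0.25``, ``c_N=1`` path exchanged per crossover, and
    ``J=1000`` generations.
    """

    s: int = 50
    p_C: float = 0.25
    p_M: float = 0.01
    p_E: float = 0.25
    c_N: int = 1
    J: int = 1000
    seed: int = 0
    #: "per_path": each path of each chromosome mutates independently with
    #: probability p_M.  "per_chromosome": each chromosome mutates with
    #: probability p_M, re-drawing one uniformly chosen path's intermediates.
    mutation_scope: str = "per_path"

    def __post_init__(self) -> None:
        if self.s < 2 or self.s % 2:
            raise ValueError("population size s must be even and >= 2")
        for name in ("p_C", "p_M", "p_E"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.c_N < 1:
            raise ValueError("c_N must be >= 1")
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.mutation_scope not in ("per_path", "per_chromosome"):
            raise ValueError(f"unknown mutation_scope {self.mutation_scope!r}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def validate_orderings(compendium: Compendium, orderings: Orderings) -> None:
    """Raise :class:`InvalidChromosomeError` unless each ordering keeps its gene
    set's terminals fixed and permutes exactly its intermediate genes."""
    if len(orderings) != compendium.m:
        raise InvalidChromosomeError(
            f"expected {compendium.m} orderings, got {len(orderings)}"
        )
    for gs, path in zip(compendium.gene_sets, orderings):
        if len(path) != gs.length or path[0] != gs.source or path[-1] != gs.sink:
            raise InvalidChromosomeError(
                f"gene set {gs.id!r}: terminals or length altered in ordering {path}"
            )
        if set(path[1:-1]) != gs.intermediates:
            raise InvalidChromosomeError(
                f"gene set {gs.id!r}: intermediate genes differ from the gene set"
            )


def assemble_network(compendium: Compendium, orderings: Orderings) -> DirectedNetwork:
    """Union of consecutive-pair edges over all ordered paths.

    Shared edges are counted once: the network is a set union of its paths.
    """
    validate_orderings(compendium, orderings)
    return DirectedNetwork.from_paths(orderings)


def feasible_space_size(compendium: Compendium) -> int:
    """Number of feasible networks, ``∏ᵢ (Lᵢ − 2)!``, as an exact integer."""
    return math.prod(math.factorial(gs.length - 2) for gs in compendium.gene_sets)


def total_orderings(compendium: Compendium) -> int:
    """Number of unconstrained orderings, ``∏ᵢ Lᵢ!``, as an exact integer.

    This is the candidate pool without the fixed-terminal prior; the ratio to
    :func:`feasible_space_size` quantifies how much the prior shrinks the
    search.
    """
    return math.prod(math.factorial(gs.length) for gs in compendium.gene_sets)


def random_feasible_orderings(compendium: Compendium, rng: np.random.Generator) -> Orderings:
    """Draw one feasible network uniformly: each gene set's intermediates are
    independently and uniformly permuted, terminals fixed."""
    out = []
    for gs in compendium.gene_sets:
        mid = gs.genes[1:-1]
        if len(mid) > 1:
            perm = rng.permutation(len(mid))
            mid = tuple(mid[j] for j in perm)
        out.append((gs.source,) + tuple(mid) + (gs.sink,))
    return tuple(out)
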