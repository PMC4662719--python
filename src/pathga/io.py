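"""Readers/writers for GMT gene sets, SIF/TSV networks, ordered-path tables,
fitness traces, and run manifests.

Terminal designation rides on GMT gene order: the first gene of each line is
the source terminal and the last the sink terminal (standard GMT treats gene
order as meaningless — here the two end positions are semantic, the interior
order is not).  All writers sort deterministically so identical in-memory
state yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path as FsPath
from typing import Iterable, Sequence

import numpy as np

from . import __version__
from .core import Compendium, DirectedNetwork, GeneSet, Orderings
from .evolve import RunResult

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "read_paths",
    "write_paths",
    "write_trace",
    "RunManifest",
]


class ParseError(ValueError):
    pass


def read_gmt(path) -> Compendium:
    """Parse a GMT file (name TAB description TAB gene...) into a compendium.

    Each line needs at least three fields (name, description, ≥1 gene — two
    genes for a usable path); duplicate genes within a line are rejected.
    """
    gene_sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                raise ParseError(f"{path}:{lineno}: duplicate gene within set {name!r}")
            try:
                gene_sets.append(GeneSet(id=name, genes=tuple(genes)))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return Compendium(tuple(gene_sets))


def write_gmt(compendium: Compendium, path, description: str = "pathga") -> None:
    with open(path, "w") as fh:
        for gs in compendium.gene_sets:
            fh.write(gs.id + "\t" + description + "\t" + "\t".join(gs.genes) + "\n")


def write_network(network: DirectedNetwork, path, format: str = "sif") -> None:
    """Write a directed edge list, lexicographically sorted for stable bytes.

    ``sif``: ``src<TAB>interacts<TAB>dst``; ``tsv``: two columns.
    """
    if format not in ("sif", "tsv"):
        raise ValueError(f"unknown network format {format!r}")
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            if format == "sif":
                fh.write(f"{u}\tinteracts\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_network(path, format: str | None = None) -> DirectedNetwork:
    """Read a SIF or 2-column TSV edge list; the format is inferred from the
    extension when not given."""
    if format is None:
        format = "sif" if str(path).endswith(".sif") else "tsv"
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if format == "sif":
                if len(fields) != 3:
                    raise ParseError(f"{path}:{lineno}: SIF line needs 3 fields")
                edges.append((fields[0], fields[2]))
            else:
                if len(fields) != 2:
                    raise ParseError(f"{path}:{lineno}: TSV edge line needs 2 fields")
                edges.append((fields[0], fields[1]))
    return DirectedNetwork.from_edges(edges)


def write_paths(paths: Sequence[tuple[str, Sequence[str]]], path) -> None:
    """Write ordered paths as TSV rows: path id, then genes in order."""
    with open(path, "w") as fh:
        for pid, genes in paths:
            fh.write(pid + "\t" + "\t".join(genes) + "\n")


def read_paths(path) -> list[tuple[str, tuple[str, ...]]]:
    """Read a TSV path table (id + ordered genes); duplicate ids rejected."""
    out: list[tuple[str, tuple[str, ...]]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: path row needs an id and >= 1 gene")
            pid, *genes = fields
            if pid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate path id {pid!r}")
            seen.add(pid)
            out.append((pid, tuple(genes)))
    return out


def orderings_as_paths(
    compendium: Compendium, orderings: Orderings,
) -> list[tuple[str, tuple[str, ...]]]:
    """Pair each gene set's id with its inferred ordering for writing."""
    return [(gs.id, o) for gs, o in zip(compendium.gene_sets, orderings)]


def write_trace(result: RunResult, path, recovery: np.ndarray | None = None) -> None:
    """Per-generation trace TSV: generation, best, mean, best-so-far fitness,
    plus the recovery proportion when ground truth was supplied.  Floats use
    6 significant digits."""
    cols = ["generation", "best_fitness", "mean_fitness", "best_so_far_fitness"]
    if recovery is not None:
        cols.append("recovery_proportion")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in range(len(result.trace_best)):
            row = [
                str(g),
                f"{result.trace_best[g]:.6g}",
                f"{result.trace_mean[g]:.6g}",
                f"{result.best_so_far_trace[g]:.6g}",
            ]
            if recovery is not None:
                row.append(f"{recovery[g]:.6g}")
            fh.write("\t".join(row) + "\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run bit-for-bit: the resolved
    parameters, the seed, digests of the inputs, and the output paths."""

    command: str
    parameters: dict
    seed: int | None
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    outputs: list[str] = dataclasses.field(default_factory=list)
    version: str = __version__

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
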