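"""Markov-chain likelihood scoring of candidate networks.

The synergy (edge overlap) among a candidate's active paths is quantified by
treating the ordered paths as samples from a first-order Markov chain over
the ``n`` distinct genes.  With ``cᵢ`` the number of paths starting at gene
``i`` and ``c_jk`` the number of ``j→k`` transitions across all ``m`` paths,
the maximum-likelihood estimates are

    p₀ᵢ = cᵢ / m,     p_jk = c_jk / Σₖ c_jk ,

and a path ``a→b→c→d`` has likelihood ``p₀(a)·p_ab·p_bc·p_cd``.  The fitness
of a candidate network is the log-likelihood of its own paths under the
parameters estimated from those same paths:

    f(X̄, Θ̄) = Σᵢ log ℓ(Xᵢ, Θᵢ).

Self-estimation makes every factor strictly positive (each observed
transition has count ≥ 1), so the fitness is always finite, and it is
maximised by orderings that reuse the same edges — the more the paths
overlap, the fewer distinct successors each gene has and the closer the
transition probabilities are to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Compendium, Orderings, Path

__all__ = [
    "MarkovParams",
    "NEG_INF",
    "estimate_markov",
    "path_log_likelihood",
    "network_fitness",
]

#: Sentinel for a zero-probability path (never arises under self-estimation).
NEG_INF = float("-inf")


@dataclass(frozen=True, eq=False)
class MarkovParams:
    """First-order Markov chain estimates with their underlying counts.

    Arrays are indexed by the compendium's ``gene_index``; ``genes`` carries
    the matching labels.  Rows of ``trans`` for genes with no outgoing
    transition are all-zero (such rows are never queried when scoring the
    paths the estimates came from).
    """

    genes: tuple[str, ...]
    p0: np.ndarray          # (n,) initial probabilities cᵢ/m
    trans: np.ndarray       # (n, n) transition probabilities p_jk
    start_counts: np.ndarray  # (n,) integer cᵢ
    trans_counts: np.ndarray  # (n, n) integer c_jk

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})

    @property
    def n(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not among the {self.n} indexed genes") from None

    def to_tsv(self, path) -> None:
        """Debug dump: p0 as one row, Π as a labelled matrix."""
        with open(path, "w") as fh:
            fh.write("p0\t" + "\t".join(self.genes) + "\n")
            fh.write("\t" + "\t".join(f"{v:.6g}" for v in self.p0) + "\n")
            fh.write("pi\t" + "\t".join(self.genes) + "\n")
            for g, row in zip(self.genes, self.trans):
                fh.write(g + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def _counts(compendium: Compendium, orderings: Orderings) -> tuple[np.ndarray, np.ndarray]:
    """Start counts (n,) and transition counts (n, n) over the ordered paths."""
    n = compendium.n
    idx = compendium.gene_index
    start = np.zeros(n, dtype=np.int64)
    trans = np.zeros((n, n), dtype=np.int64)
    for path in orderings:
        codes = [idx[g] for g in path]
        start[codes[0]] += 1
        for j, k in zip(codes, codes[1:]):
            trans[j, k] += 1
    return start, trans


def estimate_markov(compendium: Compendium, orderings: Orderings) -> MarkovParams:
    """Maximum-likelihood Markov parameters of a set of ordered paths."""
    start, trans = _counts(compendium, orderings)
    m = len(orderings)
    p0 = start / m
    out = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(out > 0, trans / np.where(out > 0, out, 1), 0.0)
    return MarkovParams(
        genes=compendium.genes,
        p0=p0,
        trans=pi,
        start_counts=start,
        trans_counts=trans,
    )


def path_log_likelihood(path: Sequence[str], params: MarkovParams) -> float:
    """``log(p₀(first) · ∏ p_jk)`` along the path; ``-inf`` if any factor is 0."""
    i = params.index(path[0])
    p = params.p0[i]
    if p == 0.0:
        return NEG_INF
    total = math.log(p)
    prev = i
    for g in path[1:]:
        k = params.index(g)
        p = params.trans[prev, k]
        if p == 0.0:
            return NEG_INF
        total += math.log(p)
        prev = k
    return total


def network_fitness(
    compendium: Compendium,
    orderings: Orderings,
    params: MarkovParams | None = None,
) -> float:
    """Log-likelihood fitness of a candidate network.

    With ``params=None`` (the default, and what the search uses) the Markov
    parameters are re-estimated from *these* orderings and the self
    log-likelihood is returned; in that case the count-based closed form

        f = Σ_i cᵢ(log cᵢ − log m) + Σ_{jk} c_jk(log c_jk − log Σₖc_jk)

    is used, which is algebraically identical to summing the per-path log
    likelihoods.  Passing explicit ``params`` scores the orderings under a
    fixed parameter set instead (may be ``-inf``).
    """
    if params is not None:
        return sum(path_log_likelihood(p, params) for p in orderings)

    n = compendium.n
    idx = compendium.gene_index
    m = len(orderings)
    starts = np.fromiter((idx[p[0]] for p in orderings), dtype=np.int64, count=m)
    codes = np.fromiter(
        (idx[a] * n + idx[b] for p in orderings for a, b in zip(p, p[1:])),
        dtype=np.int64,
    )
    c_start = np.bincount(starts, minlength=n)
    c_start = c_start[c_start > 0]
    f = float(np.sum(c_start * (np.log(c_start) - math.log(m))))
    if codes.size:
        c_pair = np.bincount(codes)
        nz = np.nonzero(c_pair)[0]
        c_jk = c_pair[nz]
        rows = nz // n
        out = np.zeros(n, dtype=np.int64)
        np.add.at(out, rows, c_jk)
        f += float(np.sum(c_jk * (np.log(c_jk) - np.log(out[rows]))))
    return f
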