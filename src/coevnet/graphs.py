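"""Residue graphs, conservation entropy, maximal cliques and cutoff sweeps.

A protein graph has one node per query position (1-based); nodes carry the
query residue and a conservation score (normalized weighted Shannon entropy),
and an edge joins two positions whose coupling score reaches the cutoff.
Maximal cliques of the graph are the package's unit of coevolving residue
groups; sweeping the cutoff over a grid yields the node/edge/clique
distributions used to choose a working cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from statistics import median

import networkx as nx
import numpy as np
import pandas as pd

from .covariance import CovarianceMatrix
from .msa_io import GAP_CODE, MSA
from .weights import SequenceWeights, compute_weights

DEFAULT_CUTOFF_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))


def column_entropy(
    msa: MSA,
    weights: SequenceWeights | None = None,
    normalize: bool = True,
    include_gaps: bool = False,
) -> np.ndarray:
    """Per-column Shannon entropy of weighted residue frequencies.

    Gaps (and unknown residues) are excluded and the frequencies renormalized
    over the remaining weight, so the score reflects residue conservation
    rather than occupancy; ``include_gaps`` adds gap as a 21st symbol.
    Natural log, normalized by ln(20) (or ln(21)) into [0, 1].
    """
    if weights is None:
        weights = compute_weights(msa)
    codes = msa.codes()
    w = weights.weights
    n_states = 21 if include_gaps else 20
    out = np.zeros(msa.L)
    for col in range(msa.L):
        c = codes[:, col]
        if include_gaps:
            keep = c <= GAP_CODE
        else:
            keep = c < GAP_CODE
        if not keep.any():
            continue
        counts = np.zeros(n_states)
        np.add.at(counts, c[keep], w[keep])
        freq = counts / counts.sum()
        pos = freq > 0
        h = float(-(freq[pos] * np.log(freq[pos])).sum())
        out[col] = h / np.log(n_states) if normalize else h
    return out


def build_graph(
    matrix: CovarianceMatrix,
    cutoff: float,
    min_separation: int = 1,
    entropy: np.ndarray | None = None,
) -> nx.Graph:
    """Threshold a coupling matrix into an undirected residue graph.

    Every position is a node (isolated nodes are retained so the node count
    is cutoff-independent); edges join unmasked pairs with score >= cutoff
    and |i - j| >= min_separation (the default 1 excludes only self-loops).
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    g = nx.Graph(cutoff=cutoff, metric=matrix.metric)
    for i in range(1, matrix.L + 1):
        attrs = {"position": i}
        if matrix.residues:
            attrs["residue"] = matrix.residues[i - 1]
        if entropy is not None:
            attrs["entropy"] = float(entropy[i - 1])
        g.add_node(i, **attrs)
    vals = matrix.values
    mask = matrix.mask
    for i in range(matrix.L):
        for j in range(i + min_separation, matrix.L):
            if not mask[i, j] and vals[i, j] >= cutoff:
                g.add_edge(i + 1, j + 1, score=float(vals[i, j]))
    return g


@dataclass
class CliqueSet:
    """Maximal cliques of a residue graph in canonical order."""

    cliques: list[tuple[int, ...]]
    cutoff: float | None = None

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.cliques]

    def containing(self, position: int) -> list[tuple[int, ...]]:
        return [c for c in self.cliques if position in c]


def maximal_cliques(graph: nx.Graph, min_size: int = 2) -> CliqueSet:
    """All maximal cliques of size >= ``min_size`` (default 2: singletons are
    visible as isolated nodes, not cliques).

    Output is canonicalized: members sorted within each clique, cliques sorted
    by size descending then lexicographically.
    """
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) >= min_size]
    cliques.sort(key=lambda c: (-len(c), c))
    return CliqueSet(cliques=cliques, cutoff=graph.graph.get("cutoff"))


def cutoff_sweep(
    matrix: CovarianceMatrix,
    grid: tuple[float, ...] | list[float] | None = None,
    min_separation: int = 1,
    min_clique_size: int = 2,
) -> pd.DataFrame:
    """Node/edge/clique distributions over an ascending cutoff grid.

    Returns one row per cutoff with the count of non-isolated nodes, edges,
    maximal cliques, the largest and median clique size, and the clique-size
    histogram. Edge and non-isolated-node counts are non-increasing along the
    grid (edge sets are nested).
    """
    if grid is None:
        grid = DEFAULT_CUTOFF_GRID
    grid = list(grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("cutoff grid must be sorted ascending")
    rows = []
    for cutoff in grid:
        g = build_graph(matrix, cutoff, min_separation=min_separation)
        cliques = maximal_cliques(g, min_size=min_clique_size)
        sizes = cliques.sizes
        hist: dict[int, int] = {}
        for s in sizes:
            hist[s] = hist.get(s, 0) + 1
        rows.append(
            {
                "cutoff": cutoff,
                "nodes": sum(1 for n in g if g.degree(n) > 0),
                "edges": g.number_of_edges(),
                "cliques": len(cliques.cliques),
                "max_clique": max(sizes) if sizes else 0,
                "median_clique": float(median(sizes)) if sizes else 0.0,
                "size_hist": hist,
            }
        )
    return pd.DataFrame(rows)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """3-column TSV: position_i, position_j, score."""
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('score', 1.0):.10g}\n")


def write_cliques(cliques: CliqueSet, path: str | Path) -> None:
    """One clique per line, comma-separated 1-based positions."""
    with open(path, "w") as fh:
        for clique in cliques.cliques:
            fh.write(",".join(str(p) for p in clique) + "\n")


def write_sweep(sweep: pd.DataFrame, path: str | Path) -> None:
    cols = ["cutoff", "nodes", "edges", "cliques", "max_clique", "median_clique"]
    sweep[cols].to_csv(path, sep="\t", index=False)
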