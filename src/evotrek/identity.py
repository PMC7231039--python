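"""Pairwise nucleotide identity matrices and identity clustering.

Percent identity is matches / compared columns over an alignment, with
columns containing a gap or ambiguity in either row excluded from both
numerator and denominator — so 100% means "no observed difference".
Clusters at a threshold are single-linkage components; at threshold 100
with exact comparison this groups sequences identical over their compared
columns, the pattern behind per-family identity heat maps where several
strains share a literally identical gene.
"""

from __future__ import annotations

import math
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["pairwise_identity", "identity_clusters", "plot_identity_heatmap"]

_NUCS = frozenset("ACGT")


def _pair_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    kept = matches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _NUCS and y in _NUCS:
            kept += 1
            if x == y:
                matches += 1
    if kept == 0:
        return math.nan
    return 100.0 * matches / kept


def pairwise_identity(alignment: Mapping[str, str]) -> pd.DataFrame:
    """Symmetric percent-identity matrix over aligned nucleotide rows.

    Diagonal is exactly 100; a pair with zero compared columns is
    undefined (``nan``), never silently 0.
    """
    ids = list(alignment)
    n = len(ids)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i in range(n):
        mat.iloc[i, i] = 100.0
        for j in range(i + 1, n):
            v = _pair_identity(alignment[ids[i]], alignment[ids[j]])
            mat.iloc[i, j] = mat.iloc[j, i] = v
    return mat


def identity_clusters(matrix: pd.DataFrame, threshold: float = 100.0) -> list[list[str]]:
    """Single-linkage clusters of members joined by identity >= threshold.

    Undefined (nan) pairs never join.  Clusters are returned sorted by
    their smallest member for determinism.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    ids = list(matrix.index)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    vals = matrix.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = vals[i, j]
            if not math.isnan(v) and v >= threshold:
                graph.add_edge(ids[i], ids[j])
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    return [sorted(c) for c in comps]


def plot_identity_heatmap(matrix: pd.DataFrame, path: str, highlight: float = 100.0) -> None:
    """Optional heat-map rendering of an identity matrix (requires matplotlib).

    Members are ordered by their 100%-identity cluster so identical groups
    form contiguous blocks; cells at ``highlight`` stand out at the top of
    the color scale.  The TSV matrix, not this figure, is the contract.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [m for cluster in identity_clusters(matrix, highlight) for m in cluster]
    mat = matrix.loc[order, order]
    fig, ax = plt.subplots(figsize=(0.5 * len(order) + 2,) * 2)
    im = ax.imshow(mat.to_numpy(), vmin=0, vmax=100, cmap="YlOrRd")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    for i in range(len(order)):
        for j in range(len(order)):
            ax.text(j, i, f"{mat.iloc[i, j]:.0f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label="% nucleotide identity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
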