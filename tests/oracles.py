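"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or closed
form, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping

from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# Affine-gap local alignment (Gotoh three-matrix DP, score only)


def local_align_score(a: str, b: str, submat, gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score; a gap of length k costs open + k*extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = submat[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s)
            Ix[i][j] = max(M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return best


# ---------------------------------------------------------------------------
# Exhaustive small parsimony


def enumerate_parsimony(tree, column: Mapping[str, int], cost_gain: float, cost_loss: float):
    """Minimum cost and the set of optimal full labelings, by enumeration.

    Iterates every assignment of {0,1} to the internal nodes (leaves are
    fixed by the column).  Labelings are returned as frozensets of
    (node id, state) pairs.
    """
    internals = [n for n in tree.preorder() if n.children]
    leaves = tree.leaves()
    base = {leaf.id: column[leaf.name] for leaf in leaves}
    edges = [(n.parent.id, n.id) for n in tree.preorder() if n.parent is not None]
    best = math.inf
    optimal: set[frozenset] = set()
    for states in itertools.product((0, 1), repeat=len(internals)):
        lab = dict(base)
        lab.update({n.id: s for n, s in zip(internals, states)})
        cost = 0.0
        for p, c in edges:
            if lab[p] == 0 and lab[c] == 1:
                cost += cost_gain
            elif lab[p] == 1 and lab[c] == 0:
                cost += cost_loss
        if cost < best - 1e-9:
            best = cost
            optimal = {frozenset(lab.items())}
        elif abs(cost - best) <= 1e-9:
            optimal.add(frozenset(lab.items()))
    return best, optimal


# ---------------------------------------------------------------------------
# NG86 neighbor/pathway enumeration (via Biopython translation)


def _tr(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """(S, N) sites for one codon: 1/3 per non-stop single-nt neighbor."""
    syn = non = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            nb = codon[:pos] + nt + codon[pos + 1 :]
            if _tr(nb) == "*":
                continue
            if _tr(nb) == _tr(codon):
                syn += 1 / 3
            else:
                non += 1 / 3
    return syn, non


def ng86_diffs_oracle(a: str, b: str) -> tuple[float, float]:
    """(Sd, Nd) by explicit pathway enumeration, stop pathways excluded."""
    pos = [i for i in range(3) if a[i] != b[i]]
    if not pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(pos):
        cur = a
        syn = non = 0.0
        ok = True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if _tr(nxt) == "*":
                ok = False
                break
            if _tr(nxt) == _tr(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            results.append((syn, non))
    assert results, "all pathways blocked for sense endpoints"
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


# ---------------------------------------------------------------------------
# Graph components (BFS, no library)


def components_oracle(nodes, edges) -> set[frozenset]:
    adj: dict = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = set()
    comps = set()
    for start in nodes:
        if start in seen:
            continue
        comp = set()
        queue = [start]
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.add(frozenset(comp))
    return comps


# ---------------------------------------------------------------------------
# Expected flip counts for the two-state gain/loss process


def expected_event_count(tree, gain: float, loss: float, p_root_present: float) -> float:
    """Expected total number of state flips over the tree, per family.

    Closed-form occupancy integration of the two-state Markov process:
    with p1(u) the probability of presence at time u along a branch,
    E[gain flips] = gain * int p0 du and E[loss flips] = loss * int p1 du.
    """
    tot = gain + loss
    if tot == 0:
        return 0.0
    pi1 = gain / tot

    q1: dict[int, float] = {}
    total = 0.0
    for node in tree.preorder():
        if node.parent is None:
            q1[node.id] = p_root_present
            continue
        q = q1[node.parent.id]
        T = node.length
        decay = math.exp(-tot * T)
        int_p1 = pi1 * T + (q - pi1) * (1.0 - decay) / tot
        int_p0 = T - int_p1
        total += gain * int_p0 + loss * int_p1
        q1[node.id] = pi1 + (q - pi1) * decay
    return total


def expected_branch_events(tree, gain: float, loss: float, p_root_present: float) -> dict[int, float]:
    """Per-branch expected flip counts (child node id -> expectation)."""
    tot = gain + loss
    out: dict[int, float] = {}
    if tot == 0:
        return {n.id: 0.0 for n in tree.preorder() if n.parent is not None}
    pi1 = gain / tot
    q1: dict[int, float] = {}
    for node in tree.preorder():
        if node.parent is None:
            q1[node.id] = p_root_present
            continue
        q = q1[node.parent.id]
        T = node.length
        decay = math.exp(-tot * T)
        int_p1 = pi1 * T + (q - pi1) * (1.0 - decay) / tot
        int_p0 = T - int_p1
        out[node.id] = gain * int_p0 + loss * int_p1
        q1[node.id] = pi1 + (q - pi1) * decay
    return out
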