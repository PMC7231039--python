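"""Maximum-parsimony reconstruction of gene gain/loss events.

Given a binary presence/absence matrix (gene families x taxa) and a rooted
species tree, each family's ancestral states are reconstructed by weighted
(Sankoff) parsimony with separate costs for gains (0 -> 1) and losses
(1 -> 0).  All co-optimal labelings are enumerated (capped), each is
converted to per-branch events, and a single canonical scenario is chosen
by a deterministic tie rule for summary tables; the full set of co-optimal
scenarios is always retained so genuinely ambiguous histories — e.g. a
family present in the whole ingroup but absent from the outgroup, which is
equally well explained by a gain on the ingroup stem or by ancestral
presence plus a loss in the outgroup — stay visible.

Default costs penalize gains (gain=2, loss=1): acquiring a new gene,
typically by horizontal transfer, is treated as rarer than losing one.
Unit costs reproduce Fitch parsimony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .phylo import Node, SpeciesTree, TreeError

__all__ = [
    "fitch",
    "sankoff",
    "extract_events",
    "replay_events",
    "build_event_map",
    "FamilyEvents",
    "EventMap",
    "SCENARIO_CAP",
]

SCENARIO_CAP = 64

Event = tuple[int, str]  # (child node id of the branch, "gain" | "loss")


def _check_column(tree: SpeciesTree, column: Mapping[str, int]) -> None:
    for leaf in tree.leaves():
        if leaf.name not in column:
            raise ValueError(f"leaf {leaf.name!r} missing from character column")
        if column[leaf.name] not in (0, 1):
            raise ValueError(f"state for {leaf.name!r} must be 0 or 1")


def fitch(tree: SpeciesTree, column: Mapping[str, int]) -> tuple[int, dict[int, int]]:
    """Fitch small parsimony for one binary character on a binary tree.

    Post-order union/intersection, then pre-order resolution; ties at the
    root and during resolution prefer state 0 (absence).  Returns the
    minimum number of state changes and one optimal labeling
    (node id -> state).
    """
    _check_column(tree, column)
    for node in tree.preorder():
        if node.children and len(node.children) != 2:
            raise TreeError("fitch requires a binary tree; use sankoff for polytomies")

    sets: dict[int, frozenset[int]] = {}
    changes = 0
    for node in tree.postorder():
        if node.is_leaf:
            sets[node.id] = frozenset({column[node.name]})  # type: ignore[index]
        else:
            a, b = (sets[c.id] for c in node.children)
            inter = a & b
            if inter:
                sets[node.id] = inter
            else:
                sets[node.id] = a | b
                changes += 1

    labeling: dict[int, int] = {}
    for node in tree.preorder():
        s = sets[node.id]
        if node.parent is not None and labeling[node.parent.id] in s:
            labeling[node.id] = labeling[node.parent.id]
        else:
            labeling[node.id] = min(s)
    return changes, labeling


def sankoff(
    tree: SpeciesTree,
    column: Mapping[str, int],
    cost_gain: float = 2.0,
    cost_loss: float = 1.0,
    cap: int = SCENARIO_CAP,
) -> tuple[float, list[dict[int, int]], bool]:
    """Weighted parsimony with gain/loss costs; enumerates optimal labelings.

    A 0 -> 1 transition on a branch costs ``cost_gain``, 1 -> 0 costs
    ``cost_loss``.  Polytomies are allowed.  Returns ``(min_cost,
    labelings, overflow)`` where ``labelings`` are all cost-optimal full
    node-state assignments (at most ``cap``; ``overflow`` is True when the
    cap truncated the enumeration).
    """
    if cost_gain < 0 or cost_loss < 0:
        raise ValueError("costs must be non-negative")
    _check_column(tree, column)

    trans = [[0.0, float(cost_gain)], [float(cost_loss), 0.0]]
    INF = math.inf
    cost: dict[int, list[float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = column[node.name]  # type: ignore[index]
            cost[node.id] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
        else:
            c0 = c1 = 0.0
            for child in node.children:
                cc = cost[child.id]
                c0 += min(trans[0][0] + cc[0], trans[0][1] + cc[1])
                c1 += min(trans[1][0] + cc[0], trans[1][1] + cc[1])
            cost[node.id] = [c0, c1]

    root_costs = cost[tree.root.id]
    min_cost = min(root_costs)

    # backtracking enumeration of all optimal labelings
    tol = 1e-9
    labelings: list[dict[int, int]] = []
    overflow = False

    def expand(partial: dict[int, int], frontier: list[Node]) -> None:
        nonlocal overflow
        if len(labelings) >= cap:
            overflow = True
            return
        if not frontier:
            labelings.append(dict(partial))
            return
        node, rest = frontier[0], frontier[1:]
        pstate = partial[node.parent.id] if node.parent is not None else None
        for s in (0, 1):
            c = cost[node.id][s]
            if c == INF:
                continue
            if pstate is not None:
                # is s an optimal child choice given the parent state?
                other = 1 - s
                best = min(
                    trans[pstate][s] + cost[node.id][s],
                    trans[pstate][other] + cost[node.id][other],
                )
                if trans[pstate][s] + c > best + tol:
                    continue
            elif c > min_cost + tol:
                continue
            partial[node.id] = s
            expand(partial, rest)
            del partial[node.id]
            if overflow and len(labelings) >= cap:
                return

    order = list(tree.preorder())
    expand({}, order)
    return min_cost, labelings, overflow


def extract_events(labeling: Mapping[int, int], tree: SpeciesTree) -> list[Event]:
    """Per-branch events implied by an ancestral labeling.

    A branch (parent -> child) carries a gain when the state goes 0 -> 1
    and a loss when it goes 1 -> 0.  Events are reported as
    ``(child node id, kind)`` sorted by node id.
    """
    events: list[Event] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        p, c = labeling[node.parent.id], labeling[node.id]
        if p == 0 and c == 1:
            events.append((node.id, "gain"))
        elif p == 1 and c == 0:
            events.append((node.id, "loss"))
    events.sort()
    return events


def replay_events(
    tree: SpeciesTree, root_state: int, events: Sequence[Event]
) -> dict[str, int]:
    """Propagate a root state and branch events down the tree to the leaves."""
    ev = {nid: kind for nid, kind in events}
    state: dict[int, int] = {}
    leaf_states: dict[str, int] = {}
    for node in tree.preorder():
        if node.parent is None:
            state[node.id] = root_state
        else:
            s = state[node.parent.id]
            kind = ev.get(node.id)
            if kind == "gain":
                s = 1
            elif kind == "loss":
                s = 0
            state[node.id] = s
        if node.is_leaf:
            leaf_states[node.name] = state[node.id]  # type: ignore[index]
    return leaf_states


@dataclass
class FamilyEvents:
    """Parsimony reconstruction for one gene family."""

    family: str
    min_cost: float
    root_state: int  # canonical scenario's root state
    events: list[Event]  # canonical scenario
    scenarios: list[tuple[int, list[Event]]]  # all co-optimal (root_state, events)
    overflow: bool = False
    annotations: dict = field(default_factory=dict)  # e.g. duplication taxa

    @property
    def n_scenarios(self) -> int:
        return len(self.scenarios)


@dataclass
class EventMap:
    """Per-branch gain/loss assignments for every family, with ambiguity."""

    tree: SpeciesTree
    families: dict[str, FamilyEvents]
    cost_gain: float
    cost_loss: float


def _canonical_key(tree: SpeciesTree, root_state: int, events: list[Event]):
    n_gains = sum(1 for _, k in events if k == "gain")
    depth_total = sum(tree.depth(tree.nodes[nid]) for nid, _ in events)
    # prefer fewer gains, then events closer to the tips (DELTRAN-like),
    # then a fixed serialization for full determinism
    return (n_gains, -depth_total, root_state, tuple(events))


def build_event_map(
    matrix: pd.DataFrame,
    tree: SpeciesTree,
    cost_gain: float = 2.0,
    cost_loss: float = 1.0,
    copy_number: Optional[pd.DataFrame] = None,
    cap: int = SCENARIO_CAP,
) -> EventMap:
    """Sankoff reconstruction for every family of a presence/absence matrix.

    ``matrix`` has families as rows and taxa as columns (binary cells);
    its columns must equal the tree's leaf set.  The root state is free —
    the observed state of the outgroup leaf polarizes gains against
    losses.  ``copy_number`` (same shape, integer cells) adds duplication
    annotations for taxa carrying more than one family member.
    """
    leaf_names = set(tree.leaf_names())
    if set(matrix.columns) != leaf_names:
        raise ValueError(
            "matrix taxa do not match tree leaves: "
            f"{sorted(set(matrix.columns) ^ leaf_names)}"
        )
    families: dict[str, FamilyEvents] = {}
    for fam, row in matrix.iterrows():
        column = {t: int(v) for t, v in row.items()}
        min_cost, labelings, overflow = sankoff(
            tree, column, cost_gain, cost_loss, cap=cap
        )
        scen = []
        seen = set()
        for lab in labelings:
            rs = lab[tree.root.id]
            ev = extract_events(lab, tree)
            key = (rs, tuple(ev))
            if key not in seen:  # distinct labelings can imply identical events
                seen.add(key)
                scen.append((rs, ev))
        scen.sort(key=lambda s: _canonical_key(tree, s[0], s[1]))
        root_state, events = scen[0]
        # replay soundness, asserted at runtime as well as in tests
        if replay_events(tree, root_state, events) != column:
            raise AssertionError(
                f"internal error: canonical scenario for {fam} does not replay"
            )
        annotations = {}
        if copy_number is not None and fam in copy_number.index:
            dup = [t for t, c in copy_number.loc[fam].items() if c > 1]
            if dup:
                annotations["duplication"] = dup
        families[str(fam)] = FamilyEvents(
            family=str(fam),
            min_cost=min_cost,
            root_state=root_state,
            events=list(events),
            scenarios=scen,
            overflow=overflow,
            annotations=annotations,
        )
    return EventMap(tree=tree, families=families, cost_gain=cost_gain, cost_loss=cost_loss)
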