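"""Per-character parsimony optimisation on a fixed rooted tree.

Everything here runs through one generalised Sankoff dynamic programme over
per-node cost vectors, which is exact on polytomies under any symmetric cost
and yields full most-parsimonious-reconstruction (MPR) state sets by a
down-pass/up-pass rather than a single ACCTRAN/DELTRAN resolution:

* unordered characters: unit cost (classical Fitch counts),
* ordered characters: cost |i - j| between states,
* continuous characters: linear (Manhattan) parsimony, realised as Sankoff
  over the sorted unique tip values with cost |v_i - v_j| (the optimum is
  always attained at tip values, so this is exact).

Missing and inapplicable cells cost zero against every state, so they can
never create steps.  Node MPR sets are the states attaining the global
minimum in at least one most-parsimonious labelling; min/max counts of
independent origins of a state are computed by a second DP restricted to the
optimal labellings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .io_formats import INAPPLICABLE, MISSING, CharacterMatrix

_INF = float("inf")


# ---------------------------------------------------------------------------
# Tree index
# ---------------------------------------------------------------------------

class TreeIndex:
    """Array-backed rooted tree: parents, children, postorder, leaf labels."""

    def __init__(self, parent: List[int], children: List[List[int]],
                 labels: List[Optional[str]], lengths: Optional[List[float]] = None):
        self.parent = parent
        self.children = children
        self.labels = labels
        self.lengths = lengths  # edge length above each node (None for root)
        self.n_nodes = len(parent)
        self.root = parent.index(-1)
        self.postorder = self._postorder()
        self.preorder = list(reversed(self.postorder))
        self.leaves = [v for v in range(self.n_nodes) if not children[v]]
        self.leaf_of = {labels[v]: v for v in self.leaves}
        #: non-root nodes in postorder; "edge i" = edge above edge_nodes[i]
        self.edge_nodes = [v for v in self.postorder if v != self.root]

    def _postorder(self) -> List[int]:
        order, stack = [], [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                for c in self.children[v]:
                    stack.append((c, False))
        return order

    def tipset(self, v: int) -> frozenset:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if not self.children[u]:
                out.append(self.labels[u])
            else:
                stack.extend(self.children[u])
        return frozenset(out)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeIndex":
        nodes = list(tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = [-1] * len(nodes)
        children: List[List[int]] = [[] for _ in nodes]
        labels: List[Optional[str]] = [None] * len(nodes)
        lengths: List[float] = [0.0] * len(nodes)
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                p = index[id(n.parent_node)]
                parent[i] = p
                children[p].append(i)
            if n.is_leaf():
                labels[i] = n.taxon.label if n.taxon else n.label
            lengths[i] = n.edge.length if n.edge.length is not None else 0.0
        return cls(parent, children, labels, lengths)

    def mrca(self, tips: Sequence[str]) -> int:
        ids = [self.leaf_of[t] for t in tips]
        if len(ids) == 1:
            return ids[0]
        # depth-align walk
        depth = {}
        for v in self.preorder:
            depth[v] = 0 if self.parent[v] == -1 else depth[self.parent[v]] + 1
        cur = ids[0]
        for other in ids[1:]:
            a, b = cur, other
            while depth[a] > depth[b]:
                a = self.parent[a]
            while depth[b] > depth[a]:
                b = self.parent[b]
            while a != b:
                a, b = self.parent[a], self.parent[b]
            cur = a
        return cur


# ---------------------------------------------------------------------------
# Reconstruction containers
# ---------------------------------------------------------------------------

@dataclass
class ParsimonyReconstruction:
    char_id: int
    steps: float
    node_mpr: Dict[int, object]       # node -> frozenset of states / (lo, hi)
    changes: List[Tuple[int, object, object]]  # (child node, from, to) of one MPR
    ambiguous_nodes: frozenset
    kind: str = "discrete"            # "discrete" | "continuous"
    # internal context reused by origin counting and synapomorphy diagnosis
    tree: Optional[TreeIndex] = None
    cost: Optional[np.ndarray] = None
    down: Optional[np.ndarray] = None
    tip_sets: Optional[list] = None
    values: Optional[np.ndarray] = None  # continuous: candidate state values


@dataclass(frozen=True)
class HomoplasyIndices:
    char_id: int
    m: float
    s: float
    g: float
    ci: float
    ri: Optional[float]


# ---------------------------------------------------------------------------
# Sankoff machinery
# ---------------------------------------------------------------------------

def _column_tip_sets(ti: TreeIndex, column: Dict[str, object], k: int) -> list:
    """Per-node admissible state sets for leaves; None marks 'all states'."""
    tip_sets = [None] * ti.n_nodes
    for v in ti.leaves:
        cell = column.get(ti.labels[v], MISSING)
        if cell is MISSING or cell is INAPPLICABLE:
            tip_sets[v] = None
        else:
            if not isinstance(cell, frozenset):
                raise TypeError(
                    f"discrete optimisation needs state-set cells, got {cell!r}"
                )
            tip_sets[v] = cell
    return tip_sets


def _sankoff_down(ti: TreeIndex, tip_sets: list, cost: np.ndarray):
    """Down-pass cost vectors and per-child edge matrices.

    Returns (down, M) with down[v, s] = min cost of subtree(v) given v = s and
    M[c][s] = min_t cost[s, t] + down[c, t] for each non-root node c.
    """
    k = cost.shape[0]
    down = np.zeros((ti.n_nodes, k))
    M = [None] * ti.n_nodes
    for v in ti.postorder:
        if not ti.children[v]:
            if tip_sets[v] is not None:
                vec = np.full(k, _INF)
                vec[sorted(tip_sets[v])] = 0.0
                down[v] = vec
        else:
            acc = np.zeros(k)
            for c in ti.children[v]:
                Mc = np.min(cost + down[c][None, :], axis=1)
                M[c] = Mc
                acc = acc + Mc
            down[v] = acc
    return down, M


def _sankoff_up(ti: TreeIndex, down: np.ndarray, M: list, cost: np.ndarray):
    """Up-pass: up[v, s] = min cost of tree minus subtree(v) given v = s."""
    k = cost.shape[0]
    up = np.zeros((ti.n_nodes, k))
    for v in ti.preorder:
        if v == ti.root:
            continue
        p = ti.parent[v]
        # R[p, s] = up[p, s] + sum over siblings' M  (= total minus this child)
        R = up[p] + (down[p] - M[v])
        up[v] = np.min(cost + R[:, None], axis=0)
    return up


def _optimise_column(ti: TreeIndex, tip_sets: list, cost: np.ndarray,
                     char_id: int, kind: str = "discrete",
                     values: Optional[np.ndarray] = None) -> ParsimonyReconstruction:
    k = cost.shape[0]
    down, M = _sankoff_down(ti, tip_sets, cost)
    up = _sankoff_up(ti, down, M, cost)
    total = down + up
    steps = float(np.min(down[ti.root]))
    tol = 1e-9 * max(1.0, abs(steps))
    node_mpr: Dict[int, object] = {}
    ambiguous = []
    for v in range(ti.n_nodes):
        opt = np.nonzero(total[v] <= steps + tol)[0]
        states = frozenset(int(s) for s in opt)
        if kind == "continuous":
            vals = values[list(sorted(states))]
            node_mpr[v] = (float(vals.min()), float(vals.max()))
            if len(states) > 1:
                ambiguous.append(v)
        else:
            node_mpr[v] = states
            if len(states) > 1:
                ambiguous.append(v)
    changes = _one_resolution_changes(ti, down, cost, values if kind == "continuous" else None)
    return ParsimonyReconstruction(
        char_id=char_id, steps=steps, node_mpr=node_mpr, changes=changes,
        ambiguous_nodes=frozenset(ambiguous), kind=kind,
        tree=ti, cost=cost, down=down, tip_sets=tip_sets, values=values,
    )


def _one_resolution_changes(ti: TreeIndex, down: np.ndarray, cost: np.ndarray,
                            values: Optional[np.ndarray]):
    """Changes of one deterministic MPR (lowest optimal state at each step)."""
    assign = {}
    root_vec = down[ti.root]
    assign[ti.root] = int(np.argmin(root_vec))
    changes = []
    for v in ti.preorder:
        if v == ti.root:
            continue
        s = assign[ti.parent[v]]
        t = int(np.argmin(cost[s] + down[v]))
        assign[v] = t
        if t != s:
            if values is not None:
                changes.append((v, float(values[s]), float(values[t])))
            else:
                changes.append((v, s, t))
    return changes


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def unit_cost(k: int) -> np.ndarray:
    return 1.0 - np.eye(k)


def ordered_cost(k: int) -> np.ndarray:
    idx = np.arange(k)
    return np.abs(idx[:, None] - idx[None, :]).astype(float)


def _as_tree_index(tree) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex.from_dendropy(tree)


def _column_k(column: Dict[str, object], k: Optional[int]) -> int:
    observed = set()
    for cell in column.values():
        if isinstance(cell, frozenset):
            observed |= cell
    if k is None:
        k = (max(observed) + 1) if observed else 1
    elif observed and max(observed) >= k:
        raise ValueError(f"state {max(observed)} out of range for k={k}")
    return max(k, 1)


def fitch_optimise(tree, column: Dict[str, object], *, k: Optional[int] = None,
                   char_id: int = 0) -> ParsimonyReconstruction:
    """Minimum unweighted state changes (generalised Fitch, exact on polytomies)."""
    if not column:
        raise ValueError("empty character column")
    ti = _as_tree_index(tree)
    k = _column_k(column, k)
    tip_sets = _column_tip_sets(ti, column, k)
    return _optimise_column(ti, tip_sets, unit_cost(k), char_id)


def sankoff_optimise(tree, column: Dict[str, object], cost: np.ndarray, *,
                     char_id: int = 0) -> ParsimonyReconstruction:
    """Minimum total cost under an arbitrary symmetric transformation cost."""
    if not column:
        raise ValueError("empty character column")
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost must be a square matrix")
    if (cost < 0).any():
        raise ValueError("negative transformation costs are not allowed")
    if not np.allclose(cost, cost.T) or np.diagonal(cost).any():
        raise ValueError("cost must be symmetric with a zero diagonal")
    # warn (not fail) on non-metric costs: triangle-inequality violations
    k = cost.shape[0]
    import warnings

    tri = cost[:, :, None] + cost[None, :, :]  # cost[i,j]+cost[j,l] over j
    if (cost > np.min(tri, axis=1) + 1e-12).any():
        warnings.warn("transformation cost is non-metric; steps remain exact "
                      "but MPR interpretation is unusual", stacklevel=2)
    ti = _as_tree_index(tree)
    _column_k(column, k)
    tip_sets = _column_tip_sets(ti, column, k)
    return _optimise_column(ti, tip_sets, cost, char_id)


def linear_parsimony_continuous(tree, column: Dict[str, object], *,
                                char_id: int = 0) -> ParsimonyReconstruction:
    """Minimum total absolute change for a continuous character.

    Exact via Sankoff over the sorted unique finite tip values (for Manhattan
    parsimony some optimum always sits at tip values at every node).
    """
    if not column:
        raise ValueError("empty character column")
    ti = _as_tree_index(tree)
    vals = {}
    for taxon, cell in column.items():
        if cell is MISSING or cell is INAPPLICABLE:
            continue
        x = float(cell)
        if not np.isfinite(x):
            raise ValueError(f"taxon {taxon!r}: non-finite continuous value")
        vals[taxon] = x
    values = np.array(sorted(set(vals.values()))) if vals else np.array([0.0])
    code = {x: i for i, x in enumerate(values)}
    cost = np.abs(values[:, None] - values[None, :])
    pseudo = {
        t: (frozenset({code[vals[t]]}) if t in vals else MISSING) for t in column
    }
    tip_sets = _column_tip_sets(ti, pseudo, len(values))
    return _optimise_column(ti, tip_sets, cost, char_id, kind="continuous",
                            values=values)


def count_state_origins(recon: ParsimonyReconstruction, state: int) -> Tuple[int, int]:
    """(min, max) number of independent origins of `state`, over all MPRs.

    A branch counts when its child bears `state` and its parent does not;
    a root bearing the state counts as one (ancestral) origin, so the pair
    answers "how many times does the state arise independently?".
    """
    if recon.kind != "discrete":
        raise ValueError("origin counting applies to discrete reconstructions")
    ti, cost, down = recon.tree, recon.cost, recon.down
    k = cost.shape[0]
    if not 0 <= state < k:
        raise ValueError(f"state {state} out of range 0..{k - 1}")
    tol = 1e-9
    lo = np.zeros((ti.n_nodes, k))
    hi = np.zeros((ti.n_nodes, k))
    for v in ti.postorder:
        for c in ti.children[v]:
            edge = cost + down[c][None, :]          # edge[s, t]
            best = np.min(edge, axis=1)
            lo_add = np.full(k, _INF)
            hi_add = np.full(k, -_INF)
            for s in range(k):
                opts = np.nonzero(edge[s] <= best[s] + tol)[0]
                gain = ((opts == state) & (s != state)).astype(float)
                lo_add[s] = np.min(lo[c][opts] + gain)
                hi_add[s] = np.max(hi[c][opts] + gain)
            lo[v] += lo_add
            hi[v] += hi_add
    root_vec = down[ti.root]
    best = np.min(root_vec)
    opts = np.nonzero(root_vec <= best + tol)[0]
    root_gain = (opts == state).astype(float)
    return (int(np.min(lo[ti.root][opts] + root_gain)),
            int(np.max(hi[ti.root][opts] + root_gain)))


def homoplasy_indices(recon: ParsimonyReconstruction,
                      column: Dict[str, object], tree=None) -> HomoplasyIndices:
    """Consistency and retention indices for one discrete character."""
    if recon.kind != "discrete":
        raise ValueError("homoplasy indices apply to discrete characters")
    ti = recon.tree if tree is None else _as_tree_index(tree)
    cost = recon.cost
    k = cost.shape[0]
    cells = [
        c for t, c in column.items()
        if t in ti.leaf_of and isinstance(c, frozenset)
    ]
    s = float(recon.steps)
    m = _min_conceivable_steps(cells, cost)
    g = _star_tree_steps(cells, cost)
    ci = 1.0 if s == 0 else m / s
    ri = None if g <= m else (g - s) / (g - m)
    return HomoplasyIndices(char_id=recon.char_id, m=m, s=s, g=g, ci=ci, ri=ri)


def _min_conceivable_steps(cells: list, cost: np.ndarray) -> float:
    """Minimum steps on ANY tree: Steiner cost of connecting the required states.

    For unit costs this is (#states needed) - 1; for ordered costs it is the
    range max-min of the needed states.  Polymorphic cells are satisfied by
    any member state, handled greedily (exact for the cost structures used
    here, where singleton-cell states dominate the cover).
    """
    singles = set()
    polys = []
    for c in cells:
        if len(c) == 1:
            singles |= c
        else:
            polys.append(c)
    for p in polys:
        if not (p & singles):
            singles.add(min(p))
    if not singles:
        return 0.0
    states = sorted(singles)
    if _is_unit(cost):
        return float(len(states) - 1)
    # ordered |i-j| cost: minimal Steiner tree on a line is the range
    return float(cost[states[0], states[-1]])


def _is_unit(cost: np.ndarray) -> bool:
    k = cost.shape[0]
    return bool(np.array_equal(cost, 1.0 - np.eye(k)))


def _star_tree_steps(cells: list, cost: np.ndarray) -> float:
    """Maximum steps g: optimisation on a star tree (single interior node)."""
    if not cells:
        return 0.0
    k = cost.shape[0]
    per_state = np.zeros(k)
    for c in cells:
        idx = sorted(c)
        per_state += np.min(cost[:, idx], axis=1)
    return float(np.min(per_state))


def optimise_matrix(matrix: CharacterMatrix, tree, *,
                    char_ids: Optional[Sequence[int]] = None
                    ) -> Dict[int, ParsimonyReconstruction]:
    """Optimise every requested character on the tree, dispatching by kind."""
    ti = _as_tree_index(tree)
    for label in ti.leaf_of:
        matrix.taxon_index(label)  # raises KeyError if the tree has unscored tips
    out = {}
    for d in matrix.definitions:
        if char_ids is not None and d.char_id not in char_ids:
            continue
        column = matrix.column(d.char_id)
        if d.kind == "continuous":
            out[d.char_id] = linear_parsimony_continuous(ti, column,
                                                         char_id=d.char_id)
        elif d.ordered:
            out[d.char_id] = sankoff_optimise(ti, column, ordered_cost(d.n_states),
                                              char_id=d.char_id)
        else:
            out[d.char_id] = fitch_optimise(ti, column, k=d.n_states,
                                            char_id=d.char_id)
    return out
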