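"""Independent brute-force oracles used to validate the DP implementations.

These enumerate internal-node labelings explicitly and stay deliberately
naive; they share no code with the package's Sankoff/pruning machinery.
"""

import itertools
import math

import numpy as np

from morphplace.io_formats import INAPPLICABLE, MISSING
from morphplace.parsimony import TreeIndex


def random_topology(rng, n_tips, allow_polytomy=True):
    """Random rooted topology as a Newick string over tips T0..T{n-1}."""
    items = [f"T{i}" for i in range(n_tips)]

    def build(group):
        if len(group) == 1:
            return group[0]
        max_parts = min(3 if allow_polytomy else 2, len(group))
        n_parts = 2 if max_parts == 2 or rng.random() < 0.7 else 3
        idx = list(range(len(group)))
        rng.shuffle(idx)
        # random composition into n_parts non-empty parts
        cuts = sorted(rng.choice(np.arange(1, len(group)), size=n_parts - 1,
                                 replace=False).tolist())
        parts, prev = [], 0
        for c in cuts + [len(group)]:
            parts.append([group[i] for i in idx[prev:c]])
            prev = c
        return "(" + ",".join(build(p) for p in parts) + ")"

    return build(items) + ";"


def brute_force_parsimony(ti: TreeIndex, tip_states, cost, target_state=None):
    """Exhaustive minimisation over all internal labelings.

    tip_states: leaf label -> set of admissible states (full set if missing).
    Returns (steps, mpr_sets by node, (min_origins, max_origins)) where the
    origin counts are over `target_state` (skipped when None).
    """
    cost = np.asarray(cost, dtype=float)
    k = cost.shape[0]
    internals = [v for v in range(ti.n_nodes) if ti.children[v]]
    tips = [v for v in range(ti.n_nodes) if not ti.children[v]]
    allowed = {v: sorted(tip_states.get(ti.labels[v], range(k))) for v in tips}

    best = math.inf
    min_total = {v: {s: math.inf for s in range(k)} for v in range(ti.n_nodes)}
    orig_records = []

    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        internal_cost = sum(
            cost[amap[ti.parent[v]], amap[v]]
            for v in internals if v != ti.root
        )
        tip_best, tip_arg = {}, {}
        for v in tips:
            p = amap[ti.parent[v]]
            costs = {s: cost[p, s] for s in allowed[v]}
            m = min(costs.values())
            tip_best[v] = m
            tip_arg[v] = [s for s, c in costs.items() if c == m]
        total = internal_cost + sum(tip_best.values())
        best = min(best, total)
        for v in internals:
            min_total[v][amap[v]] = min(min_total[v][amap[v]], total)
        for v in tips:
            p = amap[ti.parent[v]]
            for s in allowed[v]:
                t_s = total - tip_best[v] + cost[p, s]
                min_total[v][s] = min(min_total[v][s], t_s)
        if target_state is not None:
            sigma = target_state
            orig = sum(
                1 for v in internals if v != ti.root
                and amap[v] == sigma and amap[ti.parent[v]] != sigma
            )
            if amap[ti.root] == sigma:
                orig += 1
            lo = hi = orig
            for v in tips:
                p = amap[ti.parent[v]]
                gains = [1 if (s == sigma and p != sigma) else 0
                         for s in tip_arg[v]]
                lo += min(gains)
                hi += max(gains)
            # only labelings achieving the optimum count; finalised below
            orig_records.append((total, lo, hi))

    mpr = {
        v: frozenset(s for s, t in min_total[v].items() if t <= best + 1e-9)
        for v in range(ti.n_nodes)
    }
    origins = None
    if target_state is not None:
        lo = min(l for t, l, h in orig_records if t <= best + 1e-9)
        hi = max(h for t, l, h in orig_records if t <= best + 1e-9)
        origins = (lo, hi)
    return best, mpr, origins


def brute_force_linear(ti: TreeIndex, tip_values):
    """Grid brute force for L1 parsimony at candidate = tip values."""
    vals = sorted(set(tip_values.values()))
    internals = [v for v in range(ti.n_nodes) if ti.children[v]]
    tips = [v for v in range(ti.n_nodes) if not ti.children[v]]
    best = math.inf
    for assign in itertools.product(vals, repeat=len(internals)):
        amap = dict(zip(internals, assign))
        total = sum(
            abs(amap[ti.parent[v]] - amap[v])
            for v in internals if v != ti.root
        )
        for v in tips:
            label = ti.labels[v]
            if label in tip_values:
                total += abs(amap[ti.parent[v]] - tip_values[label])
        best = min(best, total)
    return best


def mk_pattern_prob(ti: TreeIndex, tip_states, k, rates):
    """Exact pattern probability by summing over internal states."""
    internals = [v for v in range(ti.n_nodes) if ti.children[v]]
    tips = [v for v in range(ti.n_nodes) if not ti.children[v]]

    def P(t, r):
        e = math.exp(-k * r * t / (k - 1))
        return np.full((k, k), (1 - e) / k) + e * np.eye(k)

    total = 0.0
    for r in rates:
        mats = {v: P(ti.lengths[v], r) for v in range(ti.n_nodes)
                if v != ti.root}
        acc = 0.0
        for assign in itertools.product(range(k), repeat=len(internals)):
            amap = dict(zip(internals, assign))
            p = 1.0 / k
            for v in internals:
                if v != ti.root:
                    p *= mats[v][amap[ti.parent[v]], amap[v]]
            for v in tips:
                states = tip_states[ti.labels[v]]
                p *= sum(mats[v][amap[ti.parent[v]], s] for s in states)
            acc += p
        total += acc / len(rates)
    return total
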