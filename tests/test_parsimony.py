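"""Parsimony optimisation: worked examples, brute-force equivalence, properties."""

import numpy as np
import pytest

import morphplace as mp
from morphplace.parsimony import TreeIndex

from oracles import brute_force_linear, brute_force_parsimony, random_topology


def col(**kw):
    return {t: (frozenset({v}) if isinstance(v, int) else v)
            for t, v in kw.items()}


class TestWorkedExamples:
    def test_single_origin_forced(self, quartet_tree):
        r = mp.fitch_optimise(quartet_tree, col(A=0, B=0, C=1, D=1))
        assert r.steps == 1

    def test_two_steps_incongruent(self, quartet_tree):
        r = mp.fitch_optimise(quartet_tree, col(A=0, B=1, C=0, D=1))
        assert r.steps == 2

    def test_constant_column(self, quartet_tree):
        r = mp.fitch_optimise(quartet_tree, col(A=0, B=0, C=0, D=0), k=2)
        assert r.steps == 0
        assert all(s == frozenset({0}) for s in r.node_mpr.values())

    def test_all_missing_column(self, quartet_tree):
        r = mp.fitch_optimise(quartet_tree,
                              {t: mp.MISSING for t in "ABCD"}, k=2)
        assert r.steps == 0
        assert all(s == frozenset({0, 1}) for s in r.node_mpr.values())

    def test_empty_column_rejected(self, quartet_tree):
        with pytest.raises(ValueError):
            mp.fitch_optimise(quartet_tree, {})

    def test_ordered_cherry_root_interval(self, cherry_tree):
        r = mp.sankoff_optimise(cherry_tree, col(A=0, B=2), mp.ordered_cost(3))
        assert r.steps == 2
        assert r.node_mpr[r.tree.root] == frozenset({0, 1, 2})

    def test_ordered_quartet(self, quartet_tree):
        r = mp.sankoff_optimise(quartet_tree, col(A=0, B=0, C=2, D=2),
                                mp.ordered_cost(3))
        assert r.steps == 2

    def test_unit_cost_equals_fitch(self, quartet_tree):
        c = col(A=0, B=2, C=1, D=1)
        rf = mp.fitch_optimise(quartet_tree, c, k=3)
        rs = mp.sankoff_optimise(quartet_tree, c, mp.unit_cost(3))
        assert rf.steps == rs.steps
        assert rf.node_mpr == rs.node_mpr

    def test_negative_cost_rejected(self, quartet_tree):
        cost = mp.unit_cost(2)
        cost[0, 1] = cost[1, 0] = -1.0
        with pytest.raises(ValueError):
            mp.sankoff_optimise(quartet_tree, col(A=0, B=1, C=0, D=1), cost)

    def test_nonmetric_cost_warns(self, quartet_tree):
        cost = np.array([[0.0, 5.0, 1.0], [5.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.warns(UserWarning):
            mp.sankoff_optimise(quartet_tree, col(A=0, B=1, C=0, D=1), cost)

    def test_linear_cherry(self, cherry_tree):
        r = mp.linear_parsimony_continuous(cherry_tree, {"A": 1.0, "B": 3.0})
        assert r.steps == pytest.approx(2.0)
        assert r.node_mpr[r.tree.root] == (1.0, 3.0)

    def test_linear_constant(self, quartet_tree):
        r = mp.linear_parsimony_continuous(
            quartet_tree, {t: 2.5 for t in "ABCD"})
        assert r.steps == 0.0

    def test_linear_quartet(self, quartet_tree):
        r = mp.linear_parsimony_continuous(
            quartet_tree, {"A": 0.0, "B": 0.0, "C": 4.0, "D": 4.0})
        assert r.steps == pytest.approx(4.0)

    def test_linear_nonfinite_rejected(self, cherry_tree):
        with pytest.raises(ValueError):
            mp.linear_parsimony_continuous(cherry_tree,
                                           {"A": 1.0, "B": float("nan")})


class TestOrigins:
    def test_single_planted_origin(self, quartet_tree):
        r = mp.fitch_optimise(quartet_tree, col(A=0, B=0, C=1, D=1))
        assert mp.count_state_origins(r, 1) == (1, 1)

    def test_incongruent_origins(self, quartet_tree):
        r = mp.fitch_optimise(quartet_tree, col(A=0, B=1, C=0, D=1))
        assert mp.count_state_origins(r, 1) == (1, 2)

    def test_absent_state(self, quartet_tree):
        r = mp.fitch_optimise(quartet_tree, col(A=0, B=0, C=0, D=0), k=2)
        assert mp.count_state_origins(r, 1) == (0, 0)

    def test_state_out_of_range(self, quartet_tree):
        r = mp.fitch_optimise(quartet_tree, col(A=0, B=0, C=1, D=1))
        with pytest.raises(ValueError):
            mp.count_state_origins(r, 7)


class TestHomoplasyIndices:
    def test_no_homoplasy(self, quartet_tree):
        c = col(A=0, B=0, C=1, D=1)
        h = mp.homoplasy_indices(mp.fitch_optimise(quartet_tree, c), c)
        assert h.ci == 1.0

    def test_incongruent_ci_ri(self, quartet_tree):
        c = col(A=0, B=1, C=0, D=1)
        h = mp.homoplasy_indices(mp.fitch_optimise(quartet_tree, c), c)
        assert (h.m, h.s, h.g) == (1.0, 2.0, 2.0)
        assert h.ci == 0.5 and h.ri == 0.0

    def test_constant_char_ri_null(self, quartet_tree):
        c = col(A=0, B=0, C=0, D=0)
        h = mp.homoplasy_indices(mp.fitch_optimise(quartet_tree, c, k=2), c)
        assert h.ci == 1.0 and h.ri is None


def _random_column(rng, tips, k, p_missing=0.2, p_poly=0.1):
    out = {}
    for t in tips:
        u = rng.random()
        if u < p_missing:
            out[t] = mp.MISSING
        elif u < p_missing + p_poly and k > 2:
            states = rng.choice(k, size=2, replace=False)
            out[t] = frozenset(int(s) for s in states)
        else:
            out[t] = frozenset({int(rng.integers(k))})
    return out


@pytest.mark.parametrize("cost_kind", ["unit", "ordered"])
def test_matches_brute_force_on_random_instances(cost_kind):
    """Steps, MPR sets and origin bounds agree with exhaustive enumeration."""
    rng = np.random.default_rng(42 if cost_kind == "unit" else 43)
    for _ in range(40):
        n_tips = int(rng.integers(3, 7))
        k = int(rng.integers(2, 5))
        tree = mp.read_newick(random_topology(rng, n_tips))
        ti = TreeIndex.from_dendropy(tree)
        column = _random_column(rng, [f"T{i}" for i in range(n_tips)], k)
        cost = mp.unit_cost(k) if cost_kind == "unit" else mp.ordered_cost(k)
        r = mp.sankoff_optimise(ti, column, cost)
        tip_states = {t: sorted(c) for t, c in column.items()
                      if isinstance(c, frozenset)}
        target = int(rng.integers(k))
        steps, mpr, origins = brute_force_parsimony(ti, tip_states, cost,
                                                    target_state=target)
        assert r.steps == pytest.approx(steps)
        for v in range(ti.n_nodes):
            assert r.node_mpr[v] == mpr[v], f"MPR mismatch at node {v}"
        assert mp.count_state_origins(r, target) == origins


def test_linear_parsimony_matches_grid_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n_tips = int(rng.integers(3, 6))
        tree = mp.read_newick(random_topology(rng, n_tips))
        ti = TreeIndex.from_dendropy(tree)
        column = {f"T{i}": float(np.round(rng.uniform(0, 5), 2))
                  for i in range(n_tips)}
        r = mp.linear_parsimony_continuous(ti, column)
        assert r.steps == pytest.approx(brute_force_linear(ti, column))


def test_ordered_at_least_unordered_and_binary_equality():
    rng = np.random.default_rng(99)
    for _ in range(30):
        n_tips = int(rng.integers(3, 7))
        k = int(rng.integers(2, 5))
        tree = mp.read_newick(random_topology(rng, n_tips))
        column = _random_column(rng, [f"T{i}" for i in range(n_tips)], k,
                                p_poly=0.0)
        r_u = mp.fitch_optimise(tree, column, k=k)
        r_o = mp.sankoff_optimise(tree, column, mp.ordered_cost(k))
        assert r_o.steps >= r_u.steps
        observed = set().union(*[c for c in column.values()
                                 if isinstance(c, frozenset)] or [set()])
        if observed <= {0, 1}:
            assert r_o.steps == r_u.steps


def test_adding_a_tip_never_decreases_steps():
    rng = np.random.default_rng(1234)
    for _ in range(20):
        n_tips = int(rng.integers(3, 6))
        k = int(rng.integers(2, 4))
        inner = random_topology(rng, n_tips).rstrip(";")
        column = _random_column(rng, [f"T{i}" for i in range(n_tips)], k,
                                p_missing=0.1, p_poly=0.0)
        base = mp.fitch_optimise(mp.read_newick(inner + ";"), column, k=k)
        grown = mp.read_newick(f"({inner},EXTRA);")
        column["EXTRA"] = frozenset({int(rng.integers(k))})
        assert mp.fitch_optimise(grown, column, k=k).steps >= base.steps


def test_linear_equals_ordered_on_integer_data():
    rng = np.random.default_rng(5)
    for _ in range(15):
        n_tips = int(rng.integers(3, 6))
        k = 4
        tree = mp.read_newick(random_topology(rng, n_tips))
        states = {f"T{i}": int(rng.integers(k)) for i in range(n_tips)}
        r_o = mp.sankoff_optimise(
            tree, {t: frozenset({s}) for t, s in states.items()},
            mp.ordered_cost(k))
        r_l = mp.linear_parsimony_continuous(
            tree, {t: float(s) for t, s in states.items()})
        assert r_l.steps == pytest.approx(r_o.steps)


def test_optimise_matrix_dispatch(matrix_factory, quartet_tree):
    m = matrix_factory(
        ["A", "B", "C", "D"],
        [{"A": 0.0, "B": 1.0, "C": 2.0, "D": 3.0},
         {"A": 0, "B": 0, "C": 1, "D": 1},
         {"A": 0, "B": 1, "C": 2, "D": 2}],
        ordered={3},
    )
    recon = mp.optimise_matrix(m, quartet_tree)
    assert recon[1].kind == "continuous"
    assert recon[2].steps == 1
    assert recon[3].kind == "discrete"
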