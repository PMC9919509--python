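"""Fossil placement: attachment scan oracle, MCMC behaviour, summaries."""

import math

import numpy as np
import pytest

import morphplace as mp
from morphplace.parsimony import TreeIndex
from morphplace.placement import Attachment, McmcResult, PosteriorSample

from oracles import random_topology


def _matrix_with_fossil(taxa, columns, fossil_name, fossil_cells):
    defs = []
    n_chars = len(columns)
    for j in range(n_chars):
        observed = set()
        for v in columns[j].values():
            observed |= v if isinstance(v, (set, frozenset)) else {v}
        fc = fossil_cells[j]
        if isinstance(fc, frozenset):
            observed |= fc
        defs.append(mp.CharacterDefinition(char_id=j + 1,
                                           n_states=max(2, max(observed) + 1)))
    cells = []
    for t in taxa:
        cells.append([frozenset({columns[j][t]}) for j in range(n_chars)])
    cells.append(list(fossil_cells))
    return mp.CharacterMatrix(taxa=list(taxa) + [fossil_name],
                              definitions=defs, cells=cells)


class TestAttachScan:
    def test_identical_to_extant_prefers_its_branch(self):
        tree = mp.read_newick("((A,B),(C,D));")
        cols = [{"A": 0, "B": 0, "C": 1, "D": 1},
                {"A": 1, "B": 0, "C": 0, "D": 0},
                {"A": 0, "B": 1, "C": 1, "D": 1}]
        m = _matrix_with_fossil("ABCD", cols, "fx",
                                [frozenset({0}), frozenset({1}), frozenset({0})])
        scores, uninformative = mp.attach_parsimony_scan("fx", m, tree)
        assert not uninformative
        assert scores[0].tips_below == frozenset({"A"})
        assert scores[0].added_steps == 0

    def test_all_missing_fossil_ties_everywhere(self):
        tree = mp.read_newick("((A,B),(C,D));")
        cols = [{"A": 0, "B": 0, "C": 1, "D": 1}]
        m = _matrix_with_fossil("ABCD", cols, "fx", [mp.MISSING])
        scores, uninformative = mp.attach_parsimony_scan("fx", m, tree)
        assert uninformative
        assert {s.added_steps for s in scores} == {0}

    def test_matches_reoptimisation_oracle(self):
        """Scan equals re-running full optimisation with the fossil grafted."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            n_tips = 5
            newick = random_topology(rng, n_tips, allow_polytomy=False)
            tree = mp.read_newick(newick)
            ti = TreeIndex.from_dendropy(tree)
            cols = [{f"T{i}": int(rng.integers(3)) for i in range(n_tips)}
                    for _ in range(4)]
            fossil_cells = [frozenset({int(rng.integers(3))}) if rng.random() > 0.3
                            else mp.MISSING for _ in range(4)]
            m = _matrix_with_fossil([f"T{i}" for i in range(n_tips)], cols,
                                    "fx", fossil_cells)
            scores, _ = mp.attach_parsimony_scan("fx", m, tree)
            base = sum(
                mp.fitch_optimise(ti, {t: frozenset({cols[j][t]})
                                       for t in cols[j]}, k=3).steps
                for j in range(4))
            for sc in scores:
                grafted = _graft_newick(newick, ti, sc.branch)
                gt = mp.read_newick(grafted)
                total = 0.0
                for j in range(4):
                    column = {t: frozenset({cols[j][t]}) for t in cols[j]}
                    column["fx"] = fossil_cells[j]
                    total += mp.fitch_optimise(gt, column, k=3).steps
                assert total - base == pytest.approx(sc.added_steps)


def _graft_newick(newick, ti, branch_node):
    """Insert (sub,fx) around the subtree string of `branch_node`."""
    tips = sorted(ti.tipset(branch_node))
    if len(tips) == 1:
        target = tips[0]
        return newick.replace(target, f"({target},fx)")
    # identify the subtree string by regenerating from the tree index
    def render(v):
        if not ti.children[v]:
            return ti.labels[v]
        return "(" + ",".join(render(c) for c in ti.children[v]) + ")"
    sub = render(branch_node)
    return newick.replace(sub, f"({sub},fx)")


def _tiny_setup(seed=2, n_extant=12, n_chars=25):
    sc = mp.simulate_scaffold(n_extant, seed)
    cfg = mp.SimulationConfig(tree=sc, n_chars=n_chars, n_continuous=0,
                              seed=seed)
    matrix, truth = mp.simulate_matrix(cfg)
    ti = truth.tree_index
    clade = sc.clades[sorted(sc.clades)[0]]
    child = ti.children[ti.mrca(sorted(clade.tips))][0]
    spec = mp.FossilSpec(name="fx", branch_tips=ti.tipset(child),
                         missing_fraction=0.4)
    matrix = mp.add_fossils(matrix, truth, [spec], seed=seed)
    sc.tip_status["fx"] = "floating"
    return sc, matrix, truth, clade


class TestMcmc:
    def test_same_seed_identical_streams(self):
        sc, matrix, truth, clade = _tiny_setup()
        cfg = mp.MkModelConfig(generations=300, sample_every=10, runs=1,
                               chains_per_run=2, seed=7)
        r1 = mp.run_mcmc(matrix, sc, cfg)
        r2 = mp.run_mcmc(matrix, sc, cfg)
        assert [s.log_posterior for s in r1.samples] == \
            [s.log_posterior for s in r2.samples]
        assert [s.attachments for s in r1.samples] == \
            [s.attachments for s in r2.samples]

    def test_no_floating_fossils_rejected(self):
        sc = mp.simulate_scaffold(8, 1)
        cfg = mp.SimulationConfig(tree=sc, n_chars=5, n_continuous=0, seed=1)
        matrix, _ = mp.simulate_matrix(cfg)
        with pytest.raises(ValueError, match="floating"):
            mp.run_mcmc(matrix, sc, mp.MkModelConfig(generations=100,
                                                     sample_every=10))

    def test_invalid_generations_rejected(self):
        with pytest.raises(ValueError):
            mp.MkModelConfig(generations=0)
        with pytest.raises(ValueError):
            mp.MkModelConfig(generations=100, sample_every=400)

    def test_recovers_planted_placement(self):
        sc, matrix, truth, clade = _tiny_setup()
        cfg = mp.MkModelConfig(generations=3000, sample_every=15, runs=1,
                               chains_per_run=1, seed=3, burnin_fraction=0.3)
        res = mp.run_mcmc(matrix, sc, cfg)
        summ = mp.summarise(res, sc)
        bpp = summ.summaries["fx"].clade_bpp
        assert bpp[(clade.name, "total")] > 0.8


class TestSummarise:
    def _fake_result(self, sc, samples_spec):
        """Build an McmcResult by hand from (host_node_tipsets) per sample."""
        bt = TreeIndex.from_dendropy(sc.tree)
        samples = []
        for gen, tips in enumerate(samples_spec):
            node = bt.mrca(sorted(tips)) if len(tips) > 1 \
                else bt.leaf_of[next(iter(tips))]
            samples.append(PosteriorSample(
                run=gen % 2, generation=gen,
                attachments={"fx": Attachment(host=("b", node), frac=0.5,
                                              pendant=0.1)},
                alpha=1.0, log_posterior=-1.0))
        cfg = mp.MkModelConfig(generations=10, sample_every=10)
        return McmcResult(samples=samples, backbone=bt, fossils=["fx"],
                          acceptance={}, n_generations=10, config=cfg)

    @pytest.fixture
    def abcd_scaffold(self):
        tree = mp.read_newick("(((A,B),(C,D)),E);")
        return mp.build_scaffold(tree, clades=[
            mp.CladeDefinition(name="AB", tips=frozenset({"A", "B"})),
            mp.CladeDefinition(name="ABCD",
                               tips=frozenset({"A", "B", "C", "D"}))])

    def test_two_thirds_bpp(self, abcd_scaffold):
        res = self._fake_result(abcd_scaffold, [{"A"}, {"B"}, {"C"}])
        summ = mp.summarise(res, abcd_scaffold)
        bpp = summ.summaries["fx"].clade_bpp
        assert bpp[("AB", "crown")] == pytest.approx(2 / 3)
        assert bpp[("ABCD", "crown")] == 1.0

    def test_stem_counts_total_only(self, abcd_scaffold):
        res = self._fake_result(abcd_scaffold, [{"A", "B"}] * 3)
        summ = mp.summarise(res, abcd_scaffold)
        bpp = summ.summaries["fx"].clade_bpp
        assert bpp.get(("AB", "crown"), 0.0) == 0.0
        assert bpp[("AB", "total")] == 1.0
        assert bpp[("ABCD", "crown")] == 1.0

    def test_branch_posterior_sums_to_one(self, abcd_scaffold):
        res = self._fake_result(abcd_scaffold, [{"A"}, {"B"}, {"C"}, {"D"}])
        summ = mp.summarise(res, abcd_scaffold)
        assert sum(summ.summaries["fx"].branch_posterior.values()) == \
            pytest.approx(1.0)

    def test_bpp_nesting_monotonicity_exact(self, abcd_scaffold):
        res = self._fake_result(abcd_scaffold,
                                [{"A"}, {"A", "B"}, {"C"}, {"E"}, {"B"}])
        summ = mp.summarise(res, abcd_scaffold)
        bpp = summ.summaries["fx"].clade_bpp
        for concept in ("crown", "total"):
            assert bpp.get(("AB", concept), 0.0) <= \
                bpp.get(("ABCD", concept), 0.0) + 1e-12

    def test_unanimous_split_has_full_support(self, abcd_scaffold):
        res = self._fake_result(abcd_scaffold, [{"A"}] * 4)
        summ = mp.summarise(res, abcd_scaffold)
        assert all(f <= 1.0 for f in summ.split_frequencies.values())
        labels = [n.label for n in summ.consensus.preorder_node_iter()
                  if n.label and not n.is_leaf()]
        assert "1.000" in labels

    def test_consensus_contains_only_majority_splits(self, abcd_scaffold):
        res = self._fake_result(abcd_scaffold,
                                [{"A"}, {"A"}, {"A"}, {"C"}, {"D"}])
        summ = mp.summarise(res, abcd_scaffold)
        all_tips = frozenset("ABCDE") | {"fx"}
        for node in summ.consensus.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            if below != all_tips:
                assert summ.split_frequencies.get(below, 0.0) > 0.5

    def test_group_bpp(self, abcd_scaffold):
        res = self._fake_result(abcd_scaffold, [{"A"}, {"B"}, {"C"}])
        summ = mp.summarise(res, abcd_scaffold,
                            groups={"grp": (["fx"], "AB", "crown")})
        assert summ.group_bpp["grp"] == pytest.approx(2 / 3)

    def test_empty_samples_rejected(self, abcd_scaffold):
        res = self._fake_result(abcd_scaffold, [{"A"}])
        res.samples = []
        with pytest.raises(ValueError):
            mp.summarise(res, abcd_scaffold)
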