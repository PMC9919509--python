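"""Backbone-constrained placement of fragmentary fossil tips.

Two complementary routes:

* :func:`attach_parsimony_scan` — exhaustive scan: for every backbone branch,
  the extra parsimony steps incurred by attaching the fossil there (exact,
  via the Sankoff down/up vectors, no re-optimisation per branch).
* :func:`run_mcmc` / :func:`summarise` — Bayesian placement under the Mk
  model with discrete-gamma rate variation and variable (ascertainment-
  corrected) coding.  Extant relationships are a hard constraint; the only
  topology moves re-attach floating fossils to backbone or other fossils'
  pendant branches.  Metropolis-coupled chains with incremental heating,
  multiple independent runs, majority-rule consensus and per-clade
  crown/total membership posteriors.

The k-state Mk transition kernel has the closed form
``P_same(t) = 1/k + (k-1)/k * exp(-k r t/(k-1))`` under the convention of one
expected change per unit branch length at rate ``r = 1``; continuous
characters are excluded from the likelihood.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from numba import njit
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .io_formats import INAPPLICABLE, MISSING, CharacterMatrix
from .parsimony import (
    ParsimonyReconstruction,
    TreeIndex,
    _column_tip_sets,
    _sankoff_down,
    _sankoff_up,
    ordered_cost,
    unit_cost,
)
from .scaffold import ScaffoldTree

# ---------------------------------------------------------------------------
# Model configuration
# ---------------------------------------------------------------------------


@dataclass
class MkModelConfig:
    """Sampler settings (defaults mirror common morphological practice)."""

    generations: int
    seed: int = 0
    n_rate_categories: int = 4
    coding: str = "variable"  # "variable" | "all"
    branch_length_prior_rate: float = 10.0
    alpha_prior_rate: float = 1.0
    runs: int = 2
    chains_per_run: int = 4
    heat_temperature: float = 0.1
    sample_every: int = 4000
    burnin_fraction: float = 0.25
    move_weights: Tuple[float, float, float] = (0.4, 0.4, 0.2)  # reattach/length/alpha

    def __post_init__(self):
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        if self.generations < self.sample_every:
            raise ValueError("generations must be >= sample_every")
        if not 0 < self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must lie in (0, 1)")
        if self.heat_temperature <= 0:
            raise ValueError("heat_temperature must be positive")
        if self.coding not in ("variable", "all"):
            raise ValueError(f"unknown coding {self.coding!r}")


# ---------------------------------------------------------------------------
# Discrete-gamma rates
# ---------------------------------------------------------------------------

def gamma_category_rates(alpha: float, n: int = 4) -> np.ndarray:
    """Mean rates of n equal-probability discrete-gamma categories (mean 1)."""
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if n == 1:
        return np.ones(1)
    bounds = _gamma_dist.ppf(np.arange(1, n) / n, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], bounds * alpha, [np.inf]])
    cdf_hi = gammainc(alpha + 1.0, edges[1:])
    cdf_lo = gammainc(alpha + 1.0, edges[:-1])
    rates = n * (cdf_hi - cdf_lo)
    return rates / rates.mean()  # guard tiny numerical drift; mean is 1 anyway


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

class _Topo:
    """Minimal rooted topology for pruning: arrays + leaf taxon labels."""

    __slots__ = ("parent", "children", "postorder", "root", "length",
                 "leaf_taxon", "post_arr", "child_ptr", "child_idx", "len_arr")

    def __init__(self, parent, children, length, leaf_taxon):
        self.parent = parent
        self.children = children
        self.length = length
        self.leaf_taxon = leaf_taxon
        self.root = parent.index(-1)
        order, stack = [], [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                order.append(v)
            else:
                stack.append((v, True))
                for c in children[v]:
                    stack.append((c, False))
        self.postorder = order
        n = len(parent)
        self.post_arr = np.asarray(order, dtype=np.int64)
        counts = np.zeros(n + 1, dtype=np.int64)
        for v in range(n):
            counts[v + 1] = len(children[v])
        self.child_ptr = np.cumsum(counts)
        self.child_idx = np.asarray(
            [c for v in range(n) for c in children[v]], dtype=np.int64)
        self.len_arr = np.asarray(length, dtype=np.float64)

    @classmethod
    def from_tree_index(cls, ti: TreeIndex) -> "_Topo":
        leaf_taxon = {v: ti.labels[v] for v in ti.leaves}
        return cls(list(ti.parent), [list(c) for c in ti.children],
                   list(ti.lengths or [0.0] * ti.n_nodes), leaf_taxon)


@njit(cache=True)
def _prune_kernel(partial, postorder, child_ptr, child_idx, length, rates, kk):
    """In-place pruning pass; partial has shape (n_nodes, R, C, k)."""
    n, R, C, k = partial.shape
    for idx in range(postorder.shape[0]):
        v = postorder[idx]
        for ci in range(child_ptr[v], child_ptr[v + 1]):
            c = child_idx[ci]
            t = length[c]
            for r in range(R):
                e = np.exp(-kk * rates[r] * t / (kk - 1.0))
                om = (1.0 - e) / kk
                for cc in range(C):
                    s = 0.0
                    for x in range(k):
                        s += partial[c, r, cc, x]
                    s *= om
                    for x in range(k):
                        partial[v, r, cc, x] *= e * partial[c, r, cc, x] + s


def _cell_partial(cell, k: int) -> np.ndarray:
    if cell is MISSING or cell is INAPPLICABLE:
        return np.ones(k)
    vec = np.zeros(k)
    vec[sorted(cell)] = 1.0
    return vec


class MkEngine:
    """Pruning likelihood for one matrix, reusable across topologies.

    Characters are grouped by state count k; per group, k extra pseudo
    characters with basis tip partials ride along the same pruning pass and
    deliver the probability of an invariant pattern for the variable-coding
    correction.
    """

    def __init__(self, matrix: CharacterMatrix, *,
                 char_ids: Optional[Sequence[int]] = None,
                 n_rate_categories: int = 4, coding: str = "variable"):
        if coding not in ("variable", "all"):
            raise ValueError(f"unknown coding {coding!r}")
        self.coding = coding
        self.n_rates = n_rate_categories
        ids = [d.char_id for d in matrix.definitions if d.kind == "discrete"]
        if char_ids is not None:
            wanted = set(char_ids)
            ids = [i for i in ids if i in wanted]
        if not ids:
            raise ValueError("no discrete characters selected for the likelihood")
        self.char_ids = ids
        by_k: Dict[int, List[int]] = defaultdict(list)
        for i in ids:
            by_k[matrix.definition(i).n_states].append(i)
        self.groups = []
        for k in sorted(by_k):
            gids = by_k[k]
            tip_part = {}
            for t in matrix.taxa:
                rows = [_cell_partial(matrix.column(i)[t], k) for i in gids]
                rows.extend(np.eye(k))  # pseudo invariant-basis characters
                tip_part[t] = np.array(rows)
            self.groups.append((k, gids, tip_part))
        self._rate_cache: Dict[Tuple[float, int], np.ndarray] = {}
        self._ctx_key = None
        self._ctx = None

    def _rates(self, alpha: float) -> np.ndarray:
        key = (round(float(alpha), 12), self.n_rates)
        if key not in self._rate_cache:
            if len(self._rate_cache) > 4096:
                self._rate_cache.clear()
            self._rate_cache[key] = gamma_category_rates(alpha, self.n_rates)
        return self._rate_cache[key]

    def _leaf_context(self, topo: _Topo):
        """Per-group leaf ids + stacked tip partials, cached across topologies
        that share the same node numbering (as MCMC placed trees do)."""
        key = (len(topo.parent), tuple(sorted(topo.leaf_taxon.items())))
        if self._ctx_key == key:
            return self._ctx
        ctx = []
        leaf_ids = np.asarray(sorted(topo.leaf_taxon), dtype=np.int64)
        for k, gids, tip_part in self.groups:
            parts = np.stack([tip_part[topo.leaf_taxon[v]] for v in leaf_ids])
            ctx.append((leaf_ids, parts))
        self._ctx_key, self._ctx = key, ctx
        return ctx

    def loglik(self, topo: _Topo, alpha: float) -> float:
        rates = self._rates(alpha)
        R = len(rates)
        total = 0.0
        ctx = self._leaf_context(topo)
        n = len(topo.parent)
        for (k, gids, tip_part), (leaf_ids, leaf_parts) in zip(self.groups, ctx):
            C = len(gids)
            partial = np.ones((n, R, C + k, k))
            partial[leaf_ids] = leaf_parts[:, None, :, :]
            _prune_kernel(partial, topo.post_arr, topo.child_ptr,
                          topo.child_idx, topo.len_arr, rates, float(k))
            lik = partial[topo.root].mean(axis=2).mean(axis=0)  # uniform root
            real, pinv = lik[:C], float(lik[C:].sum())
            if self.coding == "variable":
                denom = 1.0 - pinv
                if denom <= 0 or (real <= 0).any():
                    return -math.inf
                total += float(np.log(real).sum()) - C * math.log(denom)
            else:
                if (real <= 0).any():
                    return -math.inf
                total += float(np.log(real).sum())
        return total


def mk_log_likelihood(tree_with_lengths, matrix: CharacterMatrix, alpha: float,
                      coding: str = "variable", *, n_rate_categories: int = 4,
                      char_ids: Optional[Sequence[int]] = None) -> float:
    """Mk(v)+Γ log likelihood of the discrete characters on a given tree."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    ti = tree_with_lengths if isinstance(tree_with_lengths, TreeIndex) \
        else TreeIndex.from_dendropy(tree_with_lengths)
    lengths = ti.lengths or []
    for v in range(ti.n_nodes):
        if v != ti.root and (lengths[v] is None or lengths[v] <= 0):
            raise ValueError("every branch needs a positive length")
    engine = MkEngine(matrix, char_ids=char_ids,
                      n_rate_categories=n_rate_categories, coding=coding)
    return engine.loglik(_Topo.from_tree_index(ti), alpha)


# ---------------------------------------------------------------------------
# Exhaustive parsimony attachment scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttachmentScore:
    branch: int            # backbone node id; the branch is the edge above it
    tips_below: frozenset  # tip labels subtended by the branch
    added_steps: float


def attach_parsimony_scan(fossil: str, matrix: CharacterMatrix, tree, *,
                          char_ids: Optional[Sequence[int]] = None
                          ) -> Tuple[List[AttachmentScore], bool]:
    """Added parsimony steps of attaching `fossil` to each backbone branch.

    Returns the ascending ranking (ties broken by the branch's postorder
    index) and a flag that is True when the fossil row is entirely unscored
    (all branches then tie trivially).
    """
    ti = tree if isinstance(tree, TreeIndex) else TreeIndex.from_dendropy(tree)
    row = {d.char_id: c for d, c in zip(matrix.definitions, matrix.row(fossil))}
    added = np.zeros(len(ti.edge_nodes))
    informative = False
    for d in matrix.definitions:
        if d.kind != "discrete":
            continue
        if char_ids is not None and d.char_id not in char_ids:
            continue
        cell = row[d.char_id]
        column = {t: c for t, c in matrix.column(d.char_id).items()
                  if t in ti.leaf_of}
        cost = ordered_cost(d.n_states) if d.ordered else unit_cost(d.n_states)
        tip_sets = _column_tip_sets(ti, column, d.n_states)
        down, M = _sankoff_down(ti, tip_sets, cost)
        up = _sankoff_up(ti, down, M, cost)
        base = float(np.min(down[ti.root]))
        if cell is MISSING or cell is INAPPLICABLE:
            continue
        informative = True
        fossil_cost = np.min(cost[:, sorted(cell)], axis=1)
        for idx, v in enumerate(ti.edge_nodes):
            p = ti.parent[v]
            down_e = np.min(cost + down[v][None, :], axis=1)
            rest = up[p] + down[p] - M[v]
            up_e = np.min(cost + rest[None, :], axis=1)
            total = float(np.min(down_e + up_e + fossil_cost))
            added[idx] += total - base
    scores = [
        AttachmentScore(branch=v, tips_below=ti.tipset(v),
                        added_steps=float(round(added[i], 9)))
        for i, v in enumerate(ti.edge_nodes)
    ]
    scores.sort(key=lambda s: (s.added_steps, ti.edge_nodes.index(s.branch)))
    return scores, not informative


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Attachment:
    host: tuple      # ('b', backbone node id) or ('f', fossil index)
    frac: float      # position along the host branch, 0 = child end
    pendant: float   # pendant branch length to the fossil tip


@dataclass
class PosteriorSample:
    run: int
    generation: int
    attachments: Dict[str, Attachment]
    alpha: float
    log_posterior: float


@dataclass
class McmcResult:
    samples: List[PosteriorSample]
    backbone: TreeIndex
    fossils: List[str]
    acceptance: Dict[str, float]
    n_generations: int
    config: MkModelConfig


class _Chain:
    __slots__ = ("edge_len", "pendants", "hosts", "fracs", "alpha", "ll", "lp")

    def __init__(self, edge_len, pendants, hosts, fracs, alpha):
        self.edge_len = edge_len      # array over backbone nodes (root unused)
        self.pendants = pendants
        self.hosts = hosts            # list of ('b', node) / ('f', j)
        self.fracs = fracs
        self.alpha = alpha
        self.ll = None
        self.lp = None

    def copy_params(self):
        return (self.edge_len.copy(), self.pendants.copy(), list(self.hosts),
                self.fracs.copy(), self.alpha)


def _has_cycle(hosts, i) -> bool:
    seen = {i}
    htype, h = hosts[i]
    while htype == "f":
        if h in seen:
            return True
        seen.add(h)
        htype, h = hosts[h]
    return False


def _build_placed_topo(bt: TreeIndex, fossils: List[str], hosts, fracs,
                       pendants, edge_len) -> _Topo:
    n, F = bt.n_nodes, len(fossils)
    size = n + 2 * F
    parent = [-1] * size
    length = [0.0] * size
    children: List[List[int]] = [[] for _ in range(size)]
    attach = lambda i: n + i
    tipid = lambda i: n + F + i

    on = defaultdict(list)
    for i in range(F):
        on[tuple(hosts[i])].append((fracs[i], i))

    def lay_edge(child_end: int, parent_end: int, L: float, key) -> None:
        prev, pos = child_end, 0.0
        for t, i in sorted(on.get(key, ())):
            parent[prev] = attach(i)
            length[prev] = max((t - pos) * L, 0.0)
            prev, pos = attach(i), t
        parent[prev] = parent_end
        length[prev] = max((1.0 - pos) * L, 0.0)

    for v in bt.edge_nodes:
        lay_edge(v, bt.parent[v], float(edge_len[v]), ("b", v))
    for i in range(F):
        lay_edge(tipid(i), attach(i), float(pendants[i]), ("f", i))

    for v in range(size):
        if parent[v] != -1:
            children[parent[v]].append(v)
    leaf_taxon = {v: bt.labels[v] for v in bt.leaves}
    leaf_taxon.update({tipid(i): fossils[i] for i in range(F)})
    return _Topo(parent, children, length, leaf_taxon)


def run_mcmc(matrix: CharacterMatrix, scaffold: ScaffoldTree,
             config: MkModelConfig) -> McmcResult:
    """Sample fossil attachments, branch lengths and the gamma shape."""
    fossils = scaffold.floating_fossils()
    if not fossils:
        raise ValueError("no floating fossils to place")
    for f in fossils:
        matrix.taxon_index(f)
    bt = TreeIndex.from_dendropy(scaffold.tree)
    for label in bt.leaf_of:
        matrix.taxon_index(label)
    engine = MkEngine(matrix, n_rate_categories=config.n_rate_categories,
                      coding=config.coding)

    lam = config.branch_length_prior_rate
    lam_a = config.alpha_prior_rate
    F = len(fossils)
    n_edges = len(bt.edge_nodes)
    betas = [1.0 / (1.0 + j * config.heat_temperature)
             for j in range(config.chains_per_run)]

    def log_prior(ch: _Chain) -> float:
        bl = ch.edge_len[bt.edge_nodes]
        return (n_edges * math.log(lam) - lam * float(bl.sum())
                + F * math.log(lam) - lam * float(ch.pendants.sum())
                + math.log(lam_a) - lam_a * ch.alpha)

    def log_lik(ch: _Chain) -> float:
        topo = _build_placed_topo(bt, fossils, ch.hosts, ch.fracs,
                                  ch.pendants, ch.edge_len)
        return engine.loglik(topo, ch.alpha)

    def eligible_hosts(i: int) -> list:
        hosts = [("b", v) for v in bt.edge_nodes]
        hosts += [("f", j) for j in range(F) if j != i]
        return hosts

    all_samples: List[PosteriorSample] = []
    accepted = defaultdict(int)
    proposed = defaultdict(int)
    mw = np.asarray(config.move_weights, dtype=float)
    mw = mw / mw.sum()

    for run in range(config.runs):
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, run])
        chains: List[_Chain] = []
        for _ in range(config.chains_per_run):
            edge_len = np.zeros(bt.n_nodes)
            edge_len[bt.edge_nodes] = rng.exponential(1.0 / lam, size=n_edges)
            pendants = rng.exponential(1.0 / lam, size=F)
            hosts = []
            for i in range(F):
                opts = eligible_hosts(i)
                hosts.append(opts[rng.integers(len(opts))])
                if _has_cycle(hosts + [("b", bt.edge_nodes[0])] * (F - i - 1), i):
                    hosts[i] = ("b", bt.edge_nodes[rng.integers(n_edges)])
            fracs = rng.uniform(size=F)
            alpha = float(rng.exponential(1.0 / lam_a)) + 1e-3
            ch = _Chain(edge_len, pendants, hosts, fracs, alpha)
            ch.ll, ch.lp = log_lik(ch), log_prior(ch)
            chains.append(ch)

        run_samples: List[PosteriorSample] = []
        for gen in range(1, config.generations + 1):
            for j, ch in enumerate(chains):
                beta = betas[j]
                u = rng.random()
                move = 0 if u < mw[0] else (1 if u < mw[0] + mw[1] else 2)
                old = ch.copy_params()
                old_ll, old_lp = ch.ll, ch.lp
                log_hastings = 0.0
                name = ("reattach", "length", "alpha")[move]
                proposed[name] += 1
                if move == 0:
                    i = int(rng.integers(F))
                    opts = eligible_hosts(i)
                    ch.hosts[i] = opts[int(rng.integers(len(opts)))]
                    ch.fracs[i] = float(rng.uniform())
                    new_p = float(rng.exponential(1.0 / lam))
                    log_hastings = lam * (new_p - ch.pendants[i])
                    ch.pendants[i] = new_p
                    if _has_cycle(ch.hosts, i):
                        (ch.edge_len, ch.pendants, ch.hosts,
                         ch.fracs, ch.alpha) = old
                        continue
                elif move == 1:
                    idx = int(rng.integers(n_edges + F))
                    m = math.exp(1.4 * (rng.random() - 0.5))
                    if idx < n_edges:
                        ch.edge_len[bt.edge_nodes[idx]] *= m
                    else:
                        ch.pendants[idx - n_edges] *= m
                    log_hastings = math.log(m)
                else:
                    m = math.exp(0.7 * (rng.random() - 0.5))
                    ch.alpha *= m
                    log_hastings = math.log(m)
                    if not 1e-3 <= ch.alpha <= 1e3:
                        (ch.edge_len, ch.pendants, ch.hosts,
                         ch.fracs, ch.alpha) = old
                        continue
                new_ll, new_lp = log_lik(ch), log_prior(ch)
                log_acc = beta * ((new_ll + new_lp) - (old_ll + old_lp)) \
                    + log_hastings
                if math.log(rng.random() + 1e-300) < log_acc:
                    ch.ll, ch.lp = new_ll, new_lp
                    accepted[name] += 1
                else:
                    (ch.edge_len, ch.pendants, ch.hosts,
                     ch.fracs, ch.alpha) = old
                    ch.ll, ch.lp = old_ll, old_lp
            if len(chains) > 1:
                j = int(rng.integers(len(chains) - 1))
                a, b = chains[j], chains[j + 1]
                d = (betas[j] - betas[j + 1]) * ((b.ll + b.lp) - (a.ll + a.lp))
                proposed["swap"] += 1
                if math.log(rng.random() + 1e-300) < d:
                    chains[j], chains[j + 1] = b, a
                    accepted["swap"] += 1
            if gen % config.sample_every == 0:
                cold = chains[0]
                run_samples.append(PosteriorSample(
                    run=run, generation=gen,
                    attachments={
                        fossils[i]: Attachment(host=tuple(cold.hosts[i]),
                                               frac=float(cold.fracs[i]),
                                               pendant=float(cold.pendants[i]))
                        for i in range(F)
                    },
                    alpha=cold.alpha,
                    log_posterior=cold.ll + cold.lp,
                ))
        burn = int(config.burnin_fraction * len(run_samples))
        all_samples.extend(run_samples[burn:])

    rates = {k: accepted[k] / max(proposed[k], 1) for k in proposed}
    return McmcResult(samples=all_samples, backbone=bt, fossils=fossils,
                      acceptance=rates, n_generations=config.generations,
                      config=config)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class PlacementSummary:
    fossil: str
    branch_posterior: Dict[int, float]   # backbone node id -> frequency
    clade_bpp: Dict[Tuple[str, str], float]  # (clade, 'crown'|'total') -> BPP


@dataclass
class SummaryResult:
    summaries: Dict[str, PlacementSummary]
    consensus: dendropy.Tree
    split_frequencies: Dict[frozenset, float]
    asdsf: Optional[float]
    group_bpp: Dict[str, float] = field(default_factory=dict)


def _resolve_backbone_edge(attachments: Dict[str, Attachment],
                           fossils: List[str], i: int) -> int:
    htype, h = attachments[fossils[i]].host
    while htype == "f":
        htype, h = attachments[fossils[h]].host
    return h


def _strict_descendants(bt: TreeIndex, node: int) -> frozenset:
    out, stack = [], list(bt.children[node])
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(bt.children[v])
    return frozenset(out)


def summarise(result: McmcResult, scaffold: ScaffoldTree, *,
              clades: Optional[Sequence[str]] = None,
              groups: Optional[Dict[str, Tuple[Sequence[str], str, str]]] = None,
              max_consensus_trees: int = 500) -> SummaryResult:
    """Branch posteriors, crown/total clade BPPs, majority-rule consensus.

    groups maps a label to (fossil names, clade name, 'crown'|'total'); its
    BPP is the fraction of samples in which every listed fossil is a member.
    """
    samples = result.samples
    if not samples:
        raise ValueError("no post-burn-in samples to summarise")
    bt = result.backbone
    fossils = result.fossils
    clade_names = list(clades) if clades is not None else sorted(scaffold.clades)

    crown_desc: Dict[str, frozenset] = {}
    mrca_of: Dict[str, int] = {}
    for name in clade_names:
        m = bt.mrca(sorted(scaffold.clades[name].tips))
        mrca_of[name] = m
        crown_desc[name] = _strict_descendants(bt, m)

    branch_counts = {f: defaultdict(int) for f in fossils}
    member_counts = {f: defaultdict(int) for f in fossils}
    group_counts = defaultdict(int)
    for s in samples:
        resolved = {f: _resolve_backbone_edge(s.attachments, fossils, i)
                    for i, f in enumerate(fossils)}
        in_clade = {}
        for f, v in resolved.items():
            branch_counts[f][v] += 1
            for name in clade_names:
                crown = v in crown_desc[name]
                total = crown or v == mrca_of[name]
                in_clade[(f, name)] = (crown, total)
                if crown:
                    member_counts[f][(name, "crown")] += 1
                if total:
                    member_counts[f][(name, "total")] += 1
        if groups:
            for label, (gfossils, cname, concept) in groups.items():
                which = 0 if concept == "crown" else 1
                if all(in_clade[(f, cname)][which] for f in gfossils):
                    group_counts[label] += 1

    N = len(samples)
    summaries = {
        f: PlacementSummary(
            fossil=f,
            branch_posterior={v: c / N for v, c in sorted(branch_counts[f].items())},
            clade_bpp={k: c / N for k, c in sorted(member_counts[f].items())},
        )
        for f in fossils
    }
    group_bpp = {k: c / N for k, c in group_counts.items()}

    # consensus over (possibly thinned) placed trees
    stride = max(1, math.ceil(N / max_consensus_trees))
    used = samples[::stride]
    split_counts: Dict[frozenset, float] = defaultdict(float)
    run_split_counts: Dict[int, Dict[frozenset, float]] = defaultdict(
        lambda: defaultdict(float))
    run_sizes = defaultdict(int)
    newicks = []
    for s in used:
        topo = _build_placed_topo(
            bt, fossils,
            [s.attachments[f].host for f in fossils],
            np.array([s.attachments[f].frac for f in fossils]),
            np.array([s.attachments[f].pendant for f in fossils]),
            _edge_len_placeholder(bt),
        )
        newicks.append(_topo_newick(topo))
        run_sizes[s.run] += 1
        for split in _topo_splits(topo):
            split_counts[split] += 1
            run_split_counts[s.run][split] += 1
    n_used = len(used)
    split_freq = {sp: c / n_used for sp, c in split_counts.items()}

    asdsf = None
    if len(run_sizes) > 1:
        freqs = []
        keep = {sp for sp, f in split_freq.items() if f > 0.1}
        for sp in keep:
            per_run = [run_split_counts[r][sp] / run_sizes[r] for r in run_sizes]
            freqs.append(float(np.std(per_run)))
        asdsf = float(np.mean(freqs)) if freqs else 0.0

    tns = dendropy.TaxonNamespace()
    tree_list = dendropy.TreeList.get(data="\n".join(t + ";" for t in newicks),
                                      schema="newick", taxon_namespace=tns,
                                      rooting="force-rooted",
                                      preserve_underscores=True)
    consensus = tree_list.consensus(min_freq=0.5)
    consensus.is_rooted = True
    all_tips = frozenset(l.taxon.label for l in consensus.leaf_node_iter())
    for node in consensus.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if below != all_tips:
            node.label = f"{split_freq.get(below, 1.0):.3f}"
    return SummaryResult(summaries=summaries, consensus=consensus,
                         split_frequencies=split_freq, asdsf=asdsf,
                         group_bpp=group_bpp)


def _edge_len_placeholder(bt: TreeIndex) -> np.ndarray:
    out = np.ones(bt.n_nodes)
    return out


def _topo_splits(topo: _Topo) -> List[frozenset]:
    below: Dict[int, frozenset] = {}
    splits = []
    all_tips = frozenset(topo.leaf_taxon.values())
    for v in topo.postorder:
        if not topo.children[v]:
            below[v] = frozenset([topo.leaf_taxon[v]])
        else:
            acc = frozenset()
            for c in topo.children[v]:
                acc |= below[c]
            below[v] = acc
            if 1 < len(acc) < len(all_tips):
                splits.append(acc)
    return splits


def _topo_newick(topo: _Topo) -> str:
    def render(v: int) -> str:
        if not topo.children[v]:
            label = topo.leaf_taxon[v].replace(" ", "_")
            return f"{label}:{topo.length[v]:.6g}"
        inner = ",".join(render(c) for c in topo.children[v])
        if v == topo.root:
            return f"({inner})"
        return f"({inner}):{topo.length[v]:.6g}"

    return render(topo.root)
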