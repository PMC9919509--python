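"""Synthetic character matrices with the structure the pipeline assumes.

The generator emulates a morphological matrix scored on a fixed phylogenomic
backbone: discrete characters evolving under Mk (ordered characters under a
nearest-neighbour stepping-stone walk) with lognormal rate heterogeneity,
"planted" characters that change state exactly once on a named clade's stem
branch (perfect unreversed synapomorphies when their background rate is
zero), continuous ratio characters under Brownian motion, and fragmentary
fossil rows simulated from a known attachment branch and masked to a stated
missingness.  Simulated trees are scaled to total edge length 1, so a
character's rate is its expected number of changes across the whole tree.

Everything is seeded; a fixed seed reproduces the output byte for byte.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .io_formats import MISSING, CharacterDefinition, CharacterMatrix
from .parsimony import TreeIndex
from .scaffold import CladeDefinition, ScaffoldTree, build_scaffold


@dataclass(frozen=True)
class PlantedEvent:
    clade: str
    char_id: int
    derived_state: int = 1


@dataclass(frozen=True)
class FossilSpec:
    name: str
    branch_tips: frozenset      # the attachment branch = edge above MRCA(tips)
    missing_fraction: float = 0.6
    pendant_length: float = 0.02

    def __post_init__(self):
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must lie in [0, 1]")


@dataclass
class SimulationConfig:
    tree: ScaffoldTree
    n_chars: int = 49
    n_continuous: int = 5
    state_counts: Sequence[int] = ()        # per discrete char; default drawn 2-4
    ordered_fraction: float = 0.2           # of multistate characters
    rate_lognorm: Tuple[float, float] = (np.log(6.0), 0.6)  # changes per tree
    rate_scale: float = 1.0                 # global multiplier (0 freezes all)
    planted: Sequence[PlantedEvent] = ()
    homoplasy_boost: float = 1.0            # rate multiplier for boosted chars
    boosted_chars: Sequence[int] = ()
    brownian_sigma2: float = 1.0
    fossil_specs: Sequence[FossilSpec] = ()
    seed: int = 0


@dataclass
class SimulationTruth:
    tree_index: TreeIndex
    node_states: Dict[int, np.ndarray]      # discrete char_id -> state per node
    node_values: Dict[int, np.ndarray]      # continuous char_id -> value per node
    changes: Dict[int, list]                # char_id -> [(node, from, to), ...]
    rates: Dict[int, float]
    planted: Dict[int, PlantedEvent]
    fossil_attachments: Dict[str, frozenset] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scaffold generation
# ---------------------------------------------------------------------------

def simulate_scaffold(n_extant: int, seed: int, *, min_clade_size: int = 4,
                      max_clades: int = 12) -> ScaffoldTree:
    """Birth-death backbone scaled to total length 1, with named clades.

    Clades are registered for every internal node subtending between
    ``min_clade_size`` and half of the tips, largest first, up to
    ``max_clades`` (nested clades are allowed, as in real classifications).
    """
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_extant,
        rng=_pyrandom.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1:03d}"
    total = sum(e.length or 0.0 for e in tree.edges() if e.head_node.parent_node)
    for e in tree.edges():
        if e.length is not None:
            e.length = e.length / total
    sc = build_scaffold(tree)
    ti = TreeIndex.from_dendropy(tree)
    candidates = []
    for v in ti.postorder:
        if ti.children[v] and v != ti.root:
            tips = ti.tipset(v)
            if min_clade_size <= len(tips) <= n_extant // 2:
                candidates.append((len(tips), sorted(tips)[0], tips))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    for i, (_, _, tips) in enumerate(candidates[:max_clades]):
        sc.register_clade(CladeDefinition(name=f"clade_{i + 1:02d}", tips=tips))
    return sc


# ---------------------------------------------------------------------------
# Character simulation
# ---------------------------------------------------------------------------

def _evolve_discrete(state: int, length: float, rate: float, k: int,
                     ordered: bool, rng: np.random.Generator,
                     events: Optional[list] = None, node: int = -1) -> int:
    n_events = rng.poisson(rate * length)
    for _ in range(n_events):
        if ordered:
            if state == 0:
                new = 1
            elif state == k - 1:
                new = k - 2
            else:
                new = state + (1 if rng.random() < 0.5 else -1)
        else:
            new = int(rng.integers(k - 1))
            if new >= state:
                new += 1
        if events is not None:
            events.append((node, state, new))
        state = new
    return state


def simulate_matrix(config: SimulationConfig) -> Tuple[CharacterMatrix, SimulationTruth]:
    """Evolve a character matrix for the scaffold's extant taxa."""
    rng = np.random.default_rng(config.seed)
    sc = config.tree
    ti = TreeIndex.from_dendropy(sc.tree)
    n_disc = config.n_chars
    n_cont = config.n_continuous

    planted = {e.char_id: e for e in config.planted}
    for e in planted.values():
        if e.clade not in sc.clades:
            raise ValueError(f"planted event names unregistered clade {e.clade!r}")
        if not n_cont < e.char_id <= n_cont + n_disc:
            raise ValueError(f"planted char {e.char_id} is not a discrete character")

    if config.state_counts:
        if len(config.state_counts) != n_disc:
            raise ValueError("state_counts must match n_chars")
        kvec = list(config.state_counts)
    else:
        kvec = [int(rng.integers(2, 5)) for _ in range(n_disc)]

    definitions: List[CharacterDefinition] = []
    for j in range(n_cont):
        definitions.append(CharacterDefinition(char_id=j + 1, kind="continuous",
                                               n_states=0))
    multistate = [j for j, k in enumerate(kvec) if k >= 3]
    n_ordered = int(round(config.ordered_fraction * len(multistate)))
    ordered_js = set(
        rng.choice(multistate, size=n_ordered, replace=False).tolist()
    ) if n_ordered else set()
    for j, k in enumerate(kvec):
        definitions.append(CharacterDefinition(
            char_id=n_cont + j + 1, kind="discrete", n_states=k,
            ordered=j in ordered_js,
        ))

    mu, sigma = config.rate_lognorm
    node_states: Dict[int, np.ndarray] = {}
    node_values: Dict[int, np.ndarray] = {}
    changes: Dict[int, list] = {}
    rates: Dict[int, float] = {}

    mrca_of = {name: ti.mrca(sorted(c.tips)) for name, c in sc.clades.items()}

    for d in definitions:
        cid = d.char_id
        if d.kind == "continuous":
            vals = np.zeros(ti.n_nodes)
            for v in ti.preorder:
                if v == ti.root:
                    vals[v] = 0.0
                else:
                    L = ti.lengths[v]
                    vals[v] = vals[ti.parent[v]] + rng.normal(
                        0.0, np.sqrt(config.brownian_sigma2 * max(L, 0.0)))
            node_values[cid] = vals
            rates[cid] = 0.0
            changes[cid] = []
            continue
        k = d.n_states
        ev: list = []
        states = np.zeros(ti.n_nodes, dtype=int)
        if cid in planted:
            event = planted[cid]
            rate = 0.0
            target = mrca_of[event.clade]
            for v in ti.preorder:
                if v == ti.root:
                    states[v] = 0
                elif v == target:
                    states[v] = event.derived_state
                    ev.append((v, states[ti.parent[v]], event.derived_state))
                else:
                    states[v] = states[ti.parent[v]]
        else:
            rate = float(rng.lognormal(mu, sigma)) * config.rate_scale
            if cid in set(config.boosted_chars):
                rate *= config.homoplasy_boost
            for v in ti.preorder:
                if v == ti.root:
                    states[v] = int(rng.integers(k))
                else:
                    states[v] = _evolve_discrete(
                        states[ti.parent[v]], ti.lengths[v], rate, k,
                        d.ordered, rng, ev, v)
        node_states[cid] = states
        changes[cid] = ev
        rates[cid] = rate

    taxa = sorted(ti.leaf_of)
    cells = []
    for t in taxa:
        v = ti.leaf_of[t]
        row: list = []
        for d in definitions:
            if d.kind == "continuous":
                row.append(float(node_values[d.char_id][v]))
            else:
                row.append(frozenset({int(node_states[d.char_id][v])}))
        cells.append(row)
    matrix = CharacterMatrix(taxa=taxa, definitions=definitions, cells=cells)
    truth = SimulationTruth(tree_index=ti, node_states=node_states,
                            node_values=node_values, changes=changes,
                            rates=rates, planted=planted)
    return matrix, truth


# ---------------------------------------------------------------------------
# Fossils
# ---------------------------------------------------------------------------

def make_fossil(matrix: CharacterMatrix, truth: SimulationTruth,
                spec: FossilSpec, seed: int) -> Tuple[list, frozenset]:
    """Simulate one fossil row from a known branch; mask cells to MISSING.

    The fossil evolves from the attachment branch's child-end states along
    its pendant length, then a seeded uniform subset of cells of the stated
    fraction is masked.  Returns (row, attachment branch tip set).
    """
    rng = np.random.default_rng(seed)
    ti = truth.tree_index
    node = ti.mrca(sorted(spec.branch_tips)) if len(spec.branch_tips) > 1 \
        else ti.leaf_of[next(iter(spec.branch_tips))]
    if node == ti.root:
        raise ValueError("cannot attach a fossil above the root")
    row: list = []
    for d in matrix.definitions:
        cid = d.char_id
        if d.kind == "continuous":
            val = truth.node_values[cid][node] + rng.normal(
                0.0, np.sqrt(spec.pendant_length))
            row.append(float(val))
        else:
            state = _evolve_discrete(
                int(truth.node_states[cid][node]), spec.pendant_length,
                truth.rates[cid], d.n_states, d.ordered, rng)
            row.append(frozenset({state}))
    n_mask = int(round(spec.missing_fraction * len(row)))
    for idx in rng.choice(len(row), size=n_mask, replace=False):
        row[idx] = MISSING
    return row, ti.tipset(node)


def add_fossils(matrix: CharacterMatrix, truth: SimulationTruth,
                specs: Sequence[FossilSpec], seed: int) -> CharacterMatrix:
    """Append simulated fossil rows; true attachments recorded in `truth`."""
    taxa = list(matrix.taxa)
    cells = [list(r) for r in matrix.cells]
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 17])
    child_seeds = ss.generate_state(len(specs))
    for spec, s in zip(specs, child_seeds):
        row, attach = make_fossil(matrix, truth, spec, int(s) & 0x7FFFFFFF)
        taxa.append(spec.name)
        cells.append(row)
        truth.fossil_attachments[spec.name] = attach
    return CharacterMatrix(taxa=taxa, definitions=list(matrix.definitions),
                           cells=cells)


# ---------------------------------------------------------------------------
# Ready-made fixtures
# ---------------------------------------------------------------------------

def default_study_fixture(seed: int = 0, *, n_extant: int = 142,
                          n_discrete: int = 49, n_continuous: int = 5,
                          n_planted: int = 10, n_fossils: int = 11
                          ) -> Tuple[ScaffoldTree, CharacterMatrix, SimulationTruth]:
    """Study-scale synthetic fixture: backbone, matrix, planted markers, fossils.

    142 extant tips, 49 discrete + 5 continuous characters, ~20% of
    multistate characters ordered, 10 planted single-origin clade markers
    with zero background rate, and 11 fossil rows at 40-80% missingness.
    """
    sc = simulate_scaffold(n_extant, seed)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 5])
    clade_names = sorted(sc.clades)
    planted = []
    for i in range(n_planted):
        clade = clade_names[i % len(clade_names)]
        planted.append(PlantedEvent(clade=clade,
                                    char_id=n_continuous + 1 + i,
                                    derived_state=1))
    config = SimulationConfig(tree=sc, n_chars=n_discrete,
                              n_continuous=n_continuous,
                              planted=planted, seed=seed)
    matrix, truth = simulate_matrix(config)
    ti = truth.tree_index
    internal = [v for v in ti.postorder
                if ti.children[v] and v != ti.root]
    specs = []
    for i in range(n_fossils):
        v = internal[int(rng.integers(len(internal)))]
        specs.append(FossilSpec(
            name=f"fossil_{i + 1:02d}", branch_tips=ti.tipset(v),
            missing_fraction=float(rng.uniform(0.4, 0.8)),
        ))
    matrix = add_fossils(matrix, truth, specs, seed)
    for spec in specs:
        sc.tip_status[spec.name] = "floating"
    return sc, matrix, truth
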