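"""Fixed molecular scaffold: backbone tips, named clades, fossil status.

The backbone topology (extant taxa, plus any fossil hard-constrained to a
fixed position such as a stem taxon sister to the crown clade) is input and
never inferred here.  Floating fossils are listed but absent from the tree
until the placement module attaches them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, NamedTuple, Optional

import dendropy

BACKBONE = "backbone"
CONSTRAINED_SISTER = "constrained_sister"
FLOATING = "floating"


@dataclass(frozen=True)
class CladeDefinition:
    """A named clade given as its set of backbone tips."""

    name: str
    tips: frozenset
    concept: str = "crown"  # "crown" | "total"

    def __post_init__(self):
        if self.concept not in ("crown", "total"):
            raise ValueError(f"clade {self.name!r}: unknown concept {self.concept!r}")
        if not self.tips:
            raise ValueError(f"clade {self.name!r}: empty tip set")


class SisterResult(NamedTuple):
    nodes: tuple  # one node when the parent bifurcates, several in a polytomy
    ambiguous: bool


class Membership(NamedTuple):
    crown: bool
    total: bool


@dataclass
class ScaffoldTree:
    """Rooted scaffold + tip status map + clade registry."""

    tree: dendropy.Tree
    tip_status: Dict[str, str] = field(default_factory=dict)
    clades: Dict[str, CladeDefinition] = field(default_factory=dict)

    def __post_init__(self):
        tree_tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        for tip in tree_tips:
            self.tip_status.setdefault(tip, BACKBONE)
        for tip, status in self.tip_status.items():
            if status == FLOATING:
                if tip in tree_tips:
                    raise ValueError(
                        f"floating fossil {tip!r} must not appear in the scaffold tree"
                    )
            elif tip not in tree_tips:
                raise ValueError(f"{status} tip {tip!r} missing from the scaffold tree")
        for clade in self.clades.values():
            self._check_clade(clade)

    # -- registry --------------------------------------------------------
    def register_clade(self, clade: CladeDefinition) -> None:
        if clade.name in self.clades:
            raise ValueError(f"clade {clade.name!r} already registered")
        self._check_clade(clade)
        self.clades[clade.name] = clade

    def _check_clade(self, clade: CladeDefinition) -> None:
        backbone = self.backbone_taxa()
        missing = clade.tips - backbone
        if missing:
            raise ValueError(
                f"clade {clade.name!r}: tip(s) not on the backbone: "
                + ", ".join(sorted(missing))
            )
        if not self.is_monophyletic(clade.tips):
            raise ValueError(f"clade {clade.name!r} is not monophyletic on the backbone")

    def backbone_taxa(self) -> frozenset:
        return frozenset(
            t for t, s in self.tip_status.items() if s != FLOATING
        ) & frozenset(l.taxon.label for l in self.tree.leaf_node_iter())

    def extant_taxa(self) -> frozenset:
        return frozenset(t for t, s in self.tip_status.items() if s == BACKBONE)

    def floating_fossils(self) -> list:
        return sorted(t for t, s in self.tip_status.items() if s == FLOATING)

    # -- tree queries ----------------------------------------------------
    def mrca(self, clade, tree: Optional[dendropy.Tree] = None) -> dendropy.Node:
        """Most recent common ancestor of a clade (or explicit tip set)."""
        tree = tree or self.tree
        if isinstance(clade, CladeDefinition):
            tips = clade.tips
        elif isinstance(clade, str):
            tips = self.clades[clade].tips
        else:
            tips = frozenset(clade)
        return _mrca_of(tree, tips)

    def sister_node(self, node: dendropy.Node,
                    tree: Optional[dendropy.Tree] = None) -> SisterResult:
        tree = tree or self.tree
        if node.parent_node is None:
            raise ValueError("the root has no sister")
        siblings = tuple(c for c in node.parent_node.child_nodes() if c is not node)
        return SisterResult(nodes=siblings, ambiguous=len(siblings) > 1)

    def is_monophyletic(self, tips: Iterable, tree: Optional[dendropy.Tree] = None,
                        among: Optional[frozenset] = None) -> bool:
        tree = tree or self.tree
        tips = frozenset(tips)
        node = _mrca_of(tree, tips)
        among = among if among is not None else self.backbone_taxa()
        below = {
            l.taxon.label for l in node.leaf_iter() if l.taxon.label in among
        }
        return below == tips

    def membership(self, fossil_tip: str, placed_tree: dendropy.Tree,
                   clade) -> Membership:
        """Crown/total clade membership of a fossil in a placed tree.

        Crown: the fossil descends from the clade's crown MRCA.  Total adds
        attachment to the clade's stem branch: the least clade containing the
        clade tips plus the fossil holds no other backbone tip.
        """
        if isinstance(clade, str):
            if clade not in self.clades:
                raise KeyError(f"clade {clade!r} not registered")
            clade = self.clades[clade]
        placed_tips = {l.taxon.label for l in placed_tree.leaf_node_iter()}
        if fossil_tip not in placed_tips:
            raise ValueError(f"fossil {fossil_tip!r} not attached in the placed tree")
        backbone = self.backbone_taxa()
        crown_node = _mrca_of(placed_tree, clade.tips)
        crown = fossil_tip in {l.taxon.label for l in crown_node.leaf_iter()}
        if crown:
            return Membership(crown=True, total=True)
        stem_node = _mrca_of(placed_tree, clade.tips | {fossil_tip})
        below = {l.taxon.label for l in stem_node.leaf_iter() if l.taxon.label in backbone}
        return Membership(crown=False, total=below == clade.tips)


def _mrca_of(tree: dendropy.Tree, tips: frozenset) -> dendropy.Node:
    leaf_map = {l.taxon.label: l for l in tree.leaf_node_iter()}
    missing = [t for t in tips if t not in leaf_map]
    if missing:
        raise ValueError("tip(s) not in tree: " + ", ".join(sorted(missing)))
    if len(tips) == 1:
        return leaf_map[next(iter(tips))]
    # walk up from one tip until all tips are covered
    target = frozenset(tips)
    node = leaf_map[next(iter(tips))]
    while node is not None:
        below = {l.taxon.label for l in node.leaf_iter()}
        if target <= below:
            return node
        node = node.parent_node
    raise RuntimeError("unreachable: root covers all tips")


def build_scaffold(tree: dendropy.Tree, *, extant: Iterable = (),
                   constrained: Iterable = (), floating: Iterable = (),
                   clades: Iterable = ()) -> ScaffoldTree:
    """Convenience constructor; unlisted tree tips default to backbone status."""
    status = {t: BACKBONE for t in extant}
    status.update({t: CONSTRAINED_SISTER for t in constrained})
    status.update({t: FLOATING for t in floating})
    sc = ScaffoldTree(tree=tree, tip_status=status)
    for c in clades:
        sc.register_clade(c)
    return sc
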