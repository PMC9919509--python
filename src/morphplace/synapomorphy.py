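"""Rule-based diagnosis of clade character states on the scaffold.

A derived state is an *unreversed synapomorphy* ('*') of a clade when it is
(i) ubiquitously present in all scored members of the clade, (ii) the sole
state reconstructed at the clade's ancestral node in every most-parsimonious
reconstruction, and (iii) absent from every MPR state set at the ancestral
node of the immediate sister clade.  States inherited from rootward nodes are
*retained plesiomorphies* ('§').  States failing only the node tests are kept
as 'ambiguous'; states present in all but a few listed members are kept as
near-ubiquitous diagnostics.  Every record carries the full audit of which
criteria passed, so any classification can be traced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .io_formats import INAPPLICABLE, MISSING, CharacterMatrix
from .parsimony import ParsimonyReconstruction, TreeIndex, count_state_origins
from .scaffold import CladeDefinition, ScaffoldTree

UNREVERSED = "unreversed_synapomorphy"
AMBIGUOUS = "ambiguous_not_synapomorphy"
PLESIOMORPHY = "retained_plesiomorphy"
NEAR_UBIQUITOUS = "near_ubiquitous_diagnostic"
HOMOPLASTIC = "homoplastic"
ABSENT = "absent"

GLYPH = {UNREVERSED: "*", PLESIOMORPHY: "§"}

#: presence fraction among scored members below which a non-ubiquitous state
#: is called homoplastic rather than a near-ubiquitous diagnostic
NEAR_UBIQUITY_THRESHOLD = 0.8


@dataclass
class SynapomorphyRecord:
    clade: str
    char_id: int
    state: int
    classification: str
    exceptions: tuple = ()
    min_origins: int = 0
    max_origins: int = 0
    notes: str = ""
    #: audit trail: criterion name -> bool (or None when not evaluable)
    criteria: dict = field(default_factory=dict)

    @property
    def glyph(self) -> str:
        return GLYPH.get(self.classification, "")


def _presence(cell, state: int, mode: str) -> Optional[bool]:
    """True/False presence of `state` in a cell; None when unscored."""
    if cell is MISSING or cell is INAPPLICABLE:
        return None
    if mode == "sole":
        return cell == frozenset({state})
    return state in cell


def classify_clade_state(clade, char_id: int, state: int,
                         recon: ParsimonyReconstruction,
                         matrix: CharacterMatrix, scaffold: ScaffoldTree, *,
                         presence_mode: str = "any",
                         sister_mode: str = "strict",
                         near_threshold: float = NEAR_UBIQUITY_THRESHOLD
                         ) -> SynapomorphyRecord:
    """Classify one (clade, character, state) triple against the criteria.

    presence_mode: 'any' counts a polymorphic cell containing the state as
    present (default); 'sole' requires the state to be the only one scored.
    sister_mode: 'strict' requires the state absent from the sister node's
    MPR set in every MPR; 'soft' only requires it not be the sole state.
    """
    if isinstance(clade, str):
        clade = scaffold.clades[clade]
    if recon.kind != "discrete":
        raise ValueError("synapomorphy diagnosis applies to discrete characters")
    ti: TreeIndex = recon.tree
    notes: List[str] = []

    column = matrix.column(char_id)
    members = sorted(t for t in clade.tips if t in ti.leaf_of)
    presences = {t: _presence(column[t], state, presence_mode) for t in members}
    unscored = tuple(t for t, p in presences.items() if p is None)
    scored = {t: p for t, p in presences.items() if p is not None}
    exceptions = tuple(t for t, p in scored.items() if not p)
    n_present = sum(scored.values())
    if unscored:
        notes.append("unscored members: " + ", ".join(unscored))

    criteria: Dict[str, Optional[bool]] = {}
    criteria["ubiquitous"] = bool(scored) and not exceptions

    mrca = ti.mrca(members)
    mrca_set = recon.node_mpr[mrca]
    criteria["mrca_unambiguous"] = mrca_set == frozenset({state})

    if mrca == ti.root:
        criteria["sister_absent"] = None
        notes.append("clade spans the root: sister criterion not evaluable")
    else:
        siblings = [c for c in ti.children[ti.parent[mrca]] if c != mrca]
        if len(siblings) > 1:
            notes.append("sister ambiguous (polytomy): criterion must hold "
                         "for every co-child")
        if sister_mode == "strict":
            ok = all(state not in recon.node_mpr[s] for s in siblings)
        else:
            ok = all(recon.node_mpr[s] != frozenset({state}) for s in siblings)
        criteria["sister_absent"] = ok

    parent = ti.parent[mrca]
    criteria["parent_unambiguous_same"] = (
        parent != -1 and recon.node_mpr[parent] == frozenset({state})
    )

    if not scored or n_present == 0:
        classification = ABSENT
    elif criteria["ubiquitous"]:
        # retention first: a state inherited unchanged from the parent node
        # cannot originate on the clade's stem, however derived the sister is
        if criteria["mrca_unambiguous"] and criteria["parent_unambiguous_same"]:
            classification = PLESIOMORPHY
        elif criteria["mrca_unambiguous"] and criteria["sister_absent"] in (True, None):
            classification = UNREVERSED
        else:
            classification = AMBIGUOUS
            failed = [k for k, v in criteria.items()
                      if k in ("mrca_unambiguous", "sister_absent") and v is False]
            notes.append("failed: " + ", ".join(failed))
    elif n_present / len(scored) >= near_threshold:
        classification = NEAR_UBIQUITOUS
        notes.append(f"present in {n_present}/{len(scored)} scored members")
    else:
        classification = HOMOPLASTIC
        notes.append(f"present in {n_present}/{len(scored)} scored members")

    mn, mx = count_state_origins(recon, state)
    return SynapomorphyRecord(
        clade=clade.name, char_id=char_id, state=state,
        classification=classification, exceptions=exceptions,
        min_origins=mn, max_origins=mx, notes="; ".join(notes),
        criteria=criteria,
    )


def diagnose_clade(clade, recon_all: Dict[int, ParsimonyReconstruction],
                   matrix: CharacterMatrix, scaffold: ScaffoldTree,
                   **kwargs) -> List[SynapomorphyRecord]:
    """All diagnostic records for a clade, sorted by character then state.

    Records classified absent or homoplastic are dropped; everything the
    clade could be diagnosed by (unreversed synapomorphies, retained
    plesiomorphies, ambiguous candidates, near-ubiquitous states) is kept.
    """
    if isinstance(clade, str):
        clade = scaffold.clades[clade]
    records = []
    for d in matrix.definitions:
        if d.kind != "discrete" or d.char_id not in recon_all:
            continue
        for state in range(d.n_states):
            rec = classify_clade_state(clade, d.char_id, state,
                                       recon_all[d.char_id], matrix, scaffold,
                                       **kwargs)
            if rec.classification not in (ABSENT, HOMOPLASTIC):
                records.append(rec)
    records.sort(key=lambda r: (r.char_id, r.state))
    return records


def unique_synapomorphy_scan(recon_all: Dict[int, ParsimonyReconstruction],
                             matrix: CharacterMatrix, scaffold: ScaffoldTree, *,
                             clades: Optional[List[str]] = None,
                             **kwargs) -> List[SynapomorphyRecord]:
    """Unreversed synapomorphies that are also tree-wide unique.

    Uniqueness means the state arises on exactly one branch in every MPR
    (min_origins = max_origins = 1), counted over the whole optimisation tree
    including outgroups.  May well be empty on homoplastic data.
    """
    names = clades if clades is not None else sorted(scaffold.clades)
    out = []
    for name in names:
        for rec in diagnose_clade(name, recon_all, matrix, scaffold, **kwargs):
            if (rec.classification == UNREVERSED
                    and rec.min_origins == 1 and rec.max_origins == 1):
                out.append(rec)
    return out
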