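"""Reliable-absence calling and Dollo-parsimony loss mapping.

The model: each gene family arises once on the species tree (single gain)
and may be lost any number of times, never regained. Given leaf states in
{present, absent, missing}, the minimal-loss reconstruction places the
origin at the most recent common ancestor of the present leaves and one
loss event on the stem of every maximal subtree that contains no present
leaf but at least one reliably absent one. Missing leaves are uninformative
(compatible with either state), so an all-missing subtree generates no loss
edge — the inferred count is a lower bound, matching the "lost at least N
times" reading of patchy genomic data.

Before mapping, raw absences pass a reliability filter: an absence is kept
only when every species of the same group (genus, or any configured tag
level) lacks the gene; a lone absence among present congeners is recoded as
missing information, since species-specific absence cannot be separated
from assembly/annotation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from .io import PresenceMatrix, State
from .tree import Node, TaxonTree


class ConfigurationError(ValueError):
    pass


class FamilyNeverObservedError(ValueError):
    """No PRESENT leaf: the family's origin cannot be placed."""


@dataclass
class ReliabilityConfig:
    """How absences are promoted to reliable losses.

    ``level``: the leaf-tag level defining "same genus and closely related
    species" (default ``genus``). ``min_group_size``: smallest group allowed
    to call a reliable absence (default 1, i.e. any group).
    """

    level: str = "genus"
    min_group_size: int = 1


@dataclass
class DolloResult:
    family: str
    origin: Node
    loss_edges: List[Node]  # child node identifies the edge
    node_states: Dict[int, str]  # nid -> "present" | "absent"

    @property
    def loss_count(self) -> int:
        return len(self.loss_edges)

    @property
    def loss_edge_labels(self) -> List[str]:
        return [n.name for n in self.loss_edges]


def apply_reliability_rule(
    matrix: PresenceMatrix, tree: TaxonTree, cfg: ReliabilityConfig
) -> PresenceMatrix:
    """Recode unreliable absences as MISSING.

    An ABSENT cell survives only if every leaf sharing its group tag is
    ABSENT for that family (and the group reaches ``min_group_size``);
    PRESENT and MISSING cells are unchanged.
    """
    groups: Dict[str, List[str]] = {}
    for taxon in matrix.taxa:
        tag = tree.tag_of(taxon, cfg.level)
        if tag is None:
            raise ConfigurationError(
                f"leaf {taxon!r} carries no {cfg.level!r} tag"
            )
        groups.setdefault(tag, []).append(taxon)
    out = matrix.copy()
    for family in matrix.families:
        col = matrix.column(family)
        for taxon in matrix.taxa:
            if col[taxon] is not State.ABSENT:
                continue
            members = groups[tree.tag_of(taxon, cfg.level)]
            reliable = len(members) >= cfg.min_group_size and all(
                col[m] is State.ABSENT for m in members
            )
            if not reliable:
                out.data.loc[taxon, family] = State.MISSING
    return out


def _subtree_summary(node: Node, states: Mapping[str, State]) -> Dict[int, tuple]:
    """Postorder (has_present, has_absent) per node id."""
    summary: Dict[int, tuple] = {}

    def visit(n: Node) -> tuple:
        if n.is_leaf:
            st = states.get(n.label, State.MISSING)
            res = (st is State.PRESENT, st is State.ABSENT)
        else:
            has_p = has_a = False
            for c in n.children:
                p, a = visit(c)
                has_p |= p
                has_a |= a
            res = (has_p, has_a)
        summary[n.nid] = res
        return res

    visit(node)
    return summary


def dollo_map(
    tree: TaxonTree, states: Mapping[str, State], family: str = "family"
) -> DolloResult:
    """Map minimal loss events for one family under single-gain evolution.

    ``states`` maps leaf labels to states; leaves not listed are MISSING.
    Ambiguity resolves toward presence (losses deferred tipward), so the
    count is the minimum over all single-gain labelings.
    """
    present = [lbl for lbl, st in states.items() if st is State.PRESENT]
    if not present:
        raise FamilyNeverObservedError(f"family {family!r} never observed")
    origin = tree.mrca(present)
    summary = _subtree_summary(tree.root, states)

    loss_edges: List[Node] = []
    node_states: Dict[int, str] = {}

    def walk(n: Node, alive: bool) -> None:
        if not alive:
            node_states[n.nid] = "absent"
            for c in n.children:
                walk(c, False)
            return
        has_p, has_a = summary[n.nid]
        if not has_p and has_a:
            # Maximal subtree with no present leaf: one loss on this edge.
            loss_edges.append(n)
            node_states[n.nid] = "absent"
            for c in n.children:
                walk(c, False)
            return
        node_states[n.nid] = "present"
        for c in n.children:
            walk(c, True)

    # Nodes outside the origin's subtree predate the gain: absent.
    def mark_outside(n: Node) -> None:
        if n is origin:
            walk(n, True)
            return
        node_states[n.nid] = "absent"
        for c in n.children:
            mark_outside(c)

    mark_outside(tree.root)
    return DolloResult(family, origin, loss_edges, node_states)


def losses_by_clade(
    result: DolloResult, tree: TaxonTree, clade_names: Sequence[str]
) -> Dict[str, int]:
    """Count loss edges strictly inside each named clade.

    An edge (identified by its child node) counts toward clade C iff the
    child is a proper descendant of C's node. Edges inside none of the named
    clades are reported under ``"other"``.
    """
    clade_nodes = {name: tree.find(name) for name in clade_names}
    counts = {name: 0 for name in clade_names}
    counts["other"] = 0
    for edge_child in result.loss_edges:
        hit = False
        for name, cnode in clade_nodes.items():
            if tree.is_ancestor(cnode, edge_child, strict=True):
                counts[name] += 1
                hit = True
        if not hit:
            counts["other"] += 1
    return counts
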