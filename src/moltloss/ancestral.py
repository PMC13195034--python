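"""Ancestral orthogroup content on a named major-taxon tree.

The coverage rule: an orthogroup (OG) is attributed to an ancestor when it
contains at least one gene from every major taxon descending from that
ancestor — presence in all descendant taxa is the signature of the OG
already existing in their common ancestor. An OG whose represented taxa are
not exactly the taxon set under any single named node is "patchy"
(e.g. Enoplida + Rhabditina only): it gets no single origin node and is
reported per taxon, preserving the lower-bound reading of the
reconstruction. Node content itself is the plain coverage rule, so that
content is monotone in OG membership.

The taxon tree is small (named internal nodes over the 5 major taxa as
leaves); species map to taxa through ``taxon_of``. Gains and losses are
reported along the chain of named ancestors (root -> ... -> taxon ->
species), never against unnamed nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Set, Tuple

from .io import OrthogroupTable
from .tree import Node, TaxonTree


class ConfigurationError(ValueError):
    pass


@dataclass
class OgOrigin:
    og: str
    origin: Optional[str]  # named node label, None when patchy
    patchy: bool
    taxa: FrozenSet[str]  # major taxa represented in the OG


@dataclass
class ContentReconstruction:
    """Per named node: OG content, size, and +/- deltas vs its named ancestor."""

    content: Dict[str, Set[str]]
    species_content: Dict[str, Set[str]]
    gain: Dict[str, int]
    loss: Dict[str, int]
    parent_of: Dict[str, Optional[str]]  # named-ancestor chain
    patchy: Dict[str, FrozenSet[str]]  # og -> taxa it is scattered over

    def size(self, node: str) -> int:
        return len(self.content.get(node, self.species_content.get(node, set())))

    @property
    def patchy_count(self) -> int:
        return len(self.patchy)


def _named_nodes(taxon_tree: TaxonTree) -> List[Node]:
    return [n for n in taxon_tree.preorder() if n.label is not None]


def _represented_taxa(
    og_members: Mapping[str, List[str]], taxon_of: Mapping[str, str]
) -> FrozenSet[str]:
    taxa = set()
    for sp, genes in og_members.items():
        if not genes:
            continue
        if sp not in taxon_of:
            raise ConfigurationError(f"species {sp!r} has no major-taxon mapping")
        taxa.add(taxon_of[sp])
    return frozenset(taxa)


def assign_og_origin(
    og_members: Mapping[str, List[str]],
    taxon_of: Mapping[str, str],
    taxon_tree: TaxonTree,
) -> OgOrigin:
    """Place one OG's origin: the most inclusive named node all of whose
    descendant taxa carry the OG; "patchy" when no single node fits."""
    taxa = _represented_taxa(og_members, taxon_of)
    if not taxa:
        return OgOrigin(og="", origin=None, patchy=True, taxa=taxa)
    candidates = []
    for node in _named_nodes(taxon_tree):
        node_taxa = frozenset(taxon_tree.subtree_leaf_labels(node))
        if node_taxa <= taxa:
            candidates.append((node, node_taxa))
    # Keep maximal candidates (not dominated by another candidate).
    maximal = [
        (node, node_taxa)
        for node, node_taxa in candidates
        if not any(node_taxa < other for _, other in candidates)
    ]
    if len(maximal) == 1 and maximal[0][1] == taxa:
        return OgOrigin(og="", origin=maximal[0][0].label, patchy=False, taxa=taxa)
    return OgOrigin(og="", origin=None, patchy=True, taxa=taxa)


def reconstruct_node_content(
    table: OrthogroupTable,
    taxon_of: Mapping[str, str],
    taxon_tree: TaxonTree,
) -> ContentReconstruction:
    """Reconstruct OG content for every named node and every species.

    content(named node N) = OGs represented in every major taxon under N;
    content(species s) = OGs with >= 1 gene in s. Gains/losses are set
    differences along the named-ancestor chain, with species hanging under
    their taxon's leaf node. Patchy OGs (no single origin node) are listed
    in ``patchy``; they still enter the content of any node whose taxa they
    fully cover, keeping content monotone in OG membership.
    """
    named = _named_nodes(taxon_tree)
    node_taxa = {
        n.label: frozenset(taxon_tree.subtree_leaf_labels(n)) for n in named
    }
    origins: Dict[str, OgOrigin] = {}
    for og in table.og_ids:
        o = assign_og_origin(table.groups[og], taxon_of, taxon_tree)
        o.og = og
        origins[og] = o
    patchy = {og: o.taxa for og, o in origins.items() if o.patchy}

    content: Dict[str, Set[str]] = {n.label: set() for n in named}
    for og, o in origins.items():
        for label, taxa in node_taxa.items():
            if taxa <= o.taxa:
                content[label].add(og)

    species_content: Dict[str, Set[str]] = {sp: set() for sp in table.species}
    for og in table.og_ids:
        for sp in table.species:
            if table.groups[og][sp]:
                species_content[sp].add(og)

    # Named-ancestor chain.
    parent_of: Dict[str, Optional[str]] = {}
    for n in named:
        anc = n.parent
        while anc is not None and anc.label is None:
            anc = anc.parent
        parent_of[n.label] = anc.label if anc is not None else None
    taxon_leaves = {n.label for n in named if n.is_leaf}
    for sp, taxon in taxon_of.items():
        if sp in species_content and taxon in taxon_leaves:
            parent_of[sp] = taxon

    gain: Dict[str, int] = {}
    loss: Dict[str, int] = {}
    all_content = {**content, **species_content}
    for node, cset in all_content.items():
        parent = parent_of.get(node)
        if parent is None:
            gain[node] = len(cset)
            loss[node] = 0
        else:
            pset = all_content[parent]
            gain[node] = len(cset - pset)
            loss[node] = len(pset - cset)
    return ContentReconstruction(
        content, species_content, gain, loss, parent_of, patchy
    )
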