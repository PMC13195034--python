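"""Packaged worked-example fixture: the taxon-level nematode tree with the
ecr/usp presence pattern.

The tree encodes the major-taxon topology with named ``Tylenchina`` and
``Rhabditina`` clades; ecr is absent exactly in Alloionematidae,
Strongyloididae, Tylenchomorpha and Caenorhabditis, and usp additionally in
Panagrolaimidae, Cephalobomorpha and Strongylida — the pattern under which
Dollo mapping infers three independent ecr losses (two inside Tylenchina,
one inside Rhabditina) and usp loss preceding ecr loss.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

from .io import PresenceMatrix, read_presence_matrix
from .tree import TaxonTree, parse_newick

_TYLENCHINA = (
    "Steinernematidae",
    "Alloionematidae",
    "Strongyloididae",
    "Panagrolaimidae",
    "Cephalobomorpha",
    "Tylenchomorpha",
)
_RHABDITINA = (
    "Diplogastridae",
    "Strongylida",
    "Rhabditidae_other",
    "Caenorhabditis",
)


def _data(name: str):
    return resources.files("moltloss").joinpath("data", name)


def _leaf_tags() -> Dict[str, Dict[str, str]]:
    tags: Dict[str, Dict[str, str]] = {}
    for leaf in (
        "Enoplida",
        "Trichinellida",
        "Plectida",
        "Spirurina",
        *_TYLENCHINA,
        *_RHABDITINA,
    ):
        if leaf in _TYLENCHINA:
            major = "Tylenchina"
        elif leaf in _RHABDITINA:
            major = "Rhabditina"
        else:
            major = leaf
        # At taxon resolution each leaf is its own "genus" group, so the
        # reliability rule is the identity on this fixture.
        tags[leaf] = {"genus": leaf, "major_taxon": major}
    return tags


def load_nematode_tree() -> TaxonTree:
    """Taxon-level nematode tree with named Tylenchina/Rhabditina clades."""
    text = _data("nematode_taxa.nwk").read_text()
    return parse_newick(text, tags=_leaf_tags())


def load_nematode_presence() -> PresenceMatrix:
    """ecr/usp presence states across the fixture taxa."""
    with resources.as_file(_data("nematode_presence.tsv")) as path:
        return read_presence_matrix(path)


def load_major_taxon_tree() -> TaxonTree:
    """The 5-major-taxon tree used for ancestral orthogroup content."""
    return parse_newick(_data("major_taxa.nwk").read_text())
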