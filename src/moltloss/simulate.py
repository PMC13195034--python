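"""Synthetic fixtures with attached ground truth for every pipeline stage.

Each generator emulates the statistical structure its consuming stage
assumes: single-gain/multiple-loss presence matrices on a tree, orthogroup
tables with a known node of origin, molting-cycle expression with a planted
pre-molt oscillator fraction, reciprocal hit tables built around a known
ortholog bijection, and noisy rigid copies of idealized CA fold templates.
All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import (
    ExpressionTimecourse,
    HitTable,
    OrthogroupTable,
    PresenceMatrix,
    State,
    StructureChain,
)
from .tree import Node, TaxonTree


@dataclass
class SimTruth:
    """Ground truth attached to a generated artifact."""

    seed: int
    loss_edges: Optional[Dict[str, List[str]]] = None
    og_origins: Optional[Dict[str, str]] = None
    taxon_of: Optional[Dict[str, str]] = None
    planted_genes: Optional[List[str]] = None
    peak_offset: Optional[float] = None
    ortholog_map: Optional[Dict[Tuple[str, str], Dict[str, str]]] = None
    template_of: Optional[Dict[str, str]] = None


# -- random trees ---------------------------------------------------------


def gen_random_tree(n_leaves: int, seed: int, prefix: str = "t") -> TaxonTree:
    """Random rooted binary tree over labelled leaves (coalescent-style
    joins; topology deterministic for a fixed seed)."""
    if n_leaves < 2:
        raise ValueError("need >= 2 leaves")
    rng = np.random.default_rng(seed)
    nodes: List[Node] = [Node(label=f"{prefix}{i+1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return TaxonTree(nodes[0])


# -- presence matrices ----------------------------------------------------


def gen_presence_matrix(
    tree: TaxonTree,
    n_families: int,
    loss_rate: float,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> Tuple[PresenceMatrix, SimTruth]:
    """Single-gain / multiple-loss evolution with missing-data corruption.

    Every family originates at the root; each edge below a still-present
    lineage loses the family with ``loss_rate`` (no regain); observed
    absences flip to MISSING with ``missing_rate``.
    """
    if not (0 <= loss_rate < 1 and 0 <= missing_rate <= 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    leaves = tree.leaf_labels
    loss_edges: Dict[str, List[str]] = {}
    columns: Dict[str, List[State]] = {}
    for f in range(n_families):
        fam = f"fam{f+1}"
        alive: Dict[int, bool] = {tree.root.nid: True}
        edges: List[str] = []
        for node in tree.preorder():
            if node is tree.root:
                continue
            parent_alive = alive[node.parent.nid]
            if parent_alive and rng.random() < loss_rate:
                alive[node.nid] = False
                edges.append(node.name)
            else:
                alive[node.nid] = parent_alive
        loss_edges[fam] = edges
        states = []
        for leaf in tree.leaves():
            if alive[leaf.nid]:
                states.append(State.PRESENT)
            elif rng.random() < missing_rate:
                states.append(State.MISSING)
            else:
                states.append(State.ABSENT)
        columns[fam] = states
    df = pd.DataFrame(columns, index=leaves)
    return PresenceMatrix(df), SimTruth(seed=seed, loss_edges=loss_edges)


# -- orthogroup tables ----------------------------------------------------


def gen_orthogroups(
    taxon_tree: TaxonTree,
    species_per_taxon: int,
    n_ogs: int,
    origin_probs: Mapping[str, float],
    within_taxon_loss: float = 0.0,
    seed: int = 0,
    clean_fraction: float = 1.0,
) -> Tuple[OrthogroupTable, SimTruth]:
    """Orthogroup tables with planted origin nodes.

    ``origin_probs`` maps named nodes of the taxon tree to origin
    probabilities (summing to 1). Species under the origin each receive 1-2
    genes, then are thinned by ``within_taxon_loss``; for "clean" OGs
    (fraction ``clean_fraction``) every descendant major taxon keeps at
    least one member, so the planted origin stays reconstructible.
    """
    labels = list(origin_probs)
    probs = np.array([origin_probs[l] for l in labels], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("origin probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    taxa = taxon_tree.leaf_labels
    species = {t: [f"{t}_sp{i+1}" for i in range(species_per_taxon)] for t in taxa}
    taxon_of = {sp: t for t, sps in species.items() for sp in sps}
    all_species = [sp for t in taxa for sp in species[t]]
    groups: Dict[str, Dict[str, List[str]]] = {}
    origins: Dict[str, str] = {}
    for k in range(n_ogs):
        og = f"OG{k:07d}"
        origin = labels[rng.choice(len(labels), p=probs)]
        origins[og] = origin
        node = taxon_tree.find(origin)
        covered_taxa = taxon_tree.subtree_leaf_labels(node)
        members: Dict[str, List[str]] = {sp: [] for sp in all_species}
        clean = rng.random() < clean_fraction
        for t in covered_taxa:
            keep = [
                sp for sp in species[t] if rng.random() >= within_taxon_loss
            ]
            if clean and not keep:
                keep = [species[t][int(rng.integers(len(species[t])))]]
            for sp in keep:
                n_genes = int(rng.integers(1, 3))
                members[sp] = [f"{og}_{sp}_g{j+1}" for j in range(n_genes)]
        groups[og] = members
    table = OrthogroupTable(all_species, groups)
    return table, SimTruth(seed=seed, og_origins=origins, taxon_of=taxon_of)


# -- expression timecourses -----------------------------------------------


def gen_expression_timecourse(
    n_genes: int = 200,
    times: Optional[np.ndarray] = None,
    molt_times: Optional[Sequence[float]] = None,
    frac_premolt: float = 0.3,
    peak_offset: float = 1.0,
    amplitude: float = 10.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    baseline: float = 2.0,
    bump_width: float = 1.5,
) -> Tuple[ExpressionTimecourse, SimTruth]:
    """Molting-cycle expression with a planted pre-molt oscillator fraction.

    Planted genes carry Gaussian bumps of the given amplitude centred
    ``peak_offset`` hours before each molt; background genes are either flat
    or oscillate at a random phase away from the pre-molt window. Additive
    Gaussian noise has sd ``noise_sd * amplitude``; values clip at 0.
    """
    if not (0 <= frac_premolt <= 1):
        raise ValueError("frac_premolt must lie in [0, 1]")
    if peak_offset <= 0:
        raise ValueError("peak_offset must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(times if times is not None else np.arange(0.0, 39.0, 1.0))
    molts = np.asarray(molt_times if molt_times is not None else [8.0, 16.0, 24.0, 32.0], dtype=float)
    period = float(np.median(np.diff(molts))) if len(molts) > 1 else float(molts[0] - t.min())

    n_planted = int(round(frac_premolt * n_genes))
    planted = [f"g{i+1:04d}" for i in range(n_planted)]
    background = [f"g{i+1:04d}" for i in range(n_planted, n_genes)]

    def bumps(centers: np.ndarray, amp: float) -> np.ndarray:
        prof = np.zeros_like(t)
        for c in centers:
            prof += amp * np.exp(-0.5 * ((t - c) / bump_width) ** 2)
        return prof

    rows = []
    for _g in planted:
        rows.append(baseline + bumps(molts - peak_offset, amplitude))
    for _g in background:
        if rng.random() < 0.5:
            rows.append(np.full_like(t, baseline))
        else:
            # random-phase oscillator peaking well away from the pre-molt window
            off = rng.uniform(0.35, 0.85) * period
            rows.append(baseline + bumps(molts - off, amplitude))
    X = np.array(rows)
    X = X + rng.normal(0.0, noise_sd * amplitude, size=X.shape)
    X = np.clip(X, 0.0, None)
    df = pd.DataFrame(X, index=planted + background, columns=[f"t{v:g}" for v in t])
    tc = ExpressionTimecourse(df, t, molts, None)
    return tc, SimTruth(seed=seed, planted_genes=planted, peak_offset=peak_offset)


# -- hit tables -----------------------------------------------------------


def gen_hit_tables(
    ortholog_map: Mapping[Tuple[str, str], Mapping[str, str]],
    decoy_count: int = 0,
    decoy_evalue_factor: float = 10.0,
    seed: int = 0,
    decoy_jitter_sd: float = 0.0,
) -> Dict[Tuple[str, str], HitTable]:
    """Hit tables around a planted ortholog bijection plus decoys.

    For every (source, target) pair in ``ortholog_map``, forward and reverse
    tables are produced. True pairs draw reciprocal best e-values below
    1e-25; each decoy hit re-uses a real query with a wrong subject at
    e-value >= ``decoy_evalue_factor`` x the query's true e-value
    (``decoy_jitter_sd`` > 0 adds lognormal jitter that can undercut that
    bound, for probing recall degradation deliberately).
    """
    if decoy_evalue_factor <= 1:
        raise ValueError("decoy_evalue_factor must be > 1")
    rng = np.random.default_rng(seed)
    tables: Dict[Tuple[str, str], HitTable] = {}

    def bitscore(ev: float) -> float:
        return max(20.0, -10.0 * np.log10(max(ev, 1e-180)))

    for (src, dst), mapping in ortholog_map.items():
        fwd_rows, rev_rows = [], []
        true_ev: Dict[str, float] = {}
        for q, s in mapping.items():
            ev_f = 10.0 ** rng.uniform(-40, -26)
            ev_r = 10.0 ** rng.uniform(-40, -26)
            true_ev[q] = ev_f
            fwd_rows.append((q, s, ev_f, bitscore(ev_f)))
            rev_rows.append((s, q, ev_r, bitscore(ev_r)))
        queries = list(mapping)
        subjects = list(mapping.values())
        for d in range(decoy_count):
            q = queries[int(rng.integers(len(queries)))]
            wrong = [s for s in subjects if s != mapping[q]]
            s = (
                wrong[int(rng.integers(len(wrong)))]
                if wrong
                else f"{dst}_decoy{d+1}"
            )
            ev = true_ev[q] * decoy_evalue_factor * 10.0 ** rng.uniform(0, 2)
            if decoy_jitter_sd > 0:
                ev *= float(np.exp(rng.normal(0.0, decoy_jitter_sd)))
            fwd_rows.append((q, s, ev, bitscore(ev)))
        for direction, rows in (((src, dst), fwd_rows), ((dst, src), rev_rows)):
            df = pd.DataFrame(rows, columns=["query", "subject", "evalue", "bitscore"])
            tables[direction] = HitTable(df, direction)
    return tables


# -- structures -----------------------------------------------------------

FOLD_TEMPLATES = ("helix_bundle", "meander")


def fold_template(name: str, length: int = 160) -> StructureChain:
    """Idealized CA fold templates (deterministic, length >= 160).

    ``helix_bundle``: three antiparallel alpha-helices (2.3 Angstrom radius,
    1.5 Angstrom rise, 100 degrees per residue). ``meander``: four
    antiparallel extended strands (3.3 Angstrom rise) with tight turns.
    """
    if length < 160:
        raise ValueError("templates must be at least 160 residues")
    coords = np.zeros((length, 3))
    if name == "helix_bundle":
        per = length // 3
        for k in range(3):
            lo = k * per
            hi = length if k == 2 else lo + per
            n = hi - lo
            idx = np.arange(n)
            phase = np.deg2rad(100.0) * idx
            z = 1.5 * idx
            if k % 2 == 1:
                z = z[::-1]
            coords[lo:hi, 0] = 2.3 * np.cos(phase) + 10.0 * k
            coords[lo:hi, 1] = 2.3 * np.sin(phase)
            coords[lo:hi, 2] = z
    elif name == "meander":
        per = length // 4
        for k in range(4):
            lo = k * per
            hi = length if k == 3 else lo + per
            n = hi - lo
            idx = np.arange(n)
            z = 3.3 * idx
            if k % 2 == 1:
                z = z[::-1]
            coords[lo:hi, 0] = 4.8 * k
            coords[lo:hi, 1] = 0.9 * ((idx + k) % 2)  # pleat
            coords[lo:hi, 2] = z
    else:
        raise ValueError(f"unknown fold template {name!r}; have {FOLD_TEMPLATES}")
    return StructureChain(np.arange(1, length + 1), coords, "A", f"template:{name}")


def gen_structure_pair(
    template: str,
    n_copies: int,
    coord_noise: float = 0.5,
    seed: int = 0,
    length: int = 160,
) -> Tuple[List[StructureChain], SimTruth]:
    """Noisy rigid copies of one fold template.

    Each copy is a uniformly random proper rotation plus translation of the
    template with isotropic Gaussian coordinate noise of sd ``coord_noise``
    Angstroms. Copies pass the LBD length filter by construction.
    """
    rng = np.random.default_rng(seed)
    base = fold_template(template, length)
    chains: List[StructureChain] = []
    template_of: Dict[str, str] = {}
    for i in range(n_copies):
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-20, 20, size=3)
        coords = base.coords @ R.T + t
        coords = coords + rng.normal(0.0, coord_noise, size=coords.shape)
        name = f"{template}_copy{i+1}"
        chains.append(StructureChain(base.residue_ids.copy(), coords, "A", name))
        template_of[name] = template
    return chains, SimTruth(seed=seed, template_of=template_of)
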