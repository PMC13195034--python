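"""Reciprocal-best-hit homolog screening with iterative query expansion.

Orchestrates the three-round gene-identification scheme used for mining
molting genes (ecr, usp, hr3, ...) across many genomes: thresholded forward
hits, reciprocal one-to-one top hits, expansion of the query set with newly
accepted genes to rescue species missed by the first round, and finally
clade validation on a bootstrapped gene tree. The sequence searches
themselves run offline; this module consumes their tabular outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .io import HitTable
from .tree import TaxonTree

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Thresholds of the screening procedure.

    Both e-value cut-offs are strict ("less than"): the forward search uses
    1e-20, the reciprocal confirmation 1e-10. ``min_support`` is the
    bootstrap level below which a validating clade is not trusted.
    """

    forward_evalue: float = 1e-20
    reciprocal_evalue: float = 1e-10
    max_rounds: int = 3
    min_support: float = 70.0
    reference_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.forward_evalue <= 0 or self.reciprocal_evalue <= 0:
            raise ValueError("e-value thresholds must be positive")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class ScreenResult:
    rounds: List[Dict[str, Set[str]]] = field(default_factory=list)
    accepted: Dict[str, Set[str]] = field(default_factory=dict)
    rejected: Dict[str, str] = field(default_factory=dict)
    uncoverable: Set[str] = field(default_factory=set)

    @property
    def productive_rounds(self) -> int:
        return sum(1 for r in self.rounds if any(r.values()))


def reciprocal_top_hits(
    forward: HitTable, reverse: HitTable, cfg: ScreenConfig
) -> Set[Tuple[str, str]]:
    """One-to-one reciprocal top hits below both thresholds.

    A pair (q, s) is kept iff s is q's best forward hit with e-value
    strictly below ``forward_evalue`` AND q is s's best reverse hit with
    e-value strictly below ``reciprocal_evalue``. Best-hit ties break by
    higher bitscore, then lexicographic subject ID.
    """
    if forward.data.empty:
        return set()
    fwd_best = forward.best_per_query()
    rev_best = reverse.best_per_query() if not reverse.data.empty else None
    pairs: Set[Tuple[str, str]] = set()
    for q, row in fwd_best.iterrows():
        if not row["evalue"] < cfg.forward_evalue:
            continue
        s = row["subject"]
        if rev_best is None or s not in rev_best.index:
            continue
        back = rev_best.loc[s]
        if back["subject"] == q and back["evalue"] < cfg.reciprocal_evalue:
            pairs.add((q, s))
    # Mutual-best implies one-to-one; assert the invariant anyway.
    subjects = [s for _, s in pairs]
    assert len(subjects) == len(set(subjects)), "subject accepted twice"
    return pairs


def iterative_screen(
    seeds: Mapping[str, Set[str]],
    provider: Mapping[Tuple[str, str], HitTable],
    cfg: ScreenConfig,
    species: Sequence[str],
) -> ScreenResult:
    """Expand the accepted gene set round by round.

    ``seeds`` maps species already covered by the first screening to their
    accepted gene IDs. Each round uses the genes accepted in the previous
    round as queries against every species with no accepted gene yet,
    requiring reciprocal top hits through ``provider`` (keyed by
    (source_species, target_species)). Iteration stops when a round adds
    nothing or after ``max_rounds``.
    """
    result = ScreenResult(accepted={sp: set(seeds.get(sp, set())) for sp in species})
    previous: Dict[str, Set[str]] = {
        sp: set(g) for sp, g in seeds.items() if g
    }
    if not previous:
        return result
    for _ in range(cfg.max_rounds):
        uncovered = [sp for sp in species if not result.accepted[sp]]
        added: Dict[str, Set[str]] = {sp: set() for sp in species}
        for dst in uncovered:
            for src, queries in previous.items():
                if not queries:
                    continue
                key_f, key_r = (src, dst), (dst, src)
                if key_f not in provider or key_r not in provider:
                    logger.warning("no hit tables for %s<->%s; species uncoverable via %s", src, dst, src)
                    result.uncoverable.add(dst)
                    continue
                fwd = provider[key_f]
                restricted = HitTable(
                    fwd.data[fwd.data["query"].isin(queries)].copy(), fwd.direction
                ) if not fwd.data.empty else fwd
                for _q, s in reciprocal_top_hits(restricted, provider[key_r], cfg):
                    added[dst].add(s)
        if not any(added.values()):
            break
        result.rounds.append({sp: g for sp, g in added.items() if g})
        for sp, genes in added.items():
            result.accepted[sp] |= genes
        previous = {sp: g for sp, g in added.items() if g}
    result.uncoverable -= {sp for sp in species if result.accepted[sp]}
    return result


def clade_validate(
    gene_tree: TaxonTree, candidates: Set[str], cfg: ScreenConfig
) -> Tuple[Set[str], Dict[str, str]]:
    """Accept candidates falling inside the reference clade.

    The target clade is the smallest node containing every reference member.
    A candidate is accepted iff it descends from that node and the node's
    bootstrap support reaches ``min_support``. Returns (accepted,
    rejected-with-reason). When the reference members only join at the root,
    validation proceeds with the root (accept-all) but is flagged
    low-confidence via a warning.
    """
    if not cfg.reference_ids:
        raise ValueError("reference clade member IDs required for validation")
    clade = gene_tree.mrca(cfg.reference_ids)
    if clade is gene_tree.root:
        logger.warning(
            "reference members only monophyletic at the root; "
            "accept-all validation is low-confidence"
        )
    accepted: Set[str] = set()
    rejected: Dict[str, str] = {}
    low_support = clade.support is not None and clade.support < cfg.min_support
    for cand in sorted(candidates):
        leaf = gene_tree.find(cand)
        if not gene_tree.is_ancestor(clade, leaf):
            rejected[cand] = "outside-clade"
        elif low_support:
            rejected[cand] = "low-support"
        else:
            accepted.add(cand)
    return accepted, rejected
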