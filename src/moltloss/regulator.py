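"""Cross-species regulator screening and nuclear-receptor counting.

Candidate molting genes from each species' expression screen are pushed
through orthogroups: an orthogroup survives only if every species
contributes at least one candidate to it, a representative species' gene
list is extracted, and the list is narrowed to transcription factors by
Pfam domain content. Nuclear receptors are counted per species from
Hormone_recep (PF00104) domain-scan hits with isoforms collapsed to genes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .io import DomainTable, OrthogroupTable

logger = logging.getLogger(__name__)

DOMAIN_EVALUE_THRESHOLD = 1e-5

HORMONE_RECEP = "PF00104"

#: Pfam accessions of the transcription-factor domain panel used for the
#: final filter (versions are ignored when matching).
TF_DOMAIN_PANEL: Tuple[str, ...] = (
    "PF01388",  # ARID
    "PF02178",  # AT_hook
    "PF01586",  # Basic
    "PF02376",  # CUT
    "PF00751",  # DM
    "PF00178",  # Ets
    "PF00250",  # Forkhead
    "PF00320",  # GATA
    "PF03615",  # GCM
    "PF00010",  # HLH
    "PF00505",  # HMG_box
    "PF07527",  # Hairy_orange
    "PF00046",  # Homeobox
    "PF00104",  # Hormone_recep
    "PF03826",  # OAR
    "PF00870",  # P53
    "PF07710",  # P53_tetramer
    "PF00292",  # PAX
    "PF00157",  # Pou
    "PF05044",  # HPD
    "PF00554",  # RHD_DNA_bind
    "PF00853",  # Runt
    "PF02023",  # SCAN
    "PF06621",  # SIM_C
    "PF00319",  # SRF-TF
    "PF00907",  # T-box
    "PF12598",  # TBX
    "PF03299",  # TF_AP-2
    "PF03529",  # TF_Otx
    "PF00170",  # bZIP_1
    "PF07716",  # bZIP_2
    "PF00096",  # zf-C2H2
    "PF01530",  # zf-C2HC
    "PF00105",  # zf-C4
)

assert HORMONE_RECEP in TF_DOMAIN_PANEL

_ISOFORM_SUFFIX = re.compile(r"(\.\d+|[a-z])$")


def strip_accession_version(accession: str) -> str:
    return accession.split(".", 1)[0]


def collapse_isoform(gene_id: str, isoform_map: Optional[Mapping[str, str]] = None) -> str:
    """Map an isoform ID to its gene ID.

    An explicit map wins; otherwise a trailing ``.digit`` or trailing
    lowercase-letter variant suffix is stripped (C. elegans style ``abc-1a``
    / WormBase style ``g123.2``).
    """
    if isoform_map is not None and gene_id in isoform_map:
        return isoform_map[gene_id]
    return _ISOFORM_SUFFIX.sub("", gene_id)


def intersect_candidate_ogs(
    candidates_by_species: Mapping[str, Set[str]],
    table: OrthogroupTable,
) -> Set[str]:
    """Orthogroups holding >= 1 candidate gene from every species."""
    for sp in candidates_by_species:
        if sp not in table.species:
            raise KeyError(f"species {sp!r} not in orthogroup table")
    empty = [sp for sp, c in candidates_by_species.items() if not c]
    if empty:
        logger.warning("species with empty candidate sets: %s", empty)
        return set()
    kept: Set[str] = set()
    for og in table.og_ids:
        if all(
            any(g in cands for g in table.groups[og][sp])
            for sp, cands in candidates_by_species.items()
        ):
            kept.add(og)
    return kept


def species_gene_list(
    ogs: Iterable[str], table: OrthogroupTable, species: str
) -> List[str]:
    """Sorted, de-duplicated genes of one species across the kept OGs."""
    if species not in table.species:
        raise KeyError(f"species {species!r} not in orthogroup table")
    genes: Set[str] = set()
    for og in ogs:
        genes.update(table.groups[og][species])
    return sorted(genes)


def filter_transcription_factors(
    genes: Sequence[str],
    domains: DomainTable,
    panel: Sequence[str] = TF_DOMAIN_PANEL,
    table: Optional[OrthogroupTable] = None,
) -> Tuple[List[str], Set[str]]:
    """Keep genes with >= 1 panel domain below the scan threshold.

    Accession version suffixes are ignored on both sides. Returns the kept
    genes (sorted) and, when an orthogroup table is supplied, the set of
    orthogroups containing them.
    """
    panel_bare = {strip_accession_version(a) for a in panel}
    df = domains.data
    hits = df[df["evalue"] < DOMAIN_EVALUE_THRESHOLD]
    tf_genes = {
        g
        for g, acc in zip(hits["gene"], hits["accession"])
        if strip_accession_version(acc) in panel_bare
    }
    kept = sorted(g for g in set(genes) if g in tf_genes)
    ogs: Set[str] = set()
    if table is not None:
        gene_set = set(kept)
        for og in table.og_ids:
            for sp in table.species:
                if gene_set.intersection(table.groups[og][sp]):
                    ogs.add(og)
                    break
    return kept, ogs


def count_nuclear_receptors(
    domains: DomainTable,
    threshold: float = DOMAIN_EVALUE_THRESHOLD,
) -> int:
    """Distinct (isoform-collapsed) genes with a Hormone_recep hit below the
    threshold."""
    df = domains.data
    hits = df[
        (df["evalue"] < threshold)
        & (df["accession"].map(strip_accession_version) == HORMONE_RECEP)
    ]
    genes = {collapse_isoform(g, domains.isoform_map) for g in hits["gene"]}
    return len(genes)
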