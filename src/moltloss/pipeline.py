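"""Config-driven orchestration of the analysis stages.

A pipeline config (YAML) holds one block per stage plus a global seed and
output directory. Stages run in dependency order; every output file gets a
sidecar provenance record (tool version, config hash, seed). Any stage
failure marks its partial outputs with a ``.failed`` file and aborts with a
report naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestral import reconstruct_node_content
from .expression import (
    cluster_timecourse,
    collapse_replicates_and_merge,
    select_premolt_clusters,
    smooth_windows,
)
from .fixtures import load_nematode_presence, load_nematode_tree
from .homolog import ScreenConfig, clade_validate, iterative_screen
from .io import (
    read_domain_table,
    read_expression,
    read_hit_table,
    read_orthogroups,
    read_presence_matrix,
    read_structure_ca,
    write_hit_table,
    write_orthogroups,
    write_presence_matrix,
    write_structure_ca,
)
from .loss_mapping import ReliabilityConfig, apply_reliability_rule, dollo_map, losses_by_clade
from .regulator import filter_transcription_factors, intersect_candidate_ogs, species_gene_list
from .simulate import (
    gen_expression_timecourse,
    gen_hit_tables,
    gen_presence_matrix,
    gen_structure_pair,
)
from .structure import classify_against_references, lbd_length_filter
from .tree import parse_newick
from .io import State

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "simulate",
    "losses",
    "ancestral",
    "screen_homologs",
    "cluster_expression",
    "screen_regulators",
    "struct_classify",
)
_GLOBAL_KEYS = {"seed", "outdir", "log_level"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    unknown = set(config) - _GLOBAL_KEYS - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return config


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _provenance(out: Path, config: Mapping, seed: int, stage: str) -> None:
    record = {
        "tool": f"moltloss {__version__}",
        "stage": stage,
        "config_hash": _config_hash(config),
        "seed": seed,
    }
    out.with_suffix(out.suffix + ".prov.json").write_text(
        json.dumps(record, sort_keys=True) + "\n"
    )


def _load_tree(spec: str, base: Path):
    if spec == "fixture":
        return load_nematode_tree()
    return parse_newick(Path(base / spec).read_text())


def _load_presence(spec: str, base: Path):
    if spec == "fixture":
        return load_nematode_presence()
    return read_presence_matrix(base / spec)


# -- stage runners --------------------------------------------------------


def run_losses(block: Mapping, outdir: Path, seed: int, base: Path) -> Path:
    tree = _load_tree(block.get("tree", "fixture"), base)
    matrix = _load_presence(block.get("matrix", "fixture"), base)
    clades = list(block.get("clades", []))
    families = block.get("families") or matrix.families
    level = block.get("group_level", "genus")
    cfg = ReliabilityConfig(level=level, min_group_size=int(block.get("min_group_size", 1)))
    if all(tree.tag_of(t, level) is not None for t in matrix.taxa):
        matrix = apply_reliability_rule(matrix, tree, cfg)
    rows = []
    for family in families:
        result = dollo_map(tree, matrix.column(family), family)
        per_clade = losses_by_clade(result, tree, clades) if clades else {"other": result.loss_count}
        row = {
            "family": family,
            "total_losses": result.loss_count,
            **{f"losses_{c}": n for c, n in per_clade.items()},
            "loss_edges": ";".join(result.loss_edge_labels),
        }
        rows.append(row)
    out = outdir / block.get("out", "losses.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out


def run_ancestral(block: Mapping, outdir: Path, seed: int, base: Path) -> Path:
    table = read_orthogroups(base / block["orthogroups"])
    taxa_df = pd.read_csv(base / block["taxa"], sep="\t")
    taxon_of = dict(zip(taxa_df["species"], taxa_df["major_taxon"]))
    tree = _load_tree(block["tree"], base)
    recon = reconstruct_node_content(table, taxon_of, tree)
    rows = []
    for node in list(recon.content) + list(recon.species_content):
        rows.append(
            {
                "node": node,
                "content_size": recon.size(node),
                "gain": recon.gain.get(node, 0),
                "loss": recon.loss.get(node, 0),
                "patchy_count": recon.patchy_count,
            }
        )
    out = outdir / block.get("out", "content.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out


def run_screen_homologs(block: Mapping, outdir: Path, seed: int, base: Path) -> Path:
    hits_dir = base / block["hits_dir"]
    provider = {}
    for f in sorted(hits_dir.glob("*.tsv")):
        src, dst = f.stem.split("__")
        provider[(src, dst)] = read_hit_table(f, (src, dst))
    seeds_df = pd.read_csv(base / block["seeds"], sep="\t")
    seeds: Dict[str, Set[str]] = {}
    for sp, gene in zip(seeds_df["species"], seeds_df["gene"]):
        seeds.setdefault(sp, set()).add(gene)
    species = sorted({s for pair in provider for s in pair} | set(seeds))
    cfg = ScreenConfig(
        forward_evalue=float(block.get("forward_evalue", 1e-20)),
        reciprocal_evalue=float(block.get("reciprocal_evalue", 1e-10)),
        max_rounds=int(block.get("max_rounds", 3)),
        min_support=float(block.get("min_support", 70.0)),
        reference_ids=tuple(block.get("refs", ())),
    )
    result = iterative_screen(seeds, provider, cfg, species)
    accepted = result.accepted
    if block.get("gene_tree") and cfg.reference_ids:
        tree = _load_tree(block["gene_tree"], base)
        candidates = {g for genes in accepted.values() for g in genes}
        ok, rejected = clade_validate(tree, candidates, cfg)
        accepted = {sp: genes & ok for sp, genes in accepted.items()}
        result.rejected.update(rejected)
    rows = [
        {"species": sp, "genes": ";".join(sorted(genes)), "n": len(genes)}
        for sp, genes in sorted(accepted.items())
    ]
    out = outdir / block.get("out", "screen.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out


def run_cluster_expression(block: Mapping, outdir: Path, seed: int, base: Path) -> Path:
    tc = read_expression(base / block["expr"], base / block["meta"])
    tc = collapse_replicates_and_merge(tc, block.get("merge_groups"))
    if block.get("smooth", True) and tc.values.shape[1] >= 3:
        tc = smooth_windows(tc)
    result = cluster_timecourse(
        tc,
        c=int(block.get("clusters", 6)),
        seed=int(block.get("seed", seed)),
        standardize=bool(block.get("standardize", True)),
    )
    _sel, genes = select_premolt_clusters(
        result,
        tc,
        delta=float(block.get("delta", 0.25)),
        majority=float(block.get("majority", 0.5)),
    )
    out = outdir / block.get("out", "candidates.txt")
    out.write_text("".join(g + "\n" for g in genes))
    return out


def run_screen_regulators(block: Mapping, outdir: Path, seed: int, base: Path) -> Path:
    table = read_orthogroups(base / block["orthogroups"])
    cand_dir = base / block["candidates"]
    candidates = {
        f.stem: set(f.read_text().split())
        for f in sorted(cand_dir.glob("*.txt"))
    }
    kept = intersect_candidate_ogs(candidates, table)
    species = block.get("species") or sorted(candidates)[0]
    genes = species_gene_list(kept, table, species)
    domains = read_domain_table(base / block["domains"])
    tf_genes, tf_ogs = filter_transcription_factors(genes, domains, table=table)
    out = outdir / block.get("out", "tf_ogs.tsv")
    pd.DataFrame(
        {
            "orthogroup": sorted(tf_ogs),
        }
    ).to_csv(out, sep="\t", index=False)
    (outdir / "tf_genes.txt").write_text("".join(g + "\n" for g in tf_genes))
    (outdir / "conserved_ogs.txt").write_text("".join(og + "\n" for og in sorted(kept)))
    return out


def run_struct_classify(block: Mapping, outdir: Path, seed: int, base: Path) -> Path:
    def load_dir(d: Path):
        chains = {}
        for f in sorted(d.glob("*.pdb")):
            chains[f.stem] = read_structure_ca(f, block.get("chain", "A"))
        return chains

    queries = load_dir(base / block["queries"])
    refs = load_dir(base / block["refs"])
    min_len = int(block.get("min_len", 151))
    queries = {k: v for k, v in queries.items() if lbd_length_filter([v], min_len)}
    refs = {k: v for k, v in refs.items() if lbd_length_filter([v], min_len)}
    matrix = classify_against_references(queries, refs, norm=block.get("norm", "reference"))
    out = outdir / block.get("out", "tm_matrix.tsv")
    matrix.scores.to_csv(out, sep="\t")
    pd.DataFrame(
        [{"query": q, "best_reference": r} for q, r in sorted(matrix.assignments.items())]
    ).to_csv(outdir / "classification.tsv", sep="\t", index=False)
    return out


def run_simulate(block: Mapping, outdir: Path, seed: int, base: Path) -> Path:
    what = block.get("what", "presence")
    sub_seed = int(block.get("seed", seed))
    simdir = outdir / block.get("out", "simulated")
    simdir.mkdir(parents=True, exist_ok=True)
    if what == "presence":
        tree = load_nematode_tree()
        matrix, truth = gen_presence_matrix(
            tree,
            n_families=int(block.get("n_families", 20)),
            loss_rate=float(block.get("loss_rate", 0.05)),
            missing_rate=float(block.get("missing_rate", 0.1)),
            seed=sub_seed,
        )
        write_presence_matrix(matrix, simdir / "presence.tsv")
        (simdir / "truth.json").write_text(json.dumps(truth.loss_edges, indent=1))
    elif what == "expression":
        tc, truth = gen_expression_timecourse(seed=sub_seed)
        tc.values.to_csv(simdir / "expr.tsv", sep="\t")
        meta = pd.DataFrame(
            {
                "column": tc.values.columns,
                "time_h": tc.times,
                "molt_event": [int(t in set(tc.molt_times)) for t in tc.times],
            }
        )
        meta.to_csv(simdir / "meta.tsv", sep="\t", index=False)
        (simdir / "truth.json").write_text(json.dumps(truth.planted_genes, indent=1))
    elif what == "structures":
        for template in ("helix_bundle", "meander"):
            chains, _truth = gen_structure_pair(
                template,
                n_copies=int(block.get("n_copies", 3)),
                coord_noise=float(block.get("coord_noise", 0.5)),
                seed=sub_seed,
            )
            for chain in chains:
                write_structure_ca(chain, simdir / f"{chain.source}.pdb")
    elif what == "hits":
        species = [f"sp{i+1}" for i in range(int(block.get("n_species", 3)))]
        genes = {sp: [f"{sp}_g{j+1}" for j in range(5)] for sp in species}
        omap = {
            (a, b): dict(zip(genes[a], genes[b]))
            for a in species
            for b in species
            if a != b
        }
        tables = gen_hit_tables(omap, decoy_count=5, seed=sub_seed)
        for (src, dst), table in tables.items():
            write_hit_table(table, simdir / f"{src}__{dst}.tsv")
    else:
        raise ValueError(f"unknown simulate target {what!r}")
    return simdir / "done"


_RUNNERS = {
    "simulate": run_simulate,
    "losses": run_losses,
    "ancestral": run_ancestral,
    "screen_homologs": run_screen_homologs,
    "cluster_expression": run_cluster_expression,
    "screen_regulators": run_screen_regulators,
    "struct_classify": run_struct_classify,
}


def run_pipeline(config: Mapping, base_dir: str | Path = ".") -> Dict[str, str]:
    """Execute configured stages in dependency order; return a run report."""
    unknown = set(config) - _GLOBAL_KEYS - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    base = Path(base_dir)
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "moltloss_out"))
    if not outdir.is_absolute():
        outdir = base / outdir
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.get("log_level", "INFO"))
    report: Dict[str, str] = {}
    for stage in STAGE_ORDER:
        if stage not in config:
            continue
        block = config[stage] or {}
        try:
            out = _RUNNERS[stage](block, outdir, seed, base)
        except Exception as exc:
            marker = outdir / f"{stage}.failed"
            marker.write_text(str(exc) + "\n")
            raise PipelineError(stage, exc) from exc
        if out.exists():
            _provenance(out, config, seed, stage)
        report[stage] = str(out)
    return report


def demo() -> Dict[str, object]:
    """Run the packaged worked example: ecr/usp Dollo losses on the fixture."""
    tree = load_nematode_tree()
    matrix = load_nematode_presence()
    cfg = ReliabilityConfig(level="genus")
    matrix = apply_reliability_rule(matrix, tree, cfg)
    out: Dict[str, object] = {}
    for family in matrix.families:
        result = dollo_map(tree, matrix.column(family), family)
        out[family] = {
            "total_losses": result.loss_count,
            "by_clade": losses_by_clade(result, tree, ["Tylenchina", "Rhabditina"]),
            "loss_edges": result.loss_edge_labels,
        }
    return out
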