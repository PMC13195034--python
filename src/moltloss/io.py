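"""Tabular and structural domain types plus their readers and writers.

All on-disk formats are plain text: TSV for matrices and tables, the
OrthoFinder ``Orthogroups.tsv`` dialect for orthogroup membership, and PDB
ATOM records (CA atoms only) for structures.
"""

from __future__ import annotations

import csv
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file."""


class State(enum.Enum):
    """Gene-family state at a leaf: the three symbols of a presence matrix."""

    PRESENT = "1"
    ABSENT = "0"
    MISSING = "?"

    @classmethod
    def from_symbol(cls, symbol: str) -> "State":
        for st in cls:
            if st.value == symbol:
                return st
        raise FormatError(
            f"unknown state symbol {symbol!r}; expected one of 1, 0, ?"
        )


# -- presence matrix ------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Taxa x gene-family states.

    ``data`` is a pandas DataFrame of :class:`State` values with taxon row
    index and family column index.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for v in self.data.to_numpy().ravel():
            if not isinstance(v, State):
                raise FormatError(f"presence cell {v!r} is not a State")

    @property
    def taxa(self) -> List[str]:
        return list(self.data.index)

    @property
    def families(self) -> List[str]:
        return list(self.data.columns)

    def column(self, family: str) -> Dict[str, State]:
        return dict(self.data[family])

    def copy(self) -> "PresenceMatrix":
        return PresenceMatrix(self.data.copy())


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    """Read the TSV dialect: header ``taxon`` + family names, cells 1/0/?."""
    rows: List[List[str]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty presence matrix")
    header = rows[0]
    if not header or header[0] != "taxon":
        raise FormatError(f"{path}: first header column must be 'taxon'")
    families = header[1:]
    records: Dict[str, List[State]] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: ragged row at line {lineno}")
        records[row[0]] = [State.from_symbol(c) for c in row[1:]]
    df = pd.DataFrame.from_dict(records, orient="index", columns=families)
    return PresenceMatrix(df)


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["taxon"] + matrix.families)
        for taxon in matrix.taxa:
            w.writerow([taxon] + [st.value for st in matrix.data.loc[taxon]])


# -- orthogroups ----------------------------------------------------------


@dataclass
class OrthogroupTable:
    """Orthogroup ID -> species -> gene-ID list (OrthoFinder semantics)."""

    species: List[str]
    groups: Dict[str, Dict[str, List[str]]]

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for og, per_species in self.groups.items():
            for sp in self.species:
                per_species.setdefault(sp, [])
            for sp, genes in per_species.items():
                for g in genes:
                    if g in seen and seen[g] != og:
                        warnings.warn(
                            f"gene {g!r} appears in {seen[g]} and {og}; keeping first"
                        )
                    seen.setdefault(g, og)

    @property
    def og_ids(self) -> List[str]:
        return list(self.groups)

    def genes_of(self, og: str, species: str) -> List[str]:
        return self.groups[og][species]

    def species_represented(self, og: str) -> List[str]:
        return [sp for sp in self.species if self.groups[og][sp]]

    def restrict_genes(self, keep: Mapping[str, Iterable[str]]) -> "OrthogroupTable":
        """Drop genes not listed per species (used before regulator screens)."""
        keep_sets = {sp: set(v) for sp, v in keep.items()}
        groups = {
            og: {
                sp: [g for g in genes if g in keep_sets.get(sp, set())]
                for sp, genes in per.items()
            }
            for og, per in self.groups.items()
        }
        return OrthogroupTable(list(self.species), groups)


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Read OrthoFinder-dialect ``Orthogroups.tsv``.

    First column is the orthogroup ID, one column per species; cells are
    comma+space separated gene IDs or empty. Ragged rows raise a
    :class:`FormatError` naming the line; a gene ID repeated across
    orthogroups triggers a warning and the first occurrence wins.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{path}: empty orthogroup table")
    header = rows[0]
    species = header[1:]
    groups: Dict[str, Dict[str, List[str]]] = {}
    seen_genes: set = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: ragged row at line {lineno}")
        og = row[0]
        per: Dict[str, List[str]] = {}
        for sp, cell in zip(species, row[1:]):
            genes = [g.strip() for g in cell.split(",") if g.strip()] if cell.strip() else []
            kept = []
            for g in genes:
                if g in seen_genes:
                    warnings.warn(
                        f"{path}: gene {g!r} duplicated across orthogroups "
                        f"(line {lineno}); keeping first occurrence"
                    )
                    continue
                seen_genes.add(g)
                kept.append(g)
            per[sp] = kept
        groups[og] = per
    return OrthogroupTable(species, groups)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["Orthogroup"] + table.species)
        for og in table.og_ids:
            w.writerow([og] + [", ".join(table.groups[og][sp]) for sp in table.species])


# -- hit tables -----------------------------------------------------------


@dataclass
class HitTable:
    """Sequence-search hits in one direction (database A queries vs B subjects).

    ``data`` columns: query, subject, evalue, bitscore. Repeated
    (query, subject) pairs collapse to the best hit (lowest e-value, then
    highest bitscore).
    """

    data: pd.DataFrame
    direction: Tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        required = ["query", "subject", "evalue", "bitscore"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"hit table missing columns {missing}")
        if (self.data["evalue"] < 0).any():
            raise FormatError("negative e-value in hit table")
        df = self.data.sort_values(
            ["query", "subject", "evalue", "bitscore"],
            ascending=[True, True, True, False],
        ).drop_duplicates(["query", "subject"], keep="first")
        self.data = df.reset_index(drop=True)

    def best_per_query(self) -> pd.DataFrame:
        """Best hit per query: lowest e-value, ties by higher bitscore then
        lexicographic subject ID."""
        df = self.data.sort_values(
            ["query", "evalue", "bitscore", "subject"],
            ascending=[True, True, False, True],
        )
        return df.drop_duplicates("query", keep="first").set_index("query")


def read_hit_table(path: str | Path, direction: Tuple[str, str] = ("A", "B")) -> HitTable:
    """Read a headered TSV with columns qseqid, sseqid, evalue, bitscore
    (BLAST outfmt-6 compatible subset)."""
    df = pd.read_csv(path, sep="\t")
    rename = {"qseqid": "query", "sseqid": "subject"}
    df = df.rename(columns=rename)
    return HitTable(df[["query", "subject", "evalue", "bitscore"]], direction)


def write_hit_table(table: HitTable, path: str | Path) -> None:
    out = table.data.rename(columns={"query": "qseqid", "subject": "sseqid"})
    out.to_csv(path, sep="\t", index=False)


# -- domain tables --------------------------------------------------------


@dataclass
class DomainTable:
    """Per-gene Pfam-style domain hits (gene, accession, evalue)."""

    data: pd.DataFrame
    isoform_map: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        required = ["gene", "accession", "evalue"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"domain table missing columns {missing}")
        if (self.data["evalue"] < 0).any():
            raise FormatError("negative e-value in domain table")
        bad = self.data.loc[~self.data["accession"].str.match(r"PF\d+(\.\d+)?$"), "accession"]
        if len(bad):
            raise FormatError(f"non-Pfam accession(s): {sorted(set(bad))[:5]}")


def read_domain_table(path: str | Path, isoform_map: Optional[Mapping[str, str]] = None) -> DomainTable:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"domain_accession": "accession"})
    return DomainTable(df[["gene", "accession", "evalue"]], isoform_map)


# -- expression -----------------------------------------------------------


@dataclass
class ExpressionTimecourse:
    """Genes x ordered samples with molt-event annotations.

    ``values``: DataFrame (gene IDs x sample names) of non-negative
    expression levels. ``times``: per-sample numeric time (hours or ordinal
    stage index). ``replicate_groups``: per-sample group key; samples in one
    group are replicates of the same stage. ``molt_times``: ordered times at
    which ecdysis occurs, all within the observed range.
    """

    values: pd.DataFrame
    times: np.ndarray
    molt_times: np.ndarray
    replicate_groups: Optional[Sequence[str]] = None
    unit: str = "TPM"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.molt_times = np.asarray(self.molt_times, dtype=float)
        if len(self.times) != self.values.shape[1]:
            raise FormatError("times length must match sample count")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise FormatError("non-finite expression values")
        if (vals < 0).any():
            raise FormatError("negative expression values")
        if self.replicate_groups is None and len(self.times) > 1:
            if not (np.diff(self.times) > 0).all():
                raise FormatError("times must be strictly increasing after collapse")
        if len(self.molt_times) and len(self.times):
            lo, hi = self.times.min(), self.times.max()
            if (self.molt_times < lo).any() or (self.molt_times > hi).any():
                raise FormatError("molt events outside the observed time range")

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)


def read_expression(expr_path: str | Path, meta_path: str | Path) -> ExpressionTimecourse:
    """Read an expression TSV (gene x sample) plus its metadata TSV.

    Metadata columns: ``column`` (sample name), ``time_h`` (numeric), optional
    ``replicate_group``, and ``molt_event`` (0/1 marking samples at ecdysis).
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    meta = meta.set_index("column").loc[list(expr.columns)]
    times = meta["time_h"].to_numpy(dtype=float)
    reps = (
        meta["replicate_group"].astype(str).tolist()
        if "replicate_group" in meta.columns
        else None
    )
    molt_times = (
        meta.loc[meta["molt_event"] == 1, "time_h"].to_numpy(dtype=float)
        if "molt_event" in meta.columns
        else np.array([])
    )
    return ExpressionTimecourse(expr, times, np.unique(molt_times), reps)


# -- structures -----------------------------------------------------------


@dataclass
class StructureChain:
    """Ordered CA trace of one protein domain."""

    residue_ids: np.ndarray
    coords: np.ndarray
    chain_id: str = "A"
    source: str = ""

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.residue_ids) != len(self.coords):
            raise FormatError("residue index / coordinate length mismatch")
        if len(self.coords) < 3:
            raise FormatError("structure chain must have length >= 3")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise FormatError("coordinates must be (n, 3)")
        if not np.isfinite(self.coords).all():
            raise FormatError("non-finite coordinates")
        if not (np.diff(self.residue_ids) > 0).all():
            raise FormatError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.coords)


def read_structure_ca(
    path: str | Path,
    chain: str = "A",
    residue_range: Optional[Tuple[int, int]] = None,
) -> StructureChain:
    """Extract the CA trace of one chain from a PDB file.

    One record per residue; residues outside ``residue_range`` (inclusive)
    are dropped; residues with no CA atom are skipped with a warning.
    Raises ``KeyError`` when the chain is absent.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise KeyError(f"chain {chain!r} not found (have {chain_ids})")
    resids: List[int] = []
    coords: List[np.ndarray] = []
    for residue in model[chain]:
        hetflag, resseq, _icode = residue.id
        if hetflag.strip():
            continue
        if residue_range is not None and not (residue_range[0] <= resseq <= residue_range[1]):
            continue
        if "CA" not in residue:
            warnings.warn(f"{path}: residue {resseq} in chain {chain} has no CA; skipped")
            continue
        resids.append(resseq)
        coords.append(residue["CA"].coord.astype(float))
    return StructureChain(np.array(resids), np.array(coords), chain, str(path))


def write_structure_ca(chain: StructureChain, path: str | Path) -> None:
    """Write a minimal CA-only PDB file (ATOM records, %8.3f coordinates)."""
    with open(path, "w") as fh:
        for serial, (resid, (x, y, z)) in enumerate(
            zip(chain.residue_ids, chain.coords), start=1
        ):
            fh.write(
                f"ATOM  {serial:>5}  CA  ALA {chain.chain_id}{resid:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
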