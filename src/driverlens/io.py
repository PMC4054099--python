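"""Readers and writers for the cohort's external formats.

Supported formats: somatic mutation tables (a minimal MAF dialect or a
simple long TSV), undirected edge lists, gene annotation TSV, long probe
detection-p TSV, wide ternary call matrices, and GCT 1.2 screen files.
All readers are deterministic and order-independent wherever the
underlying data model is a set.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .records import (
    CALL_VALUES,
    ExpressionCallMatrix,
    GeneRecord,
    MutationRecord,
    NO_DATA,
)
from .shrna import ShrnaScreen

logger = logging.getLogger("driverlens")

#: MAF Variant_Classification -> internal mutation class.
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Ins": "frameshift",
    "Frame_Shift_Del": "frameshift",
    "Splice_Site": "splice_site",
    "Silent": "synonymous",
}

_SCORE_COLUMNS = ("sift_damage", "polyphen")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")


def _parse_score(value, column: str, row: int, sift_raw: bool = False) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    score = float(value)
    if sift_raw and column == "sift_damage":
        score = 1.0 - score
    if not (0.0 <= score <= 1.0):
        raise ValidationError(
            f"row {row}: {column} score {score} outside [0, 1]"
        )
    return score


def read_mutation_table(
    path, dialect: str = "simple", sift_raw: bool = False
) -> List[MutationRecord]:
    """Read somatic mutations from a simple TSV or a minimal MAF.

    The MAF dialect requires Hugo_Symbol, Tumor_Sample_Barcode and
    Variant_Classification; the simple dialect requires sample_id,
    gene_id and mutation_class. Optional damage-predictor columns are
    sift_damage, polyphen and mutation_taster in both dialects. Scores
    are damage-oriented in [0, 1]; ``sift_raw=True`` converts canonical
    SIFT scores (damaging near 0) via 1 - score. Exact duplicate rows
    are dropped.
    """
    if dialect not in ("simple", "maf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if dialect == "maf":
        _require_columns(
            df, ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"), path
        )
        sample_col, gene_col = "Tumor_Sample_Barcode", "Hugo_Symbol"
        classes = df["Variant_Classification"].map(
            lambda v: MAF_CLASS_MAP.get(v, "other")
        )
    else:
        _require_columns(df, ("sample_id", "gene_id", "mutation_class"), path)
        sample_col, gene_col = "sample_id", "gene_id"
        classes = df["mutation_class"]

    n_raw = len(df)
    work = df.copy()
    work["_class"] = classes
    work = work.drop_duplicates()
    n_dropped = n_raw - len(work)
    if n_dropped:
        logger.info("%s: dropped %d exact duplicate rows of %d", path, n_dropped, n_raw)

    records = []
    for row_number, (_, row) in enumerate(work.iterrows(), start=1):
        kwargs = {}
        for col in _SCORE_COLUMNS:
            if col in work.columns:
                key = "sift_damage_score" if col == "sift_damage" else "polyphen_score"
                kwargs[key] = _parse_score(row[col], col, row_number, sift_raw=sift_raw)
        if "mutation_taster" in work.columns:
            mt = row["mutation_taster"]
            kwargs["mutation_taster_call"] = None if pd.isna(mt) or mt == "" else mt
        if "conservation" in work.columns:
            kwargs["conservation_score"] = _parse_score(
                row["conservation"], "conservation", row_number
            )
        records.append(
            MutationRecord(
                sample_id=row[sample_col],
                gene_id=row[gene_col],
                mutation_class=row["_class"],
                **kwargs,
            )
        )
    logger.info("%s: read %d mutation records", path, len(records))
    return records


def write_mutation_table(mutations: Iterable[MutationRecord], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "gene_id": m.gene_id,
            "mutation_class": m.mutation_class,
            "sift_damage": m.sift_damage_score,
            "polyphen": m.polyphen_score,
            "mutation_taster": m.mutation_taster_call,
            "conservation": m.conservation_score,
        }
        for m in mutations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def network_from_edges(edges: Iterable[Tuple[str, str]]) -> nx.Graph:
    """Undirected simple graph: duplicate edges (either orientation)
    collapsed, self-loops removed."""
    graph = nx.Graph()
    n_loops = 0
    for a, b in edges:
        if a == b:
            n_loops += 1
            graph.add_node(a)
            continue
        graph.add_edge(a, b)
    if n_loops:
        logger.info("removed %d self-loop edges", n_loops)
    return graph


def read_network(path) -> nx.Graph:
    """Read an undirected interaction network from a 2+ column edge list.

    Extra columns are ignored; a single-column line is a format error.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2 or not fields[1].strip():
                raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            edges.append((fields[0].strip(), fields[1].strip()))
    if not edges:
        raise FormatError(f"{path}: empty network file")
    graph = network_from_edges(edges)
    logger.info(
        "%s: network with %d nodes, %d edges", path, graph.number_of_nodes(),
        graph.number_of_edges(),
    )
    return graph


def write_network(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            fh.write(f"{node}\t{node}\n")  # re-read drops the loop, keeps the node


def read_gene_table(path) -> Dict[str, GeneRecord]:
    """Gene annotation TSV -> gene_id -> GeneRecord (blank = missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("gene_id", "coding_length_bp"), path)
    genes: Dict[str, GeneRecord] = {}
    for _, row in df.iterrows():
        gene_id = row["gene_id"]
        if gene_id in genes:
            raise ValidationError(f"{path}: duplicate gene_id {gene_id!r}")

        def _opt(col):
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) or v == "" else v

        genes[gene_id] = GeneRecord(
            gene_id=gene_id,
            symbol=_opt("symbol") or gene_id,
            coding_length_bp=int(row["coding_length_bp"]),
            gene_class=_opt("gene_class") or "other_mutated",
            origin_epoch=_opt("origin_epoch"),
            duplicability=_opt("duplicability"),
            n_cancer_types_mutated=int(_opt("n_cancer_types_mutated") or 0),
        )
    return genes


def write_gene_table(genes: Dict[str, GeneRecord], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "symbol": g.symbol,
            "coding_length_bp": g.coding_length_bp,
            "gene_class": g.gene_class,
            "origin_epoch": g.origin_epoch or "",
            "duplicability": g.duplicability or "",
            "n_cancer_types_mutated": g.n_cancer_types_mutated,
        }
        for g in sorted(genes.values(), key=lambda g: g.gene_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_probe_detection(path) -> pd.DataFrame:
    """Long probe detection table: probe_id, gene_id, context_id, detection_p."""
    df = pd.read_csv(path, sep="\t", dtype={"detection_p": float})
    _require_columns(df, ("probe_id", "gene_id", "context_id", "detection_p"), path)
    bad = df[(df["detection_p"] < 0) | (df["detection_p"] > 1)]
    if len(bad):
        raise ValidationError(
            f"{path}: detection_p outside [0, 1] at row {bad.index[0] + 1}"
        )
    if df.duplicated(subset=["probe_id", "context_id"]).any():
        raise ValidationError(f"{path}: duplicate (probe_id, context_id) pair")
    return df


def write_probe_detection(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_call_matrix(path, level_path=None) -> ExpressionCallMatrix:
    """Wide TSV of ternary calls (contexts as rows, genes as columns)."""
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    calls.index = calls.index.astype(str)
    calls.index.name = None
    calls.columns.name = None
    bad = set(pd.unique(calls.values.ravel())) - set(CALL_VALUES)
    if bad:
        raise FormatError(f"{path}: invalid call values {sorted(bad)!r}")
    level = None
    if level_path is not None:
        level = pd.read_csv(level_path, sep="\t", index_col=0)
        level.index = level.index.astype(str)
        level.index.name = None
        level.columns.name = None
    return ExpressionCallMatrix(calls=calls, level=level)


def write_call_matrix(matrix: ExpressionCallMatrix, path, level_path=None) -> None:
    out = matrix.calls.sort_index(axis=0).sort_index(axis=1)
    out.to_csv(path, sep="\t", index_label="context_id")
    if level_path is not None and matrix.level is not None:
        lvl = matrix.level.sort_index(axis=0).sort_index(axis=1)
        lvl.to_csv(level_path, sep="\t", index_label="context_id")


def read_gct(path, probe_to_gene: Optional[Dict[str, str]] = None) -> ShrnaScreen:
    """Read a GCT 1.2 probe x condition matrix.

    The gene of each probe is taken from the Description column, or from
    the optional sidecar ``probe_to_gene`` map; probes with neither keep
    a missing gene and a warning is logged.
    """
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed dimensions line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["Name", "Description"]:
            raise FormatError(f"{path}: header must start with Name\\tDescription")
        conditions = header[2:]
        if len(conditions) != n_cols:
            raise FormatError(
                f"{path}: declared {n_cols} conditions, header has {len(conditions)}"
            )
        names, descriptions, values = [], [], []
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2 + n_cols:
                raise FormatError(f"{path}: row {fields[0]!r} has wrong column count")
            names.append(fields[0])
            descriptions.append(fields[1])
            values.append([float(v) for v in fields[2:]])
    if len(names) != n_rows:
        raise FormatError(f"{path}: declared {n_rows} rows, found {len(names)}")
    scores = pd.DataFrame(values, index=names, columns=conditions)
    gene_map: Dict[str, Optional[str]] = {}
    for probe, desc in zip(names, descriptions):
        gene = desc if desc else None
        if gene is None and probe_to_gene is not None:
            gene = probe_to_gene.get(probe)
        if gene is None:
            logger.warning("probe %s has no gene mapping; retained with gene=missing", probe)
        gene_map[probe] = gene
    return ShrnaScreen(scores=scores, probe_to_gene=gene_map)


def write_gct(screen: ShrnaScreen, path) -> None:
    scores = screen.scores
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{scores.shape[0]}\t{scores.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(scores.columns) + "\n")
        for probe in scores.index:
            gene = screen.probe_to_gene.get(probe) or ""
            row = "\t".join(repr(float(v)) for v in scores.loc[probe])
            fh.write(f"{probe}\t{gene}\t{row}\n")


def read_group_map(path) -> Dict[str, str]:
    """Replicate-group map TSV: condition_id, group_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ("condition_id", "group_id"), path)
    return dict(zip(df["condition_id"], df["group_id"]))


def write_group_map(condition_to_group: Dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(condition_to_group.items()), columns=["condition_id", "group_id"]
    ).to_csv(path, sep="\t", index=False)


def read_known_set(path) -> frozenset:
    """One gene id per line."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_known_set(known: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(known):
            fh.write(f"{gene}\n")
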