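"""Readers and writers for the pipeline's external text formats.

Formats handled:

* per-species quantification tables (TSV; accession + per-replicate
  unique-peptide-count and abundance columns),
* ortholog maps (two-column TSV: species accession, reference accession),
* complex databases in the CORUM dialect (TSV with a semicolon-delimited
  subunit column),
* binary PPI edge lists (two-column TSV),
* FASTA protein sequences,
* output TSVs for score matrices, cluster assignments and filter reports.

Column names in the quant-table reader are configuration-driven because
search-engine exports rename columns between releases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import (
    ClusterAssignment,
    ComplexDefinition,
    ComplexScoreMatrix,
    DataModelError,
    OrthologMap,
    SpeciesQuantTable,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantTableSchema:
    """Column-name conventions for a quant-table TSV.

    Replicate columns are ``{peptide_prefix}{i}`` / ``{abundance_prefix}{i}``
    for i = 1..n_replicates (n inferred from the header).
    """

    accession: str = "accession"
    peptide_prefix: str = "unique_peptides_rep"
    abundance_prefix: str = "abundance_rep"


def read_quant_table(
    path: str | Path, species_id: str, schema: QuantTableSchema = QuantTableSchema()
) -> SpeciesQuantTable:
    """Parse one species' protein quantification TSV.

    Blank abundance cells become missing (NaN), never zero. Duplicate
    accessions and negative values are rejected with the offending
    accession / row number named.
    """
    df = pd.read_csv(path, sep="\t", dtype={schema.accession: str})
    if schema.accession not in df.columns:
        raise DataModelError(f"{path}: missing accession column {schema.accession!r}")
    pep_cols = sorted(
        (c for c in df.columns if c.startswith(schema.peptide_prefix)),
        key=lambda c: int(c[len(schema.peptide_prefix):]),
    )
    ab_cols = sorted(
        (c for c in df.columns if c.startswith(schema.abundance_prefix)),
        key=lambda c: int(c[len(schema.abundance_prefix):]),
    )
    if not pep_cols or len(pep_cols) != len(ab_cols):
        raise DataModelError(f"{path}: replicate columns missing or unpaired")
    dup = df[schema.accession][df[schema.accession].duplicated()]
    if len(dup):
        raise DataModelError(f"{path}: duplicate accession {dup.iloc[0]!r}")
    for col in pep_cols + ab_cols:
        bad = df.index[df[col] < 0]
        if len(bad):
            raise DataModelError(f"{path}: negative value in row {bad[0] + 2} ({col})")
    idx = pd.Index(df[schema.accession], name="accession")
    peptides = df[pep_cols].astype(int)
    peptides.index = idx
    peptides.columns = [f"rep{i + 1}" for i in range(len(pep_cols))]
    abundance = df[ab_cols].astype(float)
    abundance.index = idx
    abundance.columns = list(peptides.columns)
    return SpeciesQuantTable(species=species_id, peptides=peptides, abundance=abundance)


def write_quant_table(
    table: SpeciesQuantTable, path: str | Path, schema: QuantTableSchema = QuantTableSchema()
) -> None:
    out = pd.DataFrame({schema.accession: table.accessions})
    for i in range(table.n_replicates):
        out[f"{schema.peptide_prefix}{i + 1}"] = table.peptides.iloc[:, i].to_numpy()
    for i in range(table.n_replicates):
        out[f"{schema.abundance_prefix}{i + 1}"] = table.abundance.iloc[:, i].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Two-column TSV (species accession, reference accession), header required."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataModelError(f"{path}: ortholog map needs two columns")
    key, val = df.columns[:2]
    dup = df[key][df[key].duplicated()]
    if len(dup):
        raise DataModelError(f"{path}: accession {dup.iloc[0]!r} mapped twice")
    return OrthologMap(dict(zip(df[key], df[val])))


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    pd.DataFrame(
        sorted(omap.pairs.items()), columns=["species_accession", "reference_accession"]
    ).to_csv(path, sep="\t", index=False)


def read_complex_db(
    path: str | Path,
    id_column: str = "complex_id",
    name_column: str = "complex_name",
    subunit_column: str = "subunits",
    subunit_sep: str = ";",
) -> list[ComplexDefinition]:
    """Parse a CORUM-dialect complex TSV into complex definitions.

    Duplicate subunits within a row are deduplicated; duplicate complex
    ids across rows are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (id_column, subunit_column):
        if col not in df.columns:
            raise DataModelError(f"{path}: missing column {col!r}")
    seen: set[str] = set()
    out: list[ComplexDefinition] = []
    for i, row in df.iterrows():
        cid = row[id_column]
        if cid in seen:
            raise DataModelError(f"{path}: duplicate complex id {cid!r}")
        seen.add(cid)
        raw = row[subunit_column]
        members = frozenset(
            m.strip() for m in str(raw).split(subunit_sep) if m and m.strip()
        ) if pd.notna(raw) else frozenset()
        if not members:
            raise DataModelError(f"{path}: complex {cid!r} (row {i + 2}) has no subunits")
        name = row[name_column] if name_column in df.columns else cid
        out.append(ComplexDefinition(complex_id=cid, name=name, members=members))
    return out


def write_complex_db(complexes: list[ComplexDefinition], path: str | Path) -> None:
    rows = [
        {
            "complex_id": c.complex_id,
            "complex_name": c.name,
            "subunits": ";".join(sorted(c.members)),
        }
        for c in complexes
    ]
    pd.DataFrame(rows, columns=["complex_id", "complex_name", "subunits"]).to_csv(
        path, sep="\t", index=False
    )


def read_ppi_edges(path: str | Path):
    """Parse a two-column edge list into a simple undirected graph.

    Self-loops are dropped (count logged) and duplicate pairs in either
    orientation are collapsed.
    """
    import networkx as nx

    graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise DataModelError(f"{path}: malformed line {lineno}: {line!r}")
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-interaction(s) from %s", n_self, path)
    graph.graph["n_self_loops_dropped"] = n_self
    return graph


def write_ppi_edges(graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records keyed by the first whitespace token of the header.

    Sequences are upper-cased and a terminal ``*`` stop is stripped.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in out:
            raise DataModelError(f"{path}: duplicate accession {acc!r}")
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise DataModelError(f"{path}: empty sequence for {acc!r}")
        out[acc] = seq
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in sequences.items():
            fh.write(f">{acc}\n{seq}\n")


def write_score_matrix(matrix: ComplexScoreMatrix, path: str | Path) -> None:
    """Score-matrix TSV: id, name, size, then per-species score and coverage."""
    out = pd.DataFrame(index=matrix.scores.index)
    out["complex_id"] = matrix.scores.index
    out["complex_name"] = matrix.names
    out["size"] = matrix.sizes
    for sp in matrix.scores.columns:
        out[f"score_{sp}"] = matrix.scores[sp]
    for sp in matrix.coverage.columns:
        out[f"coverage_{sp}"] = matrix.coverage[sp]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_score_matrix(path: str | Path) -> ComplexScoreMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"complex_id": str, "complex_name": str})
    df = df.set_index("complex_id", drop=False)
    df.index.name = "complex_id"
    species = [c[len("score_"):] for c in df.columns if c.startswith("score_")]
    scores = df[[f"score_{s}" for s in species]].astype(float)
    scores.columns = species
    coverage = df[[f"coverage_{s}" for s in species]].astype(float)
    coverage.columns = species
    return ComplexScoreMatrix(
        scores=scores,
        coverage=coverage,
        names=df["complex_name"].rename(None),
        sizes=df["size"].astype(int).rename(None),
    )


def write_cluster_assignment(assignment: ClusterAssignment, path: str | Path) -> None:
    out = pd.DataFrame(
        {"item": assignment.labels.index, "cluster": assignment.labels.to_numpy()}
    )
    header = {"k": assignment.k, "method": assignment.method, "seed": assignment.seed}
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(header)}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_cluster_assignment(path: str | Path) -> ClusterAssignment:
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("# ").strip())
        df = pd.read_csv(fh, sep="\t", dtype={"item": str})
    labels = pd.Series(df["cluster"].to_numpy(dtype=int), index=pd.Index(df["item"], name="item"))
    return ClusterAssignment(
        labels=labels, k=int(header["k"]), method=header["method"], seed=header["seed"]
    )


def write_reference_matrix(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="reference_accession", float_format="%.17g")


def read_reference_matrix(path: str | Path):
    from .datatypes import ReferenceQuantMatrix

    df = pd.read_csv(path, sep="\t", index_col="reference_accession")
    return ReferenceQuantMatrix(values=df.astype(float))


def write_run_log(path: str | Path, params: dict, counts: dict) -> None:
    """Run-level JSON log of parameters and per-stage record counts."""
    with open(path, "w") as fh:
        json.dump({"parameters": params, "counts": counts}, fh, indent=2, default=str)
        fh.write("\n")
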