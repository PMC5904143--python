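"""Readers and writers for expression matrices, regulon tables and networks.

Supported formats: dense TSV/CSV (genes in rows, header row of cell ids,
first column of gene ids), MatrixMarket MTX with one-id-per-line gene/cell
sidecar files, TRRUST-style four-column regulon tables, SIF and GraphML
network exports, and an HDF5 container for decomposition results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .metric import ExpressionMatrix

__all__ = [
    "RegulonSet",
    "read_expression",
    "write_expression",
    "read_regulons",
    "write_network_sif",
    "write_network_graphml",
]


@dataclass
class RegulonSet:
    """Mapping from transcription factors to their annotated target genes."""

    regulons: dict[str, set[str]]
    modes: dict[tuple[str, str], str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for tf, targets in self.regulons.items():
            if not tf:
                raise ValueError("empty TF id in regulon set")
            if any(not t for t in targets):
                raise ValueError(f"empty target id in regulon of {tf!r}")

    def known_genes(self) -> set[str]:
        """All gene ids the regulon table knows about (TFs and targets)."""
        genes = set(self.regulons)
        for targets in self.regulons.values():
            genes |= targets
        return genes

    def __len__(self) -> int:
        return len(self.regulons)


def read_expression(path, fmt: str = "tsv", *, gene_file=None, cell_file=None,
                    transpose: bool = False) -> ExpressionMatrix:
    """Read a labeled genes-by-cells expression matrix.

    ``fmt`` is one of ``tsv``, ``csv`` or ``mtx``; MTX requires the
    ``gene_file``/``cell_file`` sidecars (one id per line).  Rows are genes
    and columns are cells unless ``transpose`` is set; orientation is never
    guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in {path}")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing/ragged value at gene {df.index[i]!r}, "
                f"cell {df.columns[j]!r} in {path}"
            )
        gene_ids, cell_ids = df.index.astype(str), df.columns.astype(str)
    elif fmt == "mtx":
        if gene_file is None or cell_file is None:
            raise ValueError("MTX input requires gene_file and cell_file sidecars")
        for side in (gene_file, cell_file):
            if not Path(side).exists():
                raise FileNotFoundError(f"sidecar file not found: {side}")
        mat = sio.mmread(path)
        values = mat.toarray() if sp.issparse(mat) else np.asarray(mat)
        gene_ids = Path(gene_file).read_text().split()
        cell_ids = Path(cell_file).read_text().split()
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    if transpose:
        values = np.asarray(values).T
        gene_ids, cell_ids = cell_ids, gene_ids
    return ExpressionMatrix(np.asarray(values, dtype=float), gene_ids, cell_ids)


def write_expression(X: ExpressionMatrix, path, fmt: str = "tsv", *,
                     gene_file=None, cell_file=None) -> None:
    """Write an expression matrix as TSV/CSV or MTX with label sidecars."""
    path = Path(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        pd.DataFrame(X.values, index=X.gene_ids, columns=X.cell_ids).to_csv(
            path, sep=sep
        )
    elif fmt == "mtx":
        if gene_file is None or cell_file is None:
            raise ValueError("MTX output requires gene_file and cell_file sidecars")
        sio.mmwrite(str(path), sp.coo_matrix(X.values))
        Path(gene_file).write_text("\n".join(map(str, X.gene_ids)) + "\n")
        Path(cell_file).write_text("\n".join(map(str, X.cell_ids)) + "\n")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


_REGULON_HEADER_HINTS = {"tf", "factor", "source", "regulator"}


def read_regulons(path) -> RegulonSet:
    """Parse a TRRUST-style tab-separated TF/target/mode/reference table.

    A header line is auto-detected from its first field.  Modes
    (Activation/Repression/Unknown) are retained as edge attributes but do
    not enter enrichment scoring.  Duplicate TF-target rows collapse to a
    single target entry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"regulon file not found: {path}")
    regulons: dict[str, set[str]] = {}
    modes: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 tab-separated "
                    f"fields, got {len(fields)}"
                )
            if lineno == 1 and fields[0].strip().lower() in _REGULON_HEADER_HINTS:
                continue
            tf, tg = fields[0].strip(), fields[1].strip()
            if not tf or not tg:
                raise ValueError(f"{path}:{lineno}: empty TF or target id")
            regulons.setdefault(tf, set()).add(tg)
            if len(fields) >= 3 and fields[2].strip():
                modes[(tf, tg)] = fields[2].strip()
    return RegulonSet(regulons=regulons, modes=modes, provenance=str(path))


def write_network_sif(network, path) -> None:
    """Write per-archetype TF->TG edges as SIF (one file, archetype column)."""
    lines = []
    for arch in sorted(network.edges):
        for tf, tg, _p in network.edges[arch]:
            lines.append(f"{tf}\tregulates\t{tg}\tarchetype_{arch}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_network_graphml(network, path) -> None:
    """Write the network as GraphML with node roles and edge p-values."""
    import networkx as nx

    G = nx.DiGraph()
    for arch in sorted(network.edges):
        for tf, tg, p in network.edges[arch]:
            G.add_node(tf, role="TF")
            if tg not in G or G.nodes[tg].get("role") != "TF":
                G.add_node(tg, role="TG")
            G.add_edge(tf, tg, p_value=float(p), archetype=int(arch))
    nx.write_graphml(G, path)
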