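"""Delimited-text and network-file I/O.

Omics matrices travel as comma- or tab-delimited text with a header row of
feature identifiers and a leading subject-id column. Networks are exported
as SIF plus GraphML (Cytoscape-importable) with edge weight/sign and node
kind/degree attributes, alongside a delimited node-attribute table.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

from .containers import DataError, OmicsBlock
from .network import TrimmedNetwork


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    return "\t" if sample.count("\t") > sample.count(",") else ","


def read_omics_table(
    path, kind: str, run_day: Optional[pd.Series] = None
) -> OmicsBlock:
    """Parse a subjects x features delimited matrix into an OmicsBlock.

    The delimiter (comma or tab) is autodetected; blank, NA and NaN tokens
    become missing values. Duplicate ids, ragged rows and non-numeric cells
    raise a parse error naming the offending location.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader)
        width = len(header)
        feature_names = header[1:]
        dup_features = {f for f in feature_names if feature_names.count(f) > 1}
        if dup_features:
            raise DataError(
                f"{path.name}: duplicate feature id(s) {sorted(dup_features)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != width:
                raise DataError(
                    f"{path.name}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {width})"
                )
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=["", "NA", "NaN", "nan"]
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path.name}: duplicate subject id(s) {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise DataError(f"{path.name}: duplicate feature id(s) {dups}")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad) > 0:
                raise DataError(
                    f"{path.name}: non-numeric cell at subject {bad[0]!r}, "
                    f"feature {col!r}"
                )
            df[col] = coerced
    return OmicsBlock(df.astype(float), kind, run_day)


def write_omics_table(block: OmicsBlock, path) -> None:
    block.data.to_csv(path)


def to_graph(net: TrimmedNetwork, node_r: Optional[dict] = None) -> nx.Graph:
    """networkx Graph with the exporter's node/edge attributes."""
    g = nx.Graph()
    index_to_id = dict(zip(net.node_indices.tolist(), net.node_ids))
    for fid, kind in zip(net.node_ids, net.node_kinds):
        attrs = {"kind": kind, "degree": net.degrees[fid]}
        if node_r is not None and fid in node_r:
            attrs["r"] = float(node_r[fid])
        g.add_node(fid, **attrs)
    for i, j, w, sign in net.edges:
        g.add_edge(index_to_id[i], index_to_id[j], weight=float(w), sign=int(sign))
    return g


def write_network(
    net: TrimmedNetwork,
    outdir,
    basename: str = "network",
    node_r: Optional[dict] = None,
) -> dict:
    """Write SIF, GraphML and a node-attribute table for one network."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = to_graph(net, node_r)

    sif_path = outdir / f"{basename}.sif"
    with open(sif_path, "w") as fh:
        for u, v, data in g.edges(data=True):
            rel = "pos" if data["sign"] >= 0 else "neg"
            fh.write(f"{u}\t{rel}\t{v}\n")

    graphml_path = outdir / f"{basename}.graphml"
    nx.write_graphml(g, graphml_path)

    nodes_path = outdir / f"{basename}_nodes.tsv"
    rows = [
        {"feature_id": fid, **g.nodes[fid]}
        for fid in net.node_ids
    ]
    pd.DataFrame(rows).to_csv(nodes_path, sep="\t", index=False)
    return {
        "sif": str(sif_path),
        "graphml": str(graphml_path),
        "nodes": str(nodes_path),
    }
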