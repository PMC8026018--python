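"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV (first column = gene id, remaining columns
= samples) with a two-column sample→group companion file.  Pathway
membership uses GMT (set id, description, member genes, tab-separated).
Graphs are weighted edge-list TSVs.  Everything round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd
import yaml


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV; first column holds gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: expression table has no sample columns")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_groups(path: str | Path) -> pd.Series:
    """Read the two-column sample→group TSV into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns (sample, group)")
    return df.set_index(df.columns[0])[df.columns[1]]


def write_groups(groups: Mapping[str, str] | pd.Series, path: str | Path) -> None:
    s = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    s.rename_axis("sample").rename("group").to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {set id: member genes}. Descriptions are dropped."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line: {line!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set id {name!r}")
            sets[name] = set(fields[2:])
    return sets


def write_gmt(pathways: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            members = sorted(pathways[name])
            fh.write("\t".join([name, name] + members) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a weighted edge-list TSV (source, target, weight) into a Graph."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for a, b, w in df.itertuples(index=False):
        g.add_edge(a, b, weight=float(w))
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {"source": a, "target": b, "weight": d.get("weight", 1.0)}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
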