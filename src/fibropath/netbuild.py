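"""Gene map and pathway network construction, with topology diagnostics.

The gene map is a weighted undirected gene-gene graph whose edge weight
sums the per-network-type functional weights for a pair (co-expression,
physical interaction, pathway co-membership).  The pathway network links
two pathways by the number of genes they share.  Because the walk engine
routes along shortest paths with edge length 1/weight, hubs with high
betweenness and strength dominate unguided walks; the topology profile
flags the top fraction of pathways by betweenness and by degree so those
topology-favored results can be told apart from map-driven ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


def build_gene_map(functional_records: pd.DataFrame) -> nx.Graph:
    """Aggregate per-type functional weights into one gene-gene graph.

    One edge per unordered gene pair; its weight is the sum of that pair's
    weights across network types.  Duplicate (pair, type) rows — including
    reversed duplicates — are rejected.
    """
    required = {"gene_a", "gene_b", "network_type", "weight"}
    if not required <= set(functional_records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    g = nx.Graph()
    seen: set[tuple[str, str, str]] = set()
    for a, b, t, w in functional_records[
        ["gene_a", "gene_b", "network_type", "weight"]
    ].itertuples(index=False):
        if a == b:
            raise ValueError(f"self-pair record for gene {a!r}")
        if not 0.0 < w <= 1.0:
            raise ValueError(f"weight {w} outside (0, 1] for pair ({a}, {b})")
        key = (min(a, b), max(a, b), t)
        if key in seen:
            raise ValueError(f"duplicate (pair, type) record: {key}")
        seen.add(key)
        if g.has_edge(a, b):
            g[a][b]["weight"] += float(w)
        else:
            g.add_edge(a, b, weight=float(w))
    return g


def build_pathway_network(pathways: Mapping[str, set[str]]) -> nx.Graph:
    """Link pathways by shared-gene counts; zero-overlap pairs get no edge.

    Nodes carry their member-gene sets in the ``members`` attribute, so
    downstream stages (target selection, linkage) need no second lookup.
    """
    names = list(pathways)
    if len(names) != len(set(names)):
        raise ValueError("duplicate pathway ids")
    g = nx.Graph()
    for name in names:
        members = set(pathways[name])
        if len(members) < 2:
            raise ValueError(f"pathway {name!r} has fewer than 2 members")
        g.add_node(name, members=members)
    for a, b in combinations(names, 2):
        shared = len(pathways[a] & pathways[b])
        if shared >= 1:
            g.add_edge(a, b, weight=float(shared))
    return g


@dataclass
class TopologyProfile:
    """Per-pathway betweenness, strength and degree with top-fraction flags."""

    table: pd.DataFrame  # pathway, betweenness, strength, degree + flags
    top_betweenness: list[str]
    top_degree: list[str]


def _top_frac(series: pd.Series, frac: float) -> list[str]:
    import math

    k = math.ceil(frac * len(series))
    # sort by value descending, ties by id ascending — deterministic
    ranked = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]


def topology_profile(network: nx.Graph, top_frac: float = 0.05) -> TopologyProfile:
    """Weighted betweenness (edge length = 1/weight), strength and degree.

    The inverse-weight length convention matches the walk engine, so the
    flagged hubs are exactly the nodes shortest-path traffic favors.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    for a, b, d in network.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    betw = nx.betweenness_centrality(network, weight="length", normalized=False)
    strength = {
        n: sum(d["weight"] for _, _, d in network.edges(n, data=True))
        for n in network.nodes
    }
    degree = dict(network.degree())
    df = pd.DataFrame(
        {
            "pathway": sorted(network.nodes),
            "betweenness": [betw[n] for n in sorted(network.nodes)],
            "strength": [strength[n] for n in sorted(network.nodes)],
            "degree": [degree[n] for n in sorted(network.nodes)],
        }
    )
    top_b = _top_frac(df.set_index("pathway")["betweenness"], top_frac)
    top_d = _top_frac(df.set_index("pathway")["degree"].astype(float), top_frac)
    df["top_betweenness"] = df["pathway"].isin(top_b)
    df["top_degree"] = df["pathway"].isin(top_d)
    return TopologyProfile(df, top_b, top_d)


def map_gene_ids(
    genes: Iterable[str], mapping: Mapping[str, str]
) -> tuple[list[str], int]:
    """Translate gene symbols via a lookup table; unmapped genes dropped.

    Returns the translated list and the count of dropped ids, so callers
    can log the loss instead of silencing it.
    """
    out, dropped = [], 0
    for g in genes:
        if g in mapping:
            out.append(mapping[g])
        else:
            dropped += 1
    return out, dropped
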