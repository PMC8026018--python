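"""Structural screening of candidates against clinically failed drugs.

Works on fixed-length bit-vector fingerprints.  Candidate-candidate edges
form a base similarity network at Tanimoto >= 0.5; failed drugs attach to
it at the stricter >= 0.7, and every candidate adjacent to a failed drug
is flagged for lower testing priority (advisory — flagged candidates stay
in the output).  A Soergel-distance (1 − Tanimoto) Ward hierarchical
clustering cut at height 1 provides the structural grouping used when
comparing prioritized drugs with the rest of the library.

Ward linkage formally assumes a Euclidean geometry; Soergel distances are
not Euclidean, so the linkage is the stated recipe of the screening
protocol rather than a variance-minimizing optimum.  The caveat is
documented rather than silently substituting another linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


def parse_fingerprint(fp: str) -> np.ndarray:
    if not fp or set(fp) - {"0", "1"}:
        raise ValueError("fingerprint must be a non-empty 0/1 string")
    return np.frombuffer(fp.encode(), dtype=np.uint8) - ord("0")


def fingerprint_matrix(fps: list[str]) -> np.ndarray:
    arrs = [parse_fingerprint(f) for f in fps]
    lengths = {len(a) for a in arrs}
    if len(lengths) != 1:
        raise ValueError(f"fingerprint length mismatch: {sorted(lengths)}")
    return np.vstack(arrs).astype(bool)


def tanimoto(fp_a: str | np.ndarray, fp_b: str | np.ndarray) -> float:
    """|a AND b| / |a OR b| for equal-length bit vectors."""
    a = parse_fingerprint(fp_a) if isinstance(fp_a, str) else np.asarray(fp_a)
    b = parse_fingerprint(fp_b) if isinstance(fp_b, str) else np.asarray(fp_b)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("similarity undefined for two all-zero fingerprints")
    return float(np.logical_and(a, b).sum() / union)


def soergel(fp_a: str | np.ndarray, fp_b: str | np.ndarray) -> float:
    """Soergel distance = 1 − Tanimoto for bit vectors."""
    return 1.0 - tanimoto(fp_a, fp_b)


def tanimoto_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity for a boolean matrix (drugs × bits)."""
    fps = fps.astype(bool)
    if (fps.sum(axis=1) == 0).any():
        raise ValueError("all-zero fingerprint in library")
    inter = fps.astype(np.int64) @ fps.astype(np.int64).T
    on = fps.sum(axis=1)
    union = on[:, None] + on[None, :] - inter
    return inter / union


@dataclass
class SimilarityNetwork:
    """Candidate/failed drug graph with Tanimoto edge weights."""

    graph: nx.Graph  # nodes tagged kind={candidate,failed}

    def candidates(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "candidate"
        )

    def failed(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "failed"
        )


def build_similarity_network(
    candidates: pd.DataFrame,
    failed: pd.DataFrame,
    base_threshold: float = 0.5,
    attach_threshold: float = 0.7,
) -> SimilarityNetwork:
    """Base network of candidates (edges at similarity >= base_threshold)
    with failed drugs attached at similarity >= attach_threshold.

    Failed drugs never link to each other; failed drugs similar to no
    candidate are omitted.  Candidate nodes are always kept, connected or
    not.  Ids must not collide across the two lists.
    """
    cand_ids = candidates["drug_id"].tolist()
    fail_ids = failed["drug_id"].tolist() if len(failed) else []
    collision = set(cand_ids) & set(fail_ids)
    if collision:
        raise ValueError(f"id collision between lists: {sorted(collision)[:5]}")

    all_fps = candidates["fingerprint"].tolist() + (
        failed["fingerprint"].tolist() if len(failed) else []
    )
    fps = fingerprint_matrix(all_fps)
    sim = tanimoto_matrix(fps)
    n_c = len(cand_ids)

    g = nx.Graph()
    for cid in cand_ids:
        g.add_node(cid, kind="candidate")
    for i in range(n_c):
        for j in range(i + 1, n_c):
            if sim[i, j] >= base_threshold:
                g.add_edge(cand_ids[i], cand_ids[j], weight=float(sim[i, j]))
    for k, fid in enumerate(fail_ids):
        row = sim[n_c + k, :n_c]
        hits = np.nonzero(row >= attach_threshold)[0]
        if len(hits) == 0:
            continue
        g.add_node(fid, kind="failed")
        for i in hits:
            g.add_edge(fid, cand_ids[i], weight=float(row[i]))
    return SimilarityNetwork(g)


def flag_failed_similar(network: SimilarityNetwork) -> pd.DataFrame:
    """Candidates adjacent to >= 1 failed drug, with their failed neighbors.

    The flag is advisory (lower testing priority), never an exclusion.
    Returns a table (drug_id, n_failed_neighbors, failed_neighbors).
    """
    g = network.graph
    rows = []
    for cid in network.candidates():
        neighbors = sorted(
            n for n in g.neighbors(cid) if g.nodes[n]["kind"] == "failed"
        )
        if neighbors:
            rows.append(
                {
                    "drug_id": cid,
                    "n_failed_neighbors": len(neighbors),
                    "failed_neighbors": ";".join(neighbors),
                }
            )
    return pd.DataFrame(
        rows, columns=["drug_id", "n_failed_neighbors", "failed_neighbors"]
    )


def ward_cluster(
    fingerprints: pd.Series | dict[str, str],
    distance: str = "soergel",
    threshold: float = 1.0,
) -> pd.Series:
    """Agglomerative Ward clustering on Soergel distances, cut at a height.

    Returns drug_id → integer cluster label (labels renumbered in
    first-appearance order).  Duplicate fingerprints (distance 0) merge
    first by construction.
    """
    if distance != "soergel":
        raise ValueError(f"unknown distance {distance!r}")
    fps = pd.Series(dict(fingerprints)) if not isinstance(fingerprints, pd.Series) else fingerprints
    if len(fps) < 2:
        raise ValueError("need at least 2 fingerprints")
    mat = fingerprint_matrix(fps.tolist())
    dist = 1.0 - tanimoto_matrix(mat)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(z, t=threshold, criterion="distance")
    remap: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
        out.append(remap[lab])
    return pd.Series(out, index=fps.index, name="cluster")
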