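"""Cross-disease synthesis: gene overlaps, shared-drug significance and
drug–target–pathway linkage.

The shared-drug test is the hypergeometric point probability
P(X = x) = C(m, x) C(n, k−x) / C(m+n, k): drawing exactly x of a reference
disease's re-ranked drugs when k drugs are re-ranked for a query disease
out of its m + n unfiltered repurposing hits (m of which the reference
also produced).  The point probability — not an upper tail — is what the
reproduced analysis computed; ``hypergeometric_overlap(..., tail=True)``
offers the conventional P(X >= x) variant for callers who want a proper
enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .diffexpr import GeneSignature


def disease_gene_overlap(
    signatures: Mapping[str, GeneSignature] | list[GeneSignature],
    direction: str,
) -> pd.DataFrame:
    """Symmetric matrix of shared over- or under-expressed gene counts.

    Entry (d1, d2) is the intersection size of the two diseases' lists in
    the given direction; the diagonal holds list sizes.
    """
    if direction not in ("over", "under"):
        raise ValueError(f"unknown direction {direction!r}")
    if not isinstance(signatures, Mapping):
        signatures = {s.disease: s for s in signatures}
    names = sorted(signatures)
    sets = {d: set(getattr(signatures[d], direction)) for d in names}
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for d in names:
        mat.loc[d, d] = len(sets[d])
    for a, b in combinations(names, 2):
        shared = len(sets[a] & sets[b])
        mat.loc[a, b] = shared
        mat.loc[b, a] = shared
    return mat


def _log_comb(n: float, k: np.ndarray | float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(np.asarray(k) + 1) - gammaln(n - np.asarray(k) + 1)


def hypergeometric_overlap(
    x: int, m: int, n: int, k: int, tail: bool = False
) -> float:
    """Hypergeometric probability of sharing exactly x items.

    ``x`` successes in ``k`` draws without replacement from ``m`` marked
    and ``n`` unmarked items, computed in log-gamma space.  With
    ``tail=True`` returns the upper-tail P(X >= x) instead of the point
    probability.
    """
    for name, v in (("x", x), ("m", m), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if k > m + n:
        raise ValueError("cannot draw more items than the population holds")
    if x > min(m, k) or x < max(0, k - n):
        raise ValueError(f"infeasible x={x} for (m={m}, n={n}, k={k})")

    def point(xs: np.ndarray) -> np.ndarray:
        return np.exp(
            _log_comb(m, xs) + _log_comb(n, k - xs) - _log_comb(m + n, k)
        )

    if tail:
        xs = np.arange(x, min(m, k) + 1)
        return float(np.clip(point(xs).sum(), 0.0, 1.0))
    return float(point(np.array([x]))[0])


@dataclass
class OverlapTest:
    """One disease-vs-reference shared-drug test with its parameters."""

    disease: str
    x: int
    m: int
    n: int
    k: int
    p: float


def shared_drug_tests(
    reference_reranked: set[str],
    per_disease: Mapping[str, tuple[set[str], set[str]]],
) -> pd.DataFrame:
    """Shared re-ranked drug significance of each disease vs a reference.

    ``per_disease`` maps disease → (reranked drugs, unfiltered repurposing
    output).  For each disease: x = |reranked ∩ reference reranked|,
    m = |unfiltered ∩ reference reranked|, n = |unfiltered| − m,
    k = |reranked|.
    """
    rows = []
    for disease in sorted(per_disease):
        reranked, unfiltered = per_disease[disease]
        x = len(reranked & reference_reranked)
        m = len(unfiltered & reference_reranked)
        n = len(unfiltered) - m
        k = len(reranked)
        p = hypergeometric_overlap(x, m, n, k)
        rows.append(
            {"disease": disease, "x": x, "m": m, "n": n, "k": k, "p": p}
        )
    return pd.DataFrame(rows, columns=["disease", "x", "m", "n", "k", "p"])


def drug_target_pathway_linkage(
    drug_targets: Mapping[str, set[str]],
    pathway_members: Mapping[str, set[str]],
    highlighted_pathways: list[str],
    key_pathways: list[str] | None = None,
    min_key: int = 2,
    disease: str = "disease",
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Enumerate (disease, pathway, gene, drug) links and prioritize drugs.

    A linkage row exists whenever a drug's target gene belongs to a
    highlighted pathway.  A drug is prioritized when its targets reach at
    least ``min_key`` distinct key pathways (key_pathways ⊆ highlighted).
    Also returns a drug-drug functional-similarity edge list weighted by
    shared in-pathway target genes.
    """
    key_pathways = key_pathways or []
    unknown = set(key_pathways) - set(highlighted_pathways)
    if unknown:
        raise ValueError(f"key pathways not highlighted: {sorted(unknown)}")
    highlighted = [p for p in highlighted_pathways if p in pathway_members]

    rows = []
    in_pathway_targets: dict[str, set[str]] = {}
    key_hits: dict[str, set[str]] = {}
    for drug in sorted(drug_targets):
        targets = drug_targets[drug]
        for p in highlighted:
            hit_genes = sorted(targets & pathway_members[p])
            for g in hit_genes:
                rows.append(
                    {"disease": disease, "pathway": p, "gene": g, "drug": drug}
                )
                in_pathway_targets.setdefault(drug, set()).add(g)
            if hit_genes and p in key_pathways:
                key_hits.setdefault(drug, set()).add(p)

    linkage = pd.DataFrame(rows, columns=["disease", "pathway", "gene", "drug"])
    prioritized = sorted(
        d for d, pws in key_hits.items() if len(pws) >= min_key
    )

    edge_rows = []
    drugs_with_hits = sorted(in_pathway_targets)
    for a, b in combinations(drugs_with_hits, 2):
        shared = len(in_pathway_targets[a] & in_pathway_targets[b])
        if shared:
            edge_rows.append({"drug_a": a, "drug_b": b, "shared_targets": shared})
    similarity = pd.DataFrame(
        edge_rows, columns=["drug_a", "drug_b", "shared_targets"]
    )
    return linkage, prioritized, similarity


def four_layer_export(
    linkage: pd.DataFrame,
) -> dict:
    """Disease → pathway → gene → drug nesting for external viewers."""
    out: dict = {}
    for disease, pathway, gene, drug in linkage.itertuples(index=False):
        out.setdefault(disease, {}).setdefault(pathway, {}).setdefault(
            gene, []
        ).append(drug)
    for d in out.values():
        for p in d.values():
            for g in p:
                p[g] = sorted(set(p[g]))
    return out
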