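"""Signature-inversion candidate filtering and per-cluster re-ranking.

Candidates are drugs whose expression effect opposes the disease
signature: connectivity scores below −50 in any experiment, plus every
entry of the L1000-style lists.  Each candidate gets a drugability score
(fraction of the four Lipinski and two Veber rules satisfied), a composite
score combining functional association, binding affinity and drugability,
and a structural cluster from affinity propagation on Tanimoto
similarities; the best-scoring drug of each cluster is its
representative — the short list handed to the structural screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation

from .chemscreen import fingerprint_matrix, tanimoto_matrix

logger = logging.getLogger(__name__)

LIPINSKI_VEBER_RULES = (
    ("MW", 500.0),
    ("cLogP", 5.0),
    ("HBD", 5.0),
    ("HBA", 10.0),
    ("RotB", 10.0),
    ("TPSA", 140.0),
)


def filter_inhibitors(
    cmap_scores: pd.DataFrame,
    l1000_entries: pd.DataFrame | None = None,
    threshold: float = -50.0,
) -> pd.DataFrame:
    """Candidate set: CMap-style scores strictly below the threshold in any
    experiment, united with every L1000-listed drug.

    Returns a table (drug_id, source, best_score) where source records the
    provenance ("cmap", "l1000" or "cmap+l1000").
    """
    required = {"drug_id", "score"}
    if not required <= set(cmap_scores.columns):
        raise ValueError("cmap_scores needs drug_id and score columns")
    s = cmap_scores["score"]
    if ((s < -100) | (s > 100)).any():
        raise ValueError("connectivity scores must lie in [-100, 100]")

    best = cmap_scores.groupby("drug_id")["score"].min()
    cmap_hits = set(best[best < threshold].index)
    l1000_hits: set[str] = set()
    if l1000_entries is not None and not l1000_entries.empty:
        l1000_hits = set(l1000_entries["drug_id"])

    rows = []
    for did in sorted(cmap_hits | l1000_hits):
        source = "+".join(
            name
            for name, hit in (("cmap", did in cmap_hits), ("l1000", did in l1000_hits))
            if hit
        )
        rows.append(
            {
                "drug_id": did,
                "source": source,
                "best_score": float(best.get(did, np.nan)),
            }
        )
    return pd.DataFrame(rows, columns=["drug_id", "source", "best_score"])


def drugability_score(descriptors: pd.Series | dict) -> float:
    """Fraction of the six oral-drugability rules satisfied (<= boundaries
    count as satisfied): MW <= 500, cLogP <= 5, HBD <= 5, HBA <= 10,
    rotatable bonds <= 10, TPSA <= 140."""
    d = dict(descriptors) if not isinstance(descriptors, dict) else descriptors
    missing = [k for k, _ in LIPINSKI_VEBER_RULES if k not in d or pd.isna(d[k])]
    if missing:
        raise ValueError(f"missing descriptor(s): {missing}")
    satisfied = sum(1 for k, lim in LIPINSKI_VEBER_RULES if d[k] <= lim)
    return satisfied / len(LIPINSKI_VEBER_RULES)


def composite_rank(
    candidates: pd.DataFrame,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> pd.DataFrame:
    """Composite = weighted mean of functional association, binding
    affinity and drugability; descending sort, ties by drug id.

    The exact integration formula of the original re-ranking service is
    unpublished; the weighted mean here is this package's explicit,
    configurable stand-in.
    """
    if not np.isclose(sum(weights), 1.0):
        raise ValueError("weights must sum to 1")
    needed = {"drug_id", "functional_association", "binding_affinity"}
    if not needed <= set(candidates.columns):
        raise ValueError(f"candidates need columns {sorted(needed)}")
    out = candidates.copy()
    if "drugability" not in out.columns:
        out["drugability"] = [
            drugability_score(row)
            for row in out[[k for k, _ in LIPINSKI_VEBER_RULES]].to_dict("records")
        ]
    for col in ("functional_association", "binding_affinity", "drugability"):
        v = out[col]
        if ((v < 0) | (v > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    out["composite"] = (
        weights[0] * out["functional_association"]
        + weights[1] * out["binding_affinity"]
        + weights[2] * out["drugability"]
    )
    return out.sort_values(
        ["composite", "drug_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def cluster_structures(
    candidates: pd.DataFrame,
    damping: float = 0.9,
    max_iter: int = 1000,
    fallback_threshold: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Affinity-propagation clusters on pairwise Tanimoto similarity.

    Preference is the median off-diagonal similarity.  If the algorithm
    fails to converge, clusters fall back to connected components of the
    similarity graph at >= ``fallback_threshold`` (logged).  Returns a
    Series drug_id → integer cluster label (labels renumbered in first-
    appearance order for determinism).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to cluster")
    ids = candidates["drug_id"].tolist()
    all_fps = candidates["fingerprint"].tolist()
    # exact duplicates are one structure: collapse them before message
    # passing (identical points make the updates degenerate) and restore
    # the assignment afterwards
    unique_fps = list(dict.fromkeys(all_fps))
    rep_of = {fp: i for i, fp in enumerate(unique_fps)}
    fps = fingerprint_matrix(unique_fps)
    sim = tanimoto_matrix(fps)

    if len(unique_fps) == 1:
        unique_labels = np.zeros(1, dtype=int)
    else:
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        off = sim[~np.eye(len(unique_fps), dtype=bool)]
        pref = float(np.median(off))
        ap = AffinityPropagation(
            affinity="precomputed",
            damping=damping,
            max_iter=max_iter,
            preference=pref,
            random_state=seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            # a ConvergenceWarning or the "mutually equal similarities"
            # UserWarning both mean the labels are arbitrary
            warnings.simplefilter("always")
            unique_labels = ap.fit_predict(sim)
            converged = not any(
                issubclass(w.category, (ConvergenceWarning, UserWarning))
                for w in caught
            )
        centers = ap.cluster_centers_indices_
        if (
            not converged
            or (unique_labels < 0).any()
            or centers is None
            or len(centers) == 0
        ):
            logger.warning(
                "affinity propagation did not converge; falling back to "
                "connected components at similarity >= %.2f",
                fallback_threshold,
            )
            unique_labels = _component_labels(sim, fallback_threshold)

    labels = [unique_labels[rep_of[fp]] for fp in all_fps]
    remap: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
        out.append(remap[lab])
    return pd.Series(out, index=ids, name="cluster")


def _component_labels(sim: np.ndarray, threshold: float) -> np.ndarray:
    n = sim.shape[0]
    labels = -np.ones(n, dtype=int)
    current = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = current
        while stack:
            u = stack.pop()
            for v in range(n):
                if labels[v] < 0 and sim[u, v] >= threshold:
                    labels[v] = current
                    stack.append(v)
        current += 1
    return labels


@dataclass
class RerankResult:
    """Ranked, clustered candidates with per-cluster representatives."""

    table: pd.DataFrame  # drug_id, composite, drugability, cluster, representative

    @property
    def representatives(self) -> list[str]:
        t = self.table
        return t[t["representative"]]["drug_id"].tolist()


def select_representatives(
    ranked: pd.DataFrame, clusters: pd.Series
) -> RerankResult:
    """Flag the highest-composite drug of each cluster (ties by id)."""
    missing = set(ranked["drug_id"]) - set(clusters.index)
    if missing:
        raise ValueError(f"drugs without a cluster: {sorted(missing)[:5]}")
    out = ranked.copy()
    out["cluster"] = out["drug_id"].map(clusters)
    out["representative"] = False
    for _, group in out.groupby("cluster"):
        best = group.sort_values(
            ["composite", "drug_id"], ascending=[False, True], kind="mergesort"
        ).iloc[0]
        out.loc[out["drug_id"] == best["drug_id"], "representative"] = True
    return RerankResult(out.reset_index(drop=True))


def rerank(
    drugs: pd.DataFrame,
    cmap_scores: pd.DataFrame,
    l1000_entries: pd.DataFrame | None = None,
    cmap_threshold: float = -50.0,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> RerankResult:
    """Full re-ranking stage: filter inhibitors, score, cluster, select."""
    hits = filter_inhibitors(cmap_scores, l1000_entries, threshold=cmap_threshold)
    candidates = drugs[drugs["drug_id"].isin(hits["drug_id"])].copy()
    if len(candidates) < 2:
        raise ValueError("fewer than 2 inhibitor candidates; nothing to rank")
    ranked = composite_rank(candidates, weights=weights)
    clusters = cluster_structures(ranked, seed=seed)
    return select_representatives(ranked, clusters)
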