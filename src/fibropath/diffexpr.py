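"""Differential-expression signature extraction.

Implements the normalization and filtering rules used to turn a
case/control expression matrix into ordered over-/under-expressed gene
lists: quantile normalization for intensity arrays, CPM filtering and TMM
scaling factors for count data, a per-gene Welch two-sample test, and the
signature filter chain (significance cutoff, dual-sign probe removal,
lowest-p duplicate resolution, top-N capping by |logFC|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneSignature:
    """Ordered over-/under-expressed gene lists for one disease."""

    disease: str
    over: list[str]
    under: list[str]
    source_experiments: list[str] = field(default_factory=list)
    provenance: pd.DataFrame | None = None  # gene, experiment, logFC, p


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all columns to share one distribution via sorted-rank means.

    Each column's sorted values are replaced by the row means of the
    column-sorted matrix, so afterwards every column holds the identical
    multiset of values.  Ties within a column are broken by row position
    (stable), which keeps the operation exactly idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite entries")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="ordinal") - 1
        out[:, j] = ref[ranks]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _split_groups(
    matrix: pd.DataFrame, groups: pd.Series
) -> tuple[list[str], list[str]]:
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    case = [s for s in matrix.columns if groups[s] == "case"]
    control = [s for s in matrix.columns if groups[s] == "control"]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 samples")
    return case, control


def _welch_table(
    log2_matrix: pd.DataFrame, case: list[str], control: list[str]
) -> pd.DataFrame:
    a = log2_matrix[case].to_numpy(dtype=float)
    b = log2_matrix[control].to_numpy(dtype=float)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero-variance genes with equal means: no evidence of change
    p = np.where(np.isnan(p), 1.0, p)
    df = pd.DataFrame(
        {
            "gene": log2_matrix.index,
            "logFC": logfc,
            "p": p,
        }
    )
    df["direction"] = np.where(df["logFC"] > 0, "over", "under")
    return df.reset_index(drop=True)


def normalize_and_test(
    matrix: pd.DataFrame,
    groups: pd.Series,
    platform: str = "intensity",
    log2_state: str = "log2",
) -> pd.DataFrame:
    """Normalize an expression matrix and test each gene case vs control.

    Intensity platforms follow the microarray recipe: raw data are
    quantile-normalized then log2-transformed; already-log2 but
    unnormalized data are unlogged, quantile-normalized and re-logged.
    Count platforms are CPM-filtered, TMM-scaled and tested on
    log2(CPM + 0.5).  The per-gene test is a two-sided Welch two-sample
    test on the log2 scale; logFC = mean(case) − mean(control).

    Returns a table with columns gene, logFC, p, direction.
    """
    case, control = _split_groups(matrix, groups)
    if platform == "intensity":
        if log2_state not in ("raw", "log2", "log2_unnormalized"):
            raise ValueError(f"unknown log2_state {log2_state!r}")
        if log2_state == "raw":
            if (matrix.to_numpy() < 0).any():
                raise ValueError("raw intensities must be non-negative")
            norm = quantile_normalize(matrix)
            log2m = np.log2(norm + 1.0)
        elif log2_state == "log2_unnormalized":
            unlogged = 2.0 ** matrix
            norm = quantile_normalize(unlogged)
            log2m = np.log2(norm)
        else:
            log2m = matrix
        return _welch_table(log2m, case, control)
    elif platform == "counts":
        counts = cpm_filter(matrix, groups)
        factors = tmm_factors(counts)
        lib = counts.sum(axis=0) * factors
        cpm = counts / lib * 1e6
        log2m = np.log2(cpm + 0.5)
        return _welch_table(log2m, case, control)
    raise ValueError(f"unknown platform {platform!r}")


def cpm_filter(
    counts: pd.DataFrame,
    groups: pd.Series,
    min_cpm: float = 1.0,
    min_libs: int = 2,
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in >= ``min_libs`` libraries of
    each group (affected and control); row order is preserved."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every library must have a positive total count")
    case, control = _split_groups(counts, groups)
    cpm = counts / lib * 1e6
    keep = pd.Series(True, index=counts.index)
    for cols in (case, control):
        keep &= (cpm[cols] >= min_cpm).sum(axis=1) >= min_libs
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper-quartile.  For each sample, M (log2 ratio vs reference)
    and A (mean log2 abundance) are computed over genes expressed in both;
    the most extreme ``trim_m`` of M and ``trim_a`` of A are discarded on
    each side and the factor is 2 to the inverse-variance-weighted mean of
    the surviving M values.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive total count")

    cpm = mat / lib * 1e6
    uq = np.array([np.quantile(cpm[:, j][cpm[:, j] > 0], 0.75) for j in range(mat.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        log_factors[j] = _tmm_pair(
            mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    mask = (obs > 0) & (ref > 0)
    if mask.sum() == 0:
        return 0.0
    po = obs[mask] / lib_obs
    pr = ref[mask] / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic binomial variance of M (delta method)
    w = (
        (lib_obs - obs[mask]) / (lib_obs * obs[mask])
        + (lib_ref - ref[mask]) / (lib_ref * ref[mask])
    )
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() == 0 or not np.isfinite(w[keep]).all():
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def extract_signature(
    de_results: pd.DataFrame,
    disease: str = "disease",
    alpha: float = 0.05,
    top_n: int = 150,
    experiment: str | None = None,
) -> GeneSignature:
    """Apply the signature filter chain to a per-probe DE table.

    In order: (1) drop rows with p >= ``alpha``; (2) drop genes whose
    surviving rows disagree in logFC sign (dual-sign probes); (3) among
    same-sign duplicates keep the lowest-p row; (4) return the top
    ``top_n`` over- and under-expressed genes ranked by |logFC|.
    An input that empties out yields an empty signature, not an error.
    """
    required = {"gene", "logFC", "p"}
    if not required <= set(de_results.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    sig = de_results[de_results["p"] < alpha].copy()
    if sig.empty:
        return GeneSignature(disease, [], [], provenance=sig)

    signs = sig.groupby("gene")["logFC"].agg(lambda v: set(np.sign(v)))
    dual = signs[signs.apply(lambda s: len(s - {0.0}) > 1)].index
    sig = sig[~sig["gene"].isin(dual)]

    # lowest p per gene; ties broken by |logFC| then row order for determinism
    sig = sig.sort_values(
        ["p", "logFC"], key=lambda c: c.abs() if c.name == "logFC" else c,
        ascending=[True, False], kind="mergesort",
    )
    sig = sig.drop_duplicates("gene", keep="first")

    sig = sig.assign(absfc=sig["logFC"].abs()).sort_values(
        ["absfc", "gene"], ascending=[False, True], kind="mergesort"
    )
    over = sig[sig["logFC"] > 0]["gene"].tolist()[:top_n]
    under = sig[sig["logFC"] < 0]["gene"].tolist()[:top_n]
    prov = sig.drop(columns="absfc").copy()
    if experiment is not None:
        prov["experiment"] = experiment
    return GeneSignature(
        disease,
        over,
        under,
        source_experiments=[experiment] if experiment else [],
        provenance=prov.reset_index(drop=True),
    )


def aggregate_signatures(
    signatures: list[GeneSignature], disease: str
) -> GeneSignature:
    """Union per-experiment signatures into one per-disease signature.

    Genes are ordered by their best (largest) |logFC| across experiments
    where provenance is available, otherwise by first appearance.  A gene
    reported over-expressed in one experiment and under-expressed in
    another is kept in both lists with per-experiment provenance; callers
    wanting an intersection rule can post-filter via the provenance table.
    """
    over: dict[str, float] = {}
    under: dict[str, float] = {}
    prov_frames = []
    experiments: list[str] = []
    for s in signatures:
        experiments.extend(s.source_experiments)
        fc = {}
        if s.provenance is not None and not s.provenance.empty:
            prov_frames.append(s.provenance)
            fc = dict(zip(s.provenance["gene"], s.provenance["logFC"].abs()))
        for g in s.over:
            over[g] = max(over.get(g, 0.0), fc.get(g, 0.0))
        for g in s.under:
            under[g] = max(under.get(g, 0.0), fc.get(g, 0.0))
    order = lambda d: [g for g, _ in sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))]
    prov = pd.concat(prov_frames, ignore_index=True) if prov_frames else None
    return GeneSignature(disease, order(over), order(under), experiments, prov)
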