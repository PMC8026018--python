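"""Odds-ratio significance of guided vs unguided walk tallies.

For each pathway, Freq = timesWalked / totalTimesWalked within one
execution, Odds = Freq / (1 − Freq), and OddsRatio = guided odds over
unguided odds.  A Pearson chi-square test (1 df, no continuity
correction) on the 2×2 visit/non-visit table, Benjamini–Hochberg adjusted
across all pathways of the run, gives the per-pathway p-value; a pathway
is called significant when OddsRatio > 1.3 and adjusted p < .05 (both
strict, the thresholds the analysis is anchored to).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pathwalks import WalkCounts

logger = logging.getLogger(__name__)


def compute_odds_ratios(
    guided: WalkCounts,
    random: WalkCounts,
    zero_correction: float = 0.5,
) -> pd.DataFrame:
    """Per-pathway frequencies, odds and odds ratios of guided vs random.

    Pathways the random run never visited get a Haldane-style correction:
    ``zero_correction`` is added to all four cells of that pathway's 2×2
    table before the odds are formed (logged, and recorded in the
    ``corrected`` column).  Pathways with zero guided frequency keep
    Odds = 0 and OddsRatio = 0.
    """
    if set(guided.times_walked) != set(random.times_walked):
        raise ValueError("guided and random runs cover different pathway sets")
    g_total = guided.total_times_walked
    r_total = random.total_times_walked
    if g_total <= 0 or r_total <= 0:
        raise ValueError("both executions must have positive totals")

    rows = []
    n_corrected = 0
    for p in sorted(guided.times_walked):
        g, r = guided.times_walked[p], random.times_walked[p]
        corrected = r == 0 and g > 0
        if corrected:
            n_corrected += 1
            gf = (g + zero_correction) / (g_total + 2 * zero_correction)
            rf = zero_correction / (r_total + 2 * zero_correction)
        else:
            gf, rf = g / g_total, r / r_total
        g_odds = gf / (1.0 - gf) if gf < 1.0 else np.inf
        r_odds = rf / (1.0 - rf) if rf < 1.0 else np.inf
        if g_odds == 0.0:
            oratio = 0.0
        elif r_odds == 0.0:
            oratio = np.inf
        else:
            oratio = g_odds / r_odds
        rows.append(
            {
                "pathway": p,
                "guided_count": g,
                "random_count": r,
                "Freq": g / g_total,
                "RandomFreq": r / r_total,
                "MapOdds": g_odds,
                "RandomOdds": r_odds,
                "OddsRatio": oratio,
                "corrected": corrected,
            }
        )
    if n_corrected:
        logger.info(
            "continuity correction applied to %d pathway(s) with zero "
            "random-frequency",
            n_corrected,
        )
    df = pd.DataFrame(rows)
    df.attrs["guided_total"] = g_total
    df.attrs["random_total"] = r_total
    return df


def pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Closed-form Pearson chi-square (1 df, no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if (row <= 0).any() or (col <= 0).any():
        return 0.0, 1.0
    expected = np.outer(row, col) / total
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def chi_square_bh(table: pd.DataFrame) -> pd.DataFrame:
    """Attach chi-square p-values and BH-adjusted p-values to the table.

    Each pathway's 2×2 table is [(visits, total − visits) guided; same for
    random] on raw counts.  Tables with a zero margin get p = 1 with a
    logged warning.  The BH family is all pathways of the table (one
    disease run).
    """
    g_total = table.attrs.get("guided_total")
    r_total = table.attrs.get("random_total")
    if g_total is None or r_total is None:
        g_total = int(table["guided_count"].sum())
        r_total = int(table["random_count"].sum())
    chi2s, ps = [], []
    zero_margin = 0
    for g, r in table[["guided_count", "random_count"]].itertuples(index=False):
        tab = np.array([[g, g_total - g], [r, r_total - r]], dtype=float)
        if (tab.sum(axis=0) <= 0).any() or (tab.sum(axis=1) <= 0).any():
            zero_margin += 1
            chi2s.append(0.0)
            ps.append(1.0)
            continue
        c, p = pearson_chi2(tab)
        chi2s.append(c)
        ps.append(p)
    if zero_margin:
        logger.warning(
            "%d pathway table(s) had a zero margin; p set to 1", zero_margin
        )
    out = table.copy()
    out["chi2"] = chi2s
    out["p"] = ps
    out["adj_p"] = multipletests(ps, method="fdr_bh")[1]
    out.attrs.update(table.attrs)
    return out


def flag_significant(
    table: pd.DataFrame, or_threshold: float = 1.3, alpha: float = 0.05
) -> pd.DataFrame:
    """Strict-inequality significance flag: OR > threshold and adj p < alpha."""
    out = table.copy()
    out["significant"] = (out["OddsRatio"] > or_threshold) & (
        out["adj_p"] < alpha
    )
    out.attrs.update(table.attrs)
    return out


def significance_table(
    guided: WalkCounts,
    random: WalkCounts,
    or_threshold: float = 1.3,
    alpha: float = 0.05,
    zero_correction: float = 0.5,
) -> pd.DataFrame:
    """Full pipeline: odds ratios → chi-square + BH → significance flags."""
    df = compute_odds_ratios(guided, random, zero_correction=zero_correction)
    df = chi_square_bh(df)
    return flag_significant(df, or_threshold=or_threshold, alpha=alpha)
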