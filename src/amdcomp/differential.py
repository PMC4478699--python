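"""Pairwise exact tests, FDR correction and indicator-feature calling.

For every feature (a COG community-wide, or a gene within one taxon) and
every pair of communities, a 2x2 table is formed::

                    community i   community j
    feature reads        a11           a21
    all other reads      a12           a22

and compared with the two-tailed Fisher exact test.  P-values are corrected
with the Benjamini-Hochberg step-up over the whole feature x pair family
(configurably per pair), and a feature becomes an *indicator* of community c
when its proportion is significantly higher (or lower) than in every other
community — all k-1 adjusted pairwise tests significant and directionally
concordant, direction judged on proportions, never raw counts.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio
from statsmodels.stats.multitest import multipletests

from .abundance import CountMatrix, tabulate

logger = logging.getLogger(__name__)

#: relative tolerance for the "point probability <= observed" tie rule
TIE_REL_TOL = 1e-7
#: grand totals up to this size use exact integer enumeration
_EXACT_LIMIT = 1024
# integer encoding of the tie rule: w <= w_obs * (1 + 1e-7)
_TIE_NUM = 10_000_000 + 1
_TIE_DEN = 10_000_000


def fisher_two_tailed(a11: int, a12: int, a21: int, a22: int) -> float:
    """Two-tailed Fisher exact test p-value for one 2x2 table.

    The p-value is the total hypergeometric probability of all tables with
    the observed margins whose point probability does not exceed that of the
    observed table (ties judged at relative tolerance 1e-7).  Any zero margin
    makes the table degenerate and returns 1.0 by convention.

    Small tables (grand total <= 1024) are evaluated in exact integer
    arithmetic; larger ones via log-gamma in floating point.
    """
    cells = (a11, a12, a21, a22)
    if any(c < 0 for c in cells) or any(c != int(c) for c in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a11, a12, a21, a22 = (int(c) for c in cells)
    r1, r2 = a11 + a12, a21 + a22
    c1, c2 = a11 + a21, a12 + a22
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    n = r1 + r2
    kmin, kmax = max(0, c1 - r2), min(c1, r1)
    if n <= _EXACT_LIMIT:
        weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(kmin, kmax + 1)]
        w_obs = weights[a11 - kmin]
        included = sum(w for w in weights if w * _TIE_DEN <= w_obs * _TIE_NUM)
        return min(included / comb(n, c1), 1.0)
    ks = np.arange(kmin, kmax + 1)
    logw = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[a11 - kmin]
    p = w[w <= w_obs * (1.0 + TIE_REL_TOL)].sum() / w.sum()
    return float(min(p, 1.0))


def sample_odds_ratio(a11: int, a12: int, a21: int, a22: int) -> float:
    """Unconditional sample odds ratio; infinite when the denominator is 0."""
    num, den = a11 * a22, a12 * a21
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def odds_ratio_ci(
    a11: int, a12: int, a21: int, a22: int, confidence: float = 0.99
) -> tuple[float, float]:
    """Conditional maximum-likelihood confidence interval for the odds ratio."""
    result = _conditional_odds_ratio([[a11, a12], [a21, a22]], kind="conditional")
    ci = result.confidence_interval(confidence_level=confidence)
    return float(ci.low), float(ci.high)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(prop_i: float, prop_j: float) -> str:
    if prop_i > prop_j:
        return "higher"
    if prop_i < prop_j:
        return "lower"
    return "equal"


def pairwise_screen(
    matrix: CountMatrix,
    alpha: float = 0.05,
    family: str = "joint",
    with_ci: bool = False,
) -> tuple[pd.DataFrame, set[str]]:
    """Test every feature in every pair of communities.

    Returns the full results table (one row per feature x pair) and the set
    of features significant in at least one pair after BH adjustment — the
    "significantly different across communities" screen.

    ``family`` controls the BH family: ``"joint"`` (default, conservative)
    adjusts over all features and pairs together; ``"per_pair"`` adjusts
    each community pair separately.  Features absent everywhere, and
    per-pair tables with a zero feature margin, are excluded from the family
    so the BH ``m`` counts testable hypotheses only.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if family not in ("joint", "per_pair"):
        raise ValueError(f"family must be 'joint' or 'per_pair', got {family!r}")
    communities = matrix.communities
    if len(communities) < 2:
        raise ValueError("need at least 2 communities")
    if matrix.zero_communities:
        raise ValueError(f"communities with zero totals: {matrix.zero_communities}")
    counts = matrix.counts
    totals = matrix.column_totals
    nonzero = counts.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("excluding %d all-zero features from the screen", int((~nonzero).sum()))
    counts = counts.loc[nonzero]
    rows = []
    for ci_label, cj_label in combinations(communities, 2):
        tot_i, tot_j = int(totals[ci_label]), int(totals[cj_label])
        col_i = counts[ci_label].to_numpy()
        col_j = counts[cj_label].to_numpy()
        for f, a11, a21 in zip(counts.index, col_i, col_j):
            a11, a21 = int(a11), int(a21)
            a12, a22 = tot_i - a11, tot_j - a21
            degenerate = (a11 + a21 == 0) or (a12 + a22 == 0)
            p = 1.0 if degenerate else fisher_two_tailed(a11, a12, a21, a22)
            rows.append(
                (
                    f, ci_label, cj_label, a11, a12, a21, a22,
                    sample_odds_ratio(a11, a12, a21, a22),
                    p, _direction(a11 / tot_i, a21 / tot_j), degenerate,
                )
            )
    results = pd.DataFrame(
        rows,
        columns=[
            "feature", "community_i", "community_j",
            "a11", "a12", "a21", "a22", "odds_ratio", "p", "direction", "degenerate",
        ],
    )
    results["p_adjusted"] = 1.0
    testable = ~results["degenerate"]
    if family == "joint":
        results.loc[testable, "p_adjusted"] = bh_adjust(results.loc[testable, "p"])
    else:
        for _, idx in results.loc[testable].groupby(["community_i", "community_j"]).groups.items():
            results.loc[idx, "p_adjusted"] = bh_adjust(results.loc[idx, "p"])
    if with_ci:
        ci = [
            odds_ratio_ci(r.a11, r.a12, r.a21, r.a22) if not r.degenerate else (0.0, float("inf"))
            for r in results.itertuples()
        ]
        results["ci99_low"] = [lo for lo, _ in ci]
        results["ci99_high"] = [hi for _, hi in ci]
    significant = set(results.loc[results["p_adjusted"] < alpha, "feature"])
    return results, significant


def call_indicators(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Classify indicator features from a pairwise results table.

    Community ``c`` gets a *higher* indicator call for feature ``f`` iff all
    k-1 comparisons of c against the other communities are significant
    (adjusted p < alpha) and c's proportion is the larger in every one;
    *lower* symmetrically.  At most one higher and one lower call can exist
    per feature.  Stored directions are re-derived from the cell proportions
    and any contradiction is a hard error (corrupt input).
    """
    required = {"feature", "community_i", "community_j", "a11", "a12", "a21", "a22",
                "p_adjusted", "direction"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    prop_i = results["a11"] / (results["a11"] + results["a12"])
    prop_j = results["a21"] / (results["a21"] + results["a22"])
    derived = np.where(prop_i > prop_j, "higher", np.where(prop_i < prop_j, "lower", "equal"))
    if (derived != results["direction"].to_numpy()).any():
        bad = results.loc[derived != results["direction"].to_numpy()].iloc[0]
        raise ValueError(
            f"stored direction contradicts proportions for feature {bad['feature']!r} "
            f"({bad['community_i']} vs {bad['community_j']})"
        )
    communities = sorted(set(results["community_i"]) | set(results["community_j"]))
    k = len(communities)
    flip = {"higher": "lower", "lower": "higher", "equal": "equal"}
    view_i = results[["feature", "community_i", "p_adjusted", "direction"]].rename(
        columns={"community_i": "community"}
    )
    view_j = results[["feature", "community_j", "p_adjusted", "direction"]].rename(
        columns={"community_j": "community"}
    )
    view_j = view_j.assign(direction=view_j["direction"].map(flip))
    long = pd.concat([view_i, view_j], ignore_index=True)
    sig = long[(long["p_adjusted"] < alpha) & (long["direction"] != "equal")]
    calls = []
    grouped = sig.groupby(["feature", "community", "direction"], observed=True)
    for (feature, community, direction), group in grouped:
        if len(group) == k - 1:
            calls.append(
                {
                    "feature": feature,
                    "community": community,
                    "direction": direction,
                    "n_supporting": k - 1,
                    "max_p_adjusted": float(group["p_adjusted"].max()),
                }
            )
    out = pd.DataFrame(
        calls, columns=["feature", "community", "direction", "n_supporting", "max_p_adjusted"]
    )
    return out.sort_values(["community", "direction", "feature"]).reset_index(drop=True)


def indicator_counts(calls: pd.DataFrame, communities=None) -> pd.DataFrame:
    """Per-community higher/lower indicator tally (the summary bar-plot shape)."""
    if communities is None:
        communities = sorted(calls["community"].unique())
    table = (
        calls.groupby(["community", "direction"], observed=True).size().unstack(fill_value=0)
        if len(calls)
        else pd.DataFrame()
    )
    table = table.reindex(index=communities, fill_value=0)
    for col in ("higher", "lower"):
        if col not in table.columns:
            table[col] = 0
    table = table[["higher", "lower"]].astype(int)
    table["total"] = table.sum(axis=1)
    return table


def per_taxon_gene_screen(
    reads: pd.DataFrame,
    taxon: str,
    alpha: float = 0.05,
    layer: str = "cDNA",
    level: str = "cog",
    family: str = "joint",
    min_taxon_reads: int = 50,
) -> tuple[pd.DataFrame, set[str], CountMatrix]:
    """Differential screen restricted to one taxon's reads.

    Denominators are the taxon's own per-community read totals, so the test
    asks whether a gene's share *within the taxon* differs between
    communities.  Communities where the taxon has fewer than
    ``min_taxon_reads`` assigned reads are dropped (logged); the taxon must
    remain in at least two.  ``level`` names the within-taxon gene
    identifier column family (``"cog"`` for annotation tables where the COG
    id is the gene key, ``"gene"`` for tables with an explicit gene column).
    """
    subset = reads[(reads["genus"] == taxon) & (reads["layer"] == layer)]
    if subset.empty:
        raise ValueError(f"taxon {taxon!r} has no {layer} reads")
    matrix = tabulate(subset, level=level, layer=layer)
    totals = matrix.column_totals
    keep = [c for c in matrix.communities if totals[c] >= min_taxon_reads]
    dropped = sorted(set(matrix.communities) - set(keep))
    if dropped:
        logger.info(
            "dropping communities below the %d-read floor for %s: %s",
            min_taxon_reads, taxon, dropped,
        )
    if len(keep) < 2:
        raise ValueError(
            f"taxon {taxon!r} present in fewer than 2 communities after the read floor"
        )
    matrix = CountMatrix(matrix.counts[keep].copy(), level=matrix.level, layer=matrix.layer)
    results, significant = pairwise_screen(matrix, alpha=alpha, family=family)
    return results, significant, matrix
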