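"""Diagnostic ranking of candidate genes and correlation-based expansion.

A candidate gene's diagnostic value is its ROC AUC computed through the
rank-sum (Mann-Whitney) identity

    AUC = (R_pos - n_pos(n_pos + 1)/2) / (n_pos * n_neg)

with midrank handling of ties, auto-oriented so the reported AUC is
max(AUC, 1 - AUC) with the scoring direction recorded.  Differential
expression between the two groups is a two-sided Wilcoxon rank-sum test.
The hub gene is the differential candidate with the highest AUC; its
correlated gene set is every other gene with Pearson r above a threshold at
a t-distribution p-value below a cutoff.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, GeneSet, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "auc",
    "wilcoxon_rank_sum",
    "rank_candidates",
    "select_hub",
    "pearson_with_p",
    "expand_correlated",
    "correlate_with_fractions",
    "benjamini_hochberg",
]

#: Combined sample size at or below which the rank-sum test is exact.
EXACT_MAX_N = 12


def auc(values, labels, positive: str = "T2DM") -> tuple[float, str]:
    """Oriented ROC AUC of ``values`` for separating the two label levels.

    Returns ``(auc, direction)`` where ``auc = max(a, 1 - a)`` for the raw
    Mann-Whitney AUC ``a`` of the ``positive`` label, and ``direction`` is
    the label whose values tend to be higher.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive]
    neg = values[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(f"both label levels required (positive={positive!r})")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    raw = (r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg))
    negative = labels[labels != positive][0]
    if raw >= 0.5:
        return float(raw), positive
    return float(1.0 - raw), str(negative)


def wilcoxon_rank_sum(x, y, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided rank-sum p-value.

    Exact enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    if len(combined) <= exact_max_n and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def rank_candidates(
    expr: ExpressionMatrix,
    candidates: GeneSet,
    alpha: float = 0.05,
    positive: str = "T2DM",
) -> pd.DataFrame:
    """AUC + rank-sum p for each candidate gene, sorted by descending AUC.

    Candidates absent from the expression matrix are logged and skipped,
    mirroring studies where only a subset of network genes is measured.
    """
    levels = expr.group_levels()
    if positive not in levels:
        raise ValueError(f"positive level {positive!r} not in groups {levels}")
    present = [g for g in candidates if g in expr.genes]
    absent = sorted(set(candidates.genes) - set(present))
    if absent:
        logger.info("rank_candidates: %d candidate(s) not measured: %s", len(absent), absent)
    if not present:
        raise ValueError("no candidate gene is present in the expression matrix")

    labels = expr.group.to_numpy()
    rows = []
    for gene in present:
        vals = expr.values.loc[gene].to_numpy(dtype=float)
        a, direction = auc(vals, labels, positive=positive)
        p = wilcoxon_rank_sum(vals[labels == positive], vals[labels != positive])
        rows.append(
            {"gene": gene, "auc": a, "direction": direction, "wilcoxon_p": p, "differential": p < alpha}
        )
    out = pd.DataFrame(rows).sort_values(["auc", "gene"], ascending=[False, True])
    return out.reset_index(drop=True)


def select_hub(results: pd.DataFrame) -> str | None:
    """The differential candidate with maximal AUC (ties: lowest gene id).

    Returns ``None`` when no candidate is differentially expressed — a
    legitimate "no hub" outcome, not an error.
    """
    if not len(results):
        raise ValueError("empty diagnostic results")
    diff = results.loc[results["differential"]]
    if not len(diff):
        logger.info("select_hub: no differentially expressed candidate; no hub")
        return None
    best = diff.sort_values(["auc", "gene"], ascending=[False, True]).iloc[0]
    return str(best["gene"])


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-distribution p-value (n - 2 df).

    Zero variance in either vector yields ``(nan, nan)`` (flagged by the
    caller and excluded downstream) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_with_p needs n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def expand_correlated(
    expr: ExpressionMatrix,
    hub: str,
    r_min: float = 0.95,
    p_max: float = 0.001,
    absolute: bool = False,
) -> pd.DataFrame:
    """Correlate every other gene with the hub across samples.

    ``selected`` is True when r > r_min (or |r| > r_min with
    ``absolute=True``) and p < p_max.  The hub is excluded from its own set;
    zero-variance genes appear with NaN r and are never selected.
    """
    if hub not in expr.genes:
        raise ValueError(f"hub gene {hub!r} not in expression matrix")
    hub_vals = expr.values.loc[hub].to_numpy(dtype=float)
    rows = []
    for gene in expr.genes:
        if gene == hub:
            continue
        r, p = pearson_with_p(expr.values.loc[gene].to_numpy(dtype=float), hub_vals)
        stat = abs(r) if absolute else r
        selected = bool(not math.isnan(r) and stat > r_min and p < p_max)
        rows.append({"gene": gene, "r": r, "p": p, "selected": selected})
    out = pd.DataFrame(rows, columns=["gene", "r", "p", "selected"])
    out = out.sort_values("r", ascending=False, na_position="last")
    return out.reset_index(drop=True)


def correlate_with_fractions(
    expr: ExpressionMatrix,
    genes: GeneSet,
    fractions: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of each gene with each cell-type fraction.

    ``fractions`` is cell-type x sample (e.g. a deconvolution output).
    Returns a long table (gene, cell_type, r, p, tier) where tier marks
    p < 0.05 / 0.01 / 0.001 as '*', '**', '***'.  Constant rows are flagged
    with NaN.
    """
    shared = [s for s in expr.samples if s in fractions.columns]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, found {len(shared)}")
    rows = []
    for gene in genes:
        if gene not in expr.genes:
            continue
        gv = expr.values.loc[gene, shared].to_numpy(dtype=float)
        for cell_type in fractions.index:
            fv = fractions.loc[cell_type, shared].to_numpy(dtype=float)
            r, p = pearson_with_p(gv, fv)
            if math.isnan(r):
                tier = "undefined"
            elif p < 0.001:
                tier = "***"
            elif p < 0.01:
                tier = "**"
            elif p < 0.05:
                tier = "*"
            else:
                tier = ""
            rows.append({"gene": gene, "cell_type": cell_type, "r": r, "p": p, "tier": tier})
    return pd.DataFrame(rows, columns=["gene", "cell_type", "r", "p", "tier"])


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
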