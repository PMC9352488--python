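"""Cell-level QC, normalization, marker detection, and cluster abundance.

The abundance test asks, per cell cluster, whether disease cells are over- or
under-represented relative to control cells.  The effect size is the ratio of
condition-normalized cluster proportions

    FC(c) = (n_cD / N_D) / (n_cC / N_C)

and significance comes from a two-sided Fisher exact test on the 2x2 table of
(in cluster / not in cluster) x (disease / control).  A cluster is *selected*
when FC > 4 or FC < 0.25 and the raw Fisher p < 0.05; Benjamini-Hochberg
adjusted p-values are reported alongside for transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "qc_filter",
    "log_normalize",
    "fisher_exact_2x2",
    "abundance_test",
    "select_clusters",
    "find_markers",
    "top_markers",
]

#: Columns every per-cell table must carry.
CELL_COLUMNS = ("cell_id", "cluster", "condition", "n_genes", "pct_mito", "n_umi")
QC_COLUMNS = ("n_genes", "pct_mito", "n_umi")

CASE = "T2DM"
CONTROL = "normal"


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell quality-control bounds.

    ``min_genes``/``max_genes`` are inclusive; ``max_pct_mito`` and
    ``min_umi`` are strict (a cell at exactly 35% mitochondrial content or
    exactly 1000 UMIs is removed).
    """

    min_genes: int = 100
    max_genes: int = 7500
    max_pct_mito: float = 35.0
    min_umi: int = 1000

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")


def qc_filter(cells: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Keep cells satisfying all QC bounds; order is preserved."""
    missing = [c for c in QC_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing QC column(s): {missing}")
    keep = (
        cells["n_genes"].ge(thresholds.min_genes)
        & cells["n_genes"].le(thresholds.max_genes)
        & cells["pct_mito"].lt(thresholds.max_pct_mito)
        & cells["n_umi"].gt(thresholds.min_umi)
    )
    out = cells.loc[keep].copy()
    logger.info("qc_filter: kept %d cells, removed %d", len(out), len(cells) - len(out))
    return out


def log_normalize(values: pd.DataFrame, scale_factor: float = 10_000.0) -> pd.DataFrame:
    """Library-size normalize then log-transform: v -> ln(1 + v * scale / colsum)."""
    if (values.values < 0).any():
        raise ValueError("log_normalize requires nonnegative values")
    totals = values.sum(axis=0)
    zero = totals.index[totals.values == 0]
    if len(zero):
        raise ValueError(f"column {zero[0]!r} has zero total, cannot normalize")
    return np.log1p(values * (scale_factor / totals))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]."""
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError(f"counts must be nonnegative integers, got {counts}")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def select_clusters(
    table: pd.DataFrame,
    alpha: float = 0.05,
    fc_hi: float = 4.0,
    fc_lo: float = 0.25,
) -> pd.DataFrame:
    """Apply the abundance selection rule to a (cluster, p, fc) table.

    Adds a boolean ``selected`` column: (fc > fc_hi or fc < fc_lo) and
    p < alpha (raw p).  The table may come from :func:`abundance_test` or be
    externally reported statistics.
    """
    out = table.copy()
    fc = out["fc"].astype(float)
    out["selected"] = ((fc > fc_hi) | (fc < fc_lo)) & (out["p"].astype(float) < alpha)
    return out


def abundance_test(
    cells: pd.DataFrame,
    alpha: float = 0.05,
    fc_hi: float = 4.0,
    fc_lo: float = 0.25,
    case: str = CASE,
    control: str = CONTROL,
) -> pd.DataFrame:
    """Per-cluster differential abundance between the two conditions.

    Returns one row per cluster with columns ``cluster, n_t2dm, n_normal, fc,
    p, p_adj, selected``, sorted by cluster id.  ``fc`` is the ratio of
    condition-normalized proportions (case over control); an empty control
    cluster yields ``fc = inf`` (logged) and the cluster is selected iff its
    Fisher p is below ``alpha``.
    """
    for col in ("cluster", "condition"):
        if col not in cells.columns:
            raise SchemaError(f"cell table missing column {col!r}")
    conditions = set(cells["condition"].unique())
    if not {case, control} <= conditions:
        raise ValueError(f"need both conditions {case!r} and {control!r}, found {sorted(conditions)}")

    n_case_total = int((cells["condition"] == case).sum())
    n_ctrl_total = int((cells["condition"] == control).sum())
    counts = (
        cells.groupby(["cluster", "condition"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[case, control], fill_value=0)
    )

    rows = []
    for cluster, row in counts.iterrows():
        n_case, n_ctrl = int(row[case]), int(row[control])
        p = fisher_exact_2x2(n_case, n_case_total - n_case, n_ctrl, n_ctrl_total - n_ctrl)
        if n_ctrl == 0:
            fc = np.inf
            logger.info("cluster %s has no %s cells; fc set to inf", cluster, control)
        else:
            fc = (n_case / n_case_total) / (n_ctrl / n_ctrl_total)
        rows.append({"cluster": cluster, "n_t2dm": n_case, "n_normal": n_ctrl, "fc": fc, "p": p})

    out = pd.DataFrame(rows).sort_values("cluster", key=lambda s: s.astype(str)).reset_index(drop=True)
    from .diagnostics import benjamini_hochberg

    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out = select_clusters(out, alpha=alpha, fc_hi=fc_hi, fc_lo=fc_lo)
    return out[["cluster", "n_t2dm", "n_normal", "fc", "p", "p_adj", "selected"]]


def find_markers(
    expr: pd.DataFrame,
    cells: pd.DataFrame,
    min_log2fc: float = 0.5,
    min_pct: float = 0.35,
    alpha: float = 0.05,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Per-cluster marker genes: one cluster vs all other cells.

    ``expr`` is a genes x cells matrix of normalized values whose columns map
    1:1 to ``cells['cell_id']``.  For each cluster and gene a two-sided
    rank-sum test compares in-cluster vs out-of-cluster values;
    ``log2fc = log2((mean_in + eps) / (mean_out + eps))`` and ``pct_in`` /
    ``pct_out`` are the fractions of cells with a positive value.  A gene is
    reported iff log2fc >= min_log2fc, max(pct_in, pct_out) >= min_pct and
    p < alpha.  Results are sorted by cluster, then ascending p.  Clusters
    with fewer than two cells are skipped with a warning.
    """
    ids = list(cells["cell_id"])
    if set(expr.columns) != set(ids) or len(expr.columns) != len(ids):
        raise SchemaError("expression columns do not map 1:1 to cells in the cell table")
    expr = expr[ids]
    cluster_of = cells.set_index("cell_id")["cluster"]

    values = expr.to_numpy(dtype=float)
    results = []
    for cluster in sorted(cluster_of.unique(), key=str):
        mask = (cluster_of.loc[expr.columns] == cluster).to_numpy()
        n_in = int(mask.sum())
        if n_in < 2 or (~mask).sum() < 2:
            logger.warning("cluster %s has < 2 cells on one side; skipped", cluster)
            continue
        inside, outside = values[:, mask], values[:, ~mask]
        mean_in, mean_out = inside.mean(axis=1), outside.mean(axis=1)
        pct_in = (inside > 0).mean(axis=1)
        pct_out = (outside > 0).mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            # negative means (possible on already-centered input) give NaN,
            # which simply fails the fold-change filter
            log2fc = np.log2((mean_in + eps) / (mean_out + eps))
        p = stats.mannwhitneyu(
            inside, outside, axis=1, alternative="two-sided", method="asymptotic"
        ).pvalue
        from .diagnostics import benjamini_hochberg

        p_adj = benjamini_hochberg(p)
        keep = (log2fc >= min_log2fc) & (np.maximum(pct_in, pct_out) >= min_pct) & (p < alpha)
        for i in np.flatnonzero(keep):
            results.append(
                {
                    "cluster": cluster,
                    "gene": expr.index[i],
                    "log2fc": log2fc[i],
                    "pct_in": pct_in[i],
                    "pct_out": pct_out[i],
                    "p": p[i],
                    "p_adj": p_adj[i],
                }
            )
    out = pd.DataFrame(
        results, columns=["cluster", "gene", "log2fc", "pct_in", "pct_out", "p", "p_adj"]
    )
    if len(out):
        out = out.sort_values(["cluster", "p"], key=lambda s: s.astype(str) if s.name == "cluster" else s)
        out = out.reset_index(drop=True)
    return out


def top_markers(markers: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """First ``n`` markers per cluster (markers are already sorted by p)."""
    if not len(markers):
        return markers
    return markers.groupby("cluster", sort=True, observed=True).head(n).reset_index(drop=True)
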