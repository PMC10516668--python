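"""Replicate filtering, gene aggregation, hit calling and screen statistics.

After normalization, each gene is represented by up to four colony
replicates per screen (sixteen when four screens are pooled).  Outlying
replicates are removed with an iterative two-sided Grubbs test, genes with
fewer than three surviving colonies are dropped, and the replicate mean is
the gene's final yellowness / size score.  Hit groups are defined on the
z scale (yellow > +1.2 SD, white < -1.2 SD; cyan = yellow without fitness
penalty), and cross-screen reproducibility is quantified with Pearson
correlation and an upper-tail hypergeometric test on top/bottom hit-list
overlaps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Grubbs outlier filtering
# ---------------------------------------------------------------------------


@dataclass
class GrubbsResult:
    """One application of the two-sided single-outlier Grubbs test."""

    values_in: np.ndarray
    outlier_index: int | None
    G: float
    G_crit: float
    alpha: float


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t-distribution quantile.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2)) with
    t = t_{1-alpha/(2n), n-2}.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_step(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Single two-sided Grubbs test; flags the most deviant value if G > G_crit.

    Degenerate inputs (n < 3 or zero sample sd) are left untested.
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n < 3:
        return GrubbsResult(vals, None, float("nan"), float("nan"), alpha)
    sd = vals.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return GrubbsResult(vals, None, float("nan"), float("nan"), alpha)
    dev = np.abs(vals - vals.mean())
    i = int(np.argmax(dev))
    g = float(dev[i] / sd)
    g_crit = grubbs_critical(n, alpha)
    return GrubbsResult(vals, i if g > g_crit else None, g, g_crit, alpha)


def grubbs_filter(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, list[GrubbsResult]]:
    """Iteratively remove single outliers until none is flagged or n < 3.

    Returns (retained values, boolean keep-mask over the input, test trail).
    """
    vals = np.asarray(values, dtype=float)
    keep = np.ones(len(vals), dtype=bool)
    trail: list[GrubbsResult] = []
    while True:
        current = vals[keep]
        res = grubbs_step(current, alpha)
        trail.append(res)
        if res.outlier_index is None:
            break
        live = np.flatnonzero(keep)
        keep[live[res.outlier_index]] = False
    return vals[keep], keep, trail


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_genes(
    records: pd.DataFrame,
    min_replicates: int = 3,
    grubbs_alpha: float | None = 0.05,
) -> pd.DataFrame:
    """Per-gene replicate filtering and averaging.

    ``records`` is a gene-keyed table (see
    :func:`crispa.platecorr.derandomize`) with ``z_yellow`` and ``z_size``
    columns.  Records with missing yellowness are dropped; the Grubbs filter
    (if enabled) runs on the pooled z_yellow replicates of each gene and a
    flagged record is removed for both metrics.  Genes with fewer than
    ``min_replicates`` survivors are dropped.

    Returns a frame with columns gene_id, mean_yellow, mean_size,
    n_replicates plus the dropped-gene tally in ``frame.attrs``.
    """
    valid = records.dropna(subset=["z_yellow"])
    rows = []
    n_dropped = 0
    for gene, grp in valid.groupby("gene_id", sort=True):
        zy = grp["z_yellow"].to_numpy(dtype=float)
        zs = grp["z_size"].to_numpy(dtype=float)
        if grubbs_alpha is not None:
            _, keep, _ = grubbs_filter(zy, grubbs_alpha)
            zy, zs = zy[keep], zs[keep]
        if len(zy) < min_replicates:
            n_dropped += 1
            continue
        rows.append((gene, float(np.mean(zy)), float(np.nanmean(zs)), len(zy)))
    out = pd.DataFrame(rows, columns=["gene_id", "mean_yellow", "mean_size",
                                      "n_replicates"])
    out.attrs["n_dropped"] = n_dropped
    out.attrs["n_genes_in"] = valid["gene_id"].nunique()
    return out


def combine_screens(
    screens: Iterable[pd.DataFrame],
    min_replicates: int = 3,
    grubbs_alpha: float = 0.05,
) -> pd.DataFrame:
    """Pool gene-keyed records of several normalized screens and aggregate.

    Each input must come from an independently edge-corrected and normalized
    screen.  Grubbs filtering runs on the pooled replicate set of each gene.
    Duplicate (screen, plate, row, col) records raise.
    """
    pooled = pd.concat(list(screens), ignore_index=True)
    dup = pooled.duplicated(subset=["screen_id", "plate_id", "row", "col"])
    if dup.any():
        raise ValueError("duplicate colony records across screens")
    return aggregate_genes(pooled, min_replicates, grubbs_alpha)


def call_hits(
    summaries: pd.DataFrame,
    sd_threshold: float = 1.2,
    cyan_yellow_min: float = 1.2,
    cyan_size_min: float = 0.0,
) -> pd.DataFrame:
    """Assign hit groups on the z scale.

    yellow: mean_yellow > +sd_threshold; white: mean_yellow < -sd_threshold;
    otherwise none.  ``cyan`` is reported as a separate boolean sub-label —
    highly yellow genes with little or no fitness penalty (mean_yellow >
    cyan_yellow_min and mean_size > cyan_size_min) — alongside, never
    instead of, the yellow/white call.
    """
    out = summaries.copy()
    my = out["mean_yellow"]
    out["group"] = np.select(
        [my > sd_threshold, my < -sd_threshold], ["yellow", "white"], "none"
    )
    out["cyan"] = (my > cyan_yellow_min) & (out["mean_size"] > cyan_size_min)
    return out


# ---------------------------------------------------------------------------
# cross-screen statistics
# ---------------------------------------------------------------------------


@dataclass
class OverlapTestResult:
    """Upper-tail hypergeometric test on the overlap of two hit lists."""

    M: int
    n: int
    N: int
    k: int
    p_value: float
    tail: str = "top"

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.N) and max(self.n, self.N) <= self.M):
            raise ValueError("inconsistent overlap counts")


def hypergeom_overlap_pvalue(M: int, n: int, N: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, n, N)."""
    if not (0 <= k <= min(n, N) and max(n, N) <= M):
        raise ValueError("require k <= min(n, N) and n, N <= M")
    return float(stats.hypergeom.sf(k - 1, M, n, N))


def _ranked_hits(summaries: pd.DataFrame, genes: set, k: int, tail: str) -> set:
    sub = summaries[summaries["gene_id"].isin(genes)]
    asc = tail == "bottom"
    sub = sub.sort_values(["mean_yellow", "gene_id"], ascending=[asc, True])
    ranked = sub["gene_id"].tolist()
    if len(ranked) > k and sub["mean_yellow"].iloc[k - 1] == sub["mean_yellow"].iloc[k]:
        logger.info("hit-list tie at rank %d broken lexicographically", k)
    return set(ranked[:k])


def top_bottom_overlap(
    screen_a: pd.DataFrame,
    screen_b: pd.DataFrame,
    k_list_size: int = 192,
    tail: str = "top",
) -> OverlapTestResult:
    """Overlap of the top (or bottom) ``k_list_size`` genes of two screens.

    Both inputs are gene-level summaries; M is the number of genes scored
    in both screens, the hit lists are ranked by mean_yellow within those
    common genes (ties broken by gene identifier), and p is the upper-tail
    hypergeometric probability of at least the observed overlap.
    """
    if tail not in ("top", "bottom"):
        raise ValueError("tail must be 'top' or 'bottom'")
    common = set(screen_a["gene_id"]) & set(screen_b["gene_id"])
    M = len(common)
    if k_list_size > M:
        raise ValueError(f"k_list_size {k_list_size} exceeds common genes {M}")
    hits_a = _ranked_hits(screen_a, common, k_list_size, tail)
    hits_b = _ranked_hits(screen_b, common, k_list_size, tail)
    k = len(hits_a & hits_b)
    p = hypergeom_overlap_pvalue(M, k_list_size, k_list_size, k)
    return OverlapTestResult(M, k_list_size, k_list_size, k, p, tail)


def pearson(scores_a: pd.Series, scores_b: pd.Series) -> float:
    """Pearson correlation of two gene-score vectors over their common genes."""
    common = scores_a.index.intersection(scores_b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common genes")
    a = scores_a.loc[common].to_numpy(dtype=float)
    b = scores_b.loc[common].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input")
    return float(stats.pearsonr(a, b).statistic)


def one_sided_test(
    sample_mut: Sequence[float],
    sample_ref: Sequence[float],
    kind: str = "welch",
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-sided two-sample t test (Student pooled-variance or Welch).

    ``alternative`` is the direction of the mutant relative to the
    reference: "greater" for yellow (pigment-up) hits, "less" for white.
    Returns (t statistic, one-sided p).
    """
    if kind not in ("student", "welch"):
        raise ValueError("kind must be 'student' or 'welch'")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a = np.asarray(sample_mut, dtype=float)
    b = np.asarray(sample_ref, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=(kind == "student"),
                          alternative=alternative)
    return float(res.statistic), float(res.pvalue)
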