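"""Rank-list overlap analysis and informative list-size estimation.

Two ranked co-regulation lists (one per factor-grouping method) are compared
by their percent overlap at increasing list sizes n:

    overlap(n) = 100 · |top_n(A) ∩ top_n(B)| / n

Real lists overlap strongly among their leading genes and then accrue shared
genes only at the chance rate; the list size K where the curve's growth
becomes indistinguishable from that of scrambled lists (second difference
near zero, slope near the scrambled baseline's) bounds the informative part
of the rankings. The final co-regulated list is the intersection of the two
methods' top-K genes, ranked by the grouped-method correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_K = 400  # corpus-level informative list size
SMOOTH_WINDOW = 5  # grid points, centered moving average before differencing
D2_TOL = 0.05  # %-points per grid step
SLOPE_FACTOR = 2.0  # local slope must be within this multiple of baseline's


@dataclass
class OverlapCurve:
    n_values: np.ndarray
    overlap_pct: np.ndarray
    d1: np.ndarray  # first finite difference of overlap_pct per grid step
    d2: np.ndarray  # second finite difference per grid step

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n_values,
                "overlap_pct": self.overlap_pct,
                "d1": self.d1,
                "d2": self.d2,
            }
        )


@dataclass
class MethodComparison:
    """Per-gene log2 ratio of the two methods' correlations (positive r only)."""

    ratios: pd.Series  # gene -> log2(r_individual / r_grouped)
    bin_edges: np.ndarray
    counts: np.ndarray
    median: float


@dataclass
class FinalLists:
    similar: pd.DataFrame  # gene, r_grouped, r_individual, n_shared (grouped)
    dissimilar: pd.DataFrame


def percent_overlap(a: list[str], b: list[str], n: int) -> float:
    """Percentage of symbols shared by the top-n entries of two ranked lists."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > min(len(a), len(b)):
        raise ValueError(f"n={n} exceeds a list length ({len(a)}, {len(b)})")
    top_a, top_b = set(a[:n]), set(b[:n])
    if len(top_a) != n or len(top_b) != n:
        raise ValueError("ranked lists must be duplicate-free")
    return 100.0 * len(top_a & top_b) / n


def _smooth(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    if window <= 1 or y.size < window:
        return y.astype(float)
    half = window // 2
    padded = np.concatenate([y[half:0:-1], y, y[-2 : -half - 2 : -1]])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _differences(pct: np.ndarray, window: int = SMOOTH_WINDOW):
    smoothed = _smooth(np.asarray(pct, dtype=float), window)
    if smoothed.size < 2:
        zero = np.zeros_like(smoothed)
        return zero, zero.copy()
    d1 = np.gradient(smoothed)  # per grid step
    d2 = np.gradient(d1)
    return d1, d2


def overlap_curve(
    a: list[str],
    b: list[str],
    n_min: int = 10,
    n_max: int = 1000,
    step: int = 10,
) -> OverlapCurve:
    """Percent overlap over a grid of list sizes, with smoothed differences.

    If either list is shorter than ``n_max`` the grid is truncated to the
    shorter length (logged).
    """
    limit = min(len(a), len(b))
    if n_max > limit:
        logger.info("n_max lowered from %d to list length %d", n_max, limit)
        n_max = limit
    if n_min > n_max:
        raise ValueError("lists shorter than n_min")
    n_values = np.arange(n_min, n_max + 1, step)
    pct = np.array([percent_overlap(a, b, int(n)) for n in n_values])
    d1, d2 = _differences(pct)
    return OverlapCurve(n_values, pct, d1, d2)


def scrambled_baseline(
    a: list[str],
    b: list[str],
    n_min: int = 10,
    n_max: int = 1000,
    step: int = 10,
    n_reps: int = 20,
    seed: int = 0,
) -> OverlapCurve:
    """Mean overlap curve over independent random permutations of both lists.

    Estimates the chance overlap floor: for full-length lists over the same G
    symbols the expectation at size n is 100·n/G.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    a_arr, b_arr = np.asarray(a, dtype=object), np.asarray(b, dtype=object)
    limit = min(len(a), len(b))
    n_max = min(n_max, limit)
    n_values = np.arange(n_min, n_max + 1, step)
    acc = np.zeros(len(n_values))
    for _ in range(n_reps):
        pa = list(a_arr[rng.permutation(len(a_arr))])
        pb = list(b_arr[rng.permutation(len(b_arr))])
        acc += [percent_overlap(pa, pb, int(n)) for n in n_values]
    pct = acc / n_reps
    d1, d2 = _differences(pct)
    return OverlapCurve(n_values, pct, d1, d2)


def estimate_informative_size(
    curve: OverlapCurve,
    baseline: OverlapCurve,
    d2_tol: float = D2_TOL,
    slope_factor: float = SLOPE_FACTOR,
    default_k: int = DEFAULT_K,
) -> int:
    """List size where the overlap curve's growth becomes chance-like.

    K is the smallest grid size n from which, over the whole remaining grid,
    the smoothed second difference stays below ``d2_tol`` and the local slope
    stays within ``slope_factor`` times the scrambled baseline's slope (plus
    the same tolerance, so a flat plateau over a flat baseline qualifies).
    With no such n the corpus-level default of 400 is returned, clamped to
    the grid.
    """
    if not np.array_equal(curve.n_values, baseline.n_values):
        raise ValueError("curve and baseline must share a grid")
    ok = (np.abs(curve.d2) < d2_tol) & (
        np.abs(curve.d1) <= slope_factor * np.abs(baseline.d1) + d2_tol
    )
    # suffix scan: first index from which every later grid point qualifies
    good_from = len(ok)
    for i in range(len(ok) - 1, -1, -1):
        if not ok[i]:
            break
        good_from = i
    if good_from < len(ok):
        return int(curve.n_values[good_from])
    lo, hi = int(curve.n_values[0]), int(curve.n_values[-1])
    return int(min(max(default_k, lo), hi))


def method_ratio_histogram(
    recs_ind: pd.DataFrame, recs_grp: pd.DataFrame, bins: int = 41
) -> MethodComparison:
    """Histogram of log2(r_individual / r_grouped) per overlapping gene.

    Only genes with positive correlation under both methods are defined. A
    distribution centered below zero means the grouped method finds the
    stronger correlations.
    """
    ind = recs_ind.set_index("gene")["r"]
    grp = recs_grp.set_index("gene")["r"]
    common = ind.index.intersection(grp.index)
    ind, grp = ind.loc[common], grp.loc[common]
    pos = (ind > 0) & (grp > 0)
    ratios = np.log2(ind[pos] / grp[pos]).sort_index()
    ratios.name = "log2_ratio"
    if len(ratios):
        counts, edges = np.histogram(ratios.to_numpy(), bins=bins)
        median = float(np.median(ratios))
    else:
        counts, edges = np.array([], dtype=int), np.array([])
        median = float("nan")
    return MethodComparison(ratios, edges, counts, median)


def final_list(
    recs_ind: pd.DataFrame, recs_grp: pd.DataFrame, k: int = DEFAULT_K
) -> FinalLists:
    """Intersect the two methods' top-K (and bottom-K) genes.

    The similar list is the intersection of each method's K most positively
    correlated genes, restricted to genes positive under both methods and
    ordered by the grouped-method r descending; the dissimilar list mirrors
    it at the negative end (ordered ascending). Genes whose correlation sign
    differs between methods appear in neither list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")

    def top(recs: pd.DataFrame, ascending: bool) -> pd.DataFrame:
        recs = recs.sort_values(
            ["r", "gene"], ascending=[ascending, True], kind="mergesort"
        )
        return recs.head(k)

    def build(ascending: bool) -> pd.DataFrame:
        ti = top(recs_ind, ascending)
        tg = top(recs_grp, ascending)
        common = set(ti["gene"]) & set(tg["gene"])
        out = tg[tg["gene"].isin(common)].copy()
        out = out.rename(columns={"r": "r_grouped", "n_shared": "n_shared_grouped"})
        r_ind = recs_ind.set_index("gene")["r"]
        out["r_individual"] = out["gene"].map(r_ind)
        if ascending:
            out = out[(out["r_grouped"] < 0) & (out["r_individual"] < 0)]
        else:
            out = out[(out["r_grouped"] > 0) & (out["r_individual"] > 0)]
        out = out.sort_values(
            ["r_grouped", "gene"], ascending=[ascending, True], kind="mergesort"
        )
        cols = ["gene", "r_grouped", "r_individual", "n_shared_grouped"]
        return out[cols].reset_index(drop=True)

    return FinalLists(similar=build(False), dissimilar=build(True))
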