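"""1-D optimal transport between two lineage-size distributions.

To compare clone-size distributions {x_i | i=1..N} and {y_j | j=1..M} across
conditions, both samples are first put on a common footing: the higher of
the two read thresholds is applied to both and sizes are re-normalized to
reads per million.  If the lineage numbers differ, each x lineage counts as
lcm(N, M)/N transport units and each y lineage as lcm(N, M)/M units, so
both sides carry lcm(N, M) units in total.  The transport map minimizing
the summed absolute log2 fold change |log2 x - log2 T(x)| over all unit
bijections is the rank-wise map: the i-th largest unit of x pairs with the
i-th largest unit of y (the classic monotone solution of 1-D transport
under a convex cost).  Per-pair log2 fold changes are then summarized as
LOWESS-smoothed curves over source size (after removing the top 1% of
source lineages, which are few and volatile) and as weighted densities.

The lcm expansion is virtual: pairs are built by merging the two sorted
size lists with integer unit weights, never materializing lcm(N, M) rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pipeline import LineageSizeDistribution


@dataclass(frozen=True)
class TransportResult:
    """Rank-wise transport map between two lineage-size distributions.

    ``pairs`` columns: ``src_rank`` / ``tgt_rank`` (1 = largest lineage),
    ``x`` / ``y`` (RPM sizes), ``weight`` (integer transport units from the
    lcm expansion) and ``log2fc`` (= log2 y - log2 x).  ``total_units`` is
    lcm(N, M).
    """

    pairs: pd.DataFrame
    n_source: int
    n_target: int
    total_units: int

    def cost(self) -> float:
        """Total transport cost: sum of per-unit |log2 fold change|."""
        return float((self.pairs["weight"] * self.pairs["log2fc"].abs()).sum())

    def mean_fold_change(self) -> float:
        """Unit-weighted mean log2 fold change."""
        w = self.pairs["weight"]
        return float((w * self.pairs["log2fc"]).sum() / w.sum())


@dataclass(frozen=True)
class FoldChangeCurve:
    """Replicate-averaged smoothed fold-change curve over source size.

    ``grid`` holds source sizes (RPM); ``log2fc`` the averaged LOWESS-smoothed
    log2 fold change; ``density`` the averaged lineage-unit density per grid
    point (the curve-thickness weight in rank plots).
    """

    grid: np.ndarray
    log2fc: np.ndarray
    density: np.ndarray
    n_replicates: int


def _ranked_rpm(dist: "LineageSizeDistribution | Sequence[float]") -> np.ndarray:
    if isinstance(dist, LineageSizeDistribution):
        arr = dist.rpm
    else:
        arr = np.sort(np.asarray(dist, dtype=float))[::-1]
    if arr.size == 0:
        raise ValueError("empty distribution")
    if arr[-1] <= 0:
        raise ValueError("sizes must be strictly positive (threshold the sample first)")
    return arr


def harmonize_thresholds(
    x: LineageSizeDistribution, y: LineageSizeDistribution
) -> tuple[LineageSizeDistribution, LineageSizeDistribution]:
    """Apply the higher of the two read thresholds to both samples.

    Lineages whose raw read count falls below ``max(threshold_x,
    threshold_y)`` are dropped from both samples, and both are re-normalized
    to RPM.
    """
    thr = max(x.read_threshold, y.read_threshold)
    out = []
    for d in (x, y):
        df = d.df[d.df["count"] >= thr].copy()
        if df.empty:
            raise ValueError(f"sample {d.sample!r} emptied by threshold harmonization at {thr}")
        df["rpm"] = df["count"] * 1e6 / df["count"].sum()
        df = df.sort_values(["rpm", "barcode"], ascending=[False, True], kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        out.append(
            LineageSizeDistribution(sample=d.sample, df=df.reset_index(drop=True), read_threshold=thr)
        )
    return out[0], out[1]


def lcm_weights(n: int, m: int) -> tuple[int, int]:
    """Units per lineage so both samples carry lcm(n, m) units in total."""
    if n < 1 or m < 1:
        raise ValueError("lineage counts must be >= 1")
    L = math.lcm(n, m)
    return L // n, L // m


def rank_transport(
    x: "LineageSizeDistribution | Sequence[float]",
    y: "LineageSizeDistribution | Sequence[float]",
) -> TransportResult:
    """Rank-wise optimal transport with virtual lcm expansion.

    Both size lists are sorted descending; x units and y units are paired in
    rank order by merging the two weighted lists.  The result minimizes the
    summed per-unit |log2 fold change| over all unit bijections.
    """
    xv = _ranked_rpm(x)
    yv = _ranked_rpm(y)
    n, m = xv.size, yv.size
    wx, wy = lcm_weights(n, m)
    rows = []
    i = j = 0
    rx, ry = wx, wy
    while i < n and j < m:
        u = min(rx, ry)
        rows.append((i + 1, j + 1, xv[i], yv[j], u))
        rx -= u
        ry -= u
        if rx == 0:
            i += 1
            rx = wx
        if ry == 0:
            j += 1
            ry = wy
    pairs = pd.DataFrame(rows, columns=["src_rank", "tgt_rank", "x", "y", "weight"])
    pairs["log2fc"] = np.log2(pairs["y"]) - np.log2(pairs["x"])
    return TransportResult(
        pairs=pairs, n_source=n, n_target=m, total_units=math.lcm(n, m)
    )


def brute_force_transport(
    x: Sequence[float], y: Sequence[float], max_units: int = 400
) -> float:
    """Minimal summed |log2 fold change| over all unit bijections (oracle).

    Materializes the lcm expansion and solves the assignment problem
    exactly; intended for validating :func:`rank_transport` on small
    instances only.
    """
    from scipy.optimize import linear_sum_assignment

    xv = _ranked_rpm(x)
    yv = _ranked_rpm(y)
    wx, wy = lcm_weights(xv.size, yv.size)
    xu = np.repeat(xv, wx)
    yu = np.repeat(yv, wy)
    if xu.size > max_units:
        raise ValueError(f"expansion of {xu.size} units exceeds max_units={max_units}")
    cost = np.abs(np.log2(xu)[:, None] - np.log2(yu)[None, :])
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def _resample_graph(result: TransportResult, trim_top: float, n_points: int, symmetric_trim: bool):
    """Trim top source lineages, then sample the unit-rank graph uniformly.

    Returns (log10 source sizes, log2 fold changes) at ``n_points`` evenly
    spaced transport units — an equal-weight representation of the weighted
    pair list ("resampling" the graph before smoothing).
    """
    pairs = result.pairs
    if trim_top > 0:
        cut = math.ceil(trim_top * result.n_source)
        keep = pairs["src_rank"] > cut
        if symmetric_trim:
            keep &= pairs["tgt_rank"] > math.ceil(trim_top * result.n_target)
        pairs = pairs[keep]
    if pairs.empty:
        raise ValueError("trimming removed every transport pair")
    w = pairs["weight"].to_numpy(dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(w)])
    u = (np.arange(n_points) + 0.5) / n_points * edges[-1]
    idx = np.searchsorted(edges, u, side="right") - 1
    idx = np.clip(idx, 0, len(pairs) - 1)
    return (
        np.log10(pairs["x"].to_numpy()[idx]),
        pairs["log2fc"].to_numpy()[idx],
    )


def fold_change_curve(
    results: Sequence[TransportResult],
    lowess_frac: float = 0.3,
    trim_top: float = 0.01,
    grid_points: int = 200,
    resample_points: int = 2000,
    symmetric_trim: bool = False,
) -> FoldChangeCurve:
    """LOWESS-smoothed, replicate-averaged fold-change curve.

    Per replicate pair the top ``trim_top`` fraction of source lineages
    (ceiling on the lineage count) is removed, the weighted pair graph is
    resampled at ``resample_points`` equally spaced transport units, and
    log2 fold change is LOWESS-smoothed against log10 source size.  Curves
    are then linearly interpolated onto a common log-spaced source-size grid
    and averaged.  The per-grid-point transport-unit density is returned as
    the curve-thickness weight.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if len(results) == 0:
        raise ValueError("need at least one transport result")
    sampled = [
        _resample_graph(r, trim_top, resample_points, symmetric_trim) for r in results
    ]
    lo = min(lx.min() for lx, _ in sampled)
    hi = max(lx.max() for lx, _ in sampled)
    if hi <= lo:
        grid_log = np.array([lo])
    else:
        grid_log = np.linspace(lo, hi, grid_points)
    curves = np.empty((len(sampled), grid_log.size))
    dens = np.empty_like(curves)
    for r, (lx, fc) in enumerate(sampled):
        sm = lowess(fc, lx, frac=lowess_frac, return_sorted=True)
        sx, sy = sm[:, 0], sm[:, 1]
        # collapse duplicate x for interpolation
        sx_u, first = np.unique(sx, return_index=True)
        curves[r] = np.interp(grid_log, sx_u, sy[first])
        if grid_log.size == 1:
            dens[r] = 1.0
        else:
            step = grid_log[1] - grid_log[0]
            edges = np.concatenate([grid_log - step / 2, [grid_log[-1] + step / 2]])
            h, _ = np.histogram(lx, bins=edges)
            dens[r] = h / h.sum()
    return FoldChangeCurve(
        grid=10.0 ** grid_log,
        log2fc=curves.mean(axis=0),
        density=dens.mean(axis=0),
        n_replicates=len(sampled),
    )


def fold_change_density(
    result: TransportResult, bins: int = 60
) -> pd.DataFrame:
    """Unit-weighted density of per-pair log2 fold changes.

    Histogram density over the fold-change range using the lcm unit weights
    (columns ``log2fc`` bin centers, ``density``).  A degenerate
    distribution (all pairs identical) yields a single occupied bin.
    """
    fc = result.pairs["log2fc"].to_numpy(dtype=float)
    w = result.pairs["weight"].to_numpy(dtype=float)
    if fc.size == 0:
        raise ValueError("empty transport result")
    lo, hi = fc.min(), fc.max()
    if math.isclose(lo, hi):
        lo, hi = lo - 0.5, hi + 0.5
    h, edges = np.histogram(fc, bins=bins, range=(lo, hi), weights=w, density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame({"log2fc": centers, "density": h})


def permutation_null_interval(
    x: "LineageSizeDistribution | Sequence[float]",
    y: "LineageSizeDistribution | Sequence[float]",
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Null interval for the mean fold change under sample-label exchange.

    Pools the two size lists, reassigns sizes to the two samples at random
    ``n_permutations`` times and recomputes the rank-transport mean log2
    fold change; returns the central ``1 - alpha`` interval.  A mean fold
    change inside this interval is consistent with no population shift.
    """
    xv = _ranked_rpm(x)
    yv = _ranked_rpm(y)
    pool = np.concatenate([xv, yv])
    rng = np.random.default_rng(seed)
    stats = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(pool)
        stats[p] = rank_transport(perm[: xv.size], perm[xv.size :]).mean_fold_change()
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
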