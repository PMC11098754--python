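"""Summary statistics of lineage-size distributions.

Concentration measures (top-percentile share, Lorenz-style cumulative
contribution, mean/median divergence), lineage counts over time, and
in-silico subsampling envelopes that ask how few starting lineages suffice
to recapitulate whole-tissue statistics.

All statistics are invariant to barcode relabeling and to proportional
rescaling of counts (they operate on normalized sizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pipeline import LineageSizeDistribution


def _sizes(dist: "LineageSizeDistribution | np.ndarray | Sequence[float]") -> np.ndarray:
    if isinstance(dist, LineageSizeDistribution):
        arr = dist.rpm
    else:
        arr = np.sort(np.asarray(dist, dtype=float))[::-1]
    if arr.size == 0:
        raise ValueError("empty lineage-size distribution")
    return arr


def top_percentile_share(dist, p: float) -> float:
    """Fraction of total size held by the largest ``ceil(p% * N)`` lineages."""
    if not 0 < p <= 100:
        raise ValueError("p must lie in (0, 100]")
    sizes = _sizes(dist)
    k = math.ceil(p / 100 * sizes.size)
    return float(sizes[:k].sum() / sizes.sum())


def size_range_orders(dist) -> float:
    """Orders of magnitude spanned by surviving lineage sizes: log10(max/min)."""
    sizes = _sizes(dist)
    if sizes[-1] <= 0:
        raise ValueError("sizes must be positive")
    return float(np.log10(sizes[0] / sizes[-1]))


def cumulative_contribution_curve(dist) -> pd.DataFrame:
    """Lorenz-style curve from the largest lineage down.

    Columns ``rank_fraction`` and ``mass_fraction``; the last point is
    (1, 1) and the curve is concave viewed from the largest side.
    """
    sizes = _sizes(dist)
    mass = np.cumsum(sizes) / sizes.sum()
    ranks = np.arange(1, sizes.size + 1) / sizes.size
    return pd.DataFrame({"rank_fraction": ranks, "mass_fraction": mass})


def divergence_summary(dist) -> dict[str, float]:
    """Median, mean, mean/median ratio and top-1% share of a distribution.

    The mean/median ratio and the top-percentile share both rise as clonal
    growth becomes more heterogeneous; for equal sizes the ratio is 1.
    """
    sizes = _sizes(dist)
    med = float(np.median(sizes))
    mean = float(sizes.mean())
    return {
        "median": med,
        "mean": mean,
        "mean_median_ratio": mean / med,
        "top1_share": top_percentile_share(sizes, 1.0),
    }


def lineage_count_over_time(
    tables: Mapping[float, Sequence["LineageSizeDistribution | Sequence[float]"]],
) -> pd.DataFrame:
    """Surviving-lineage counts per timepoint with replicate mean and s.e.m.

    ``tables`` maps timepoint -> replicate distributions.  The s.e.m. uses
    the n-1 denominator and is reported as NaN for a single replicate.
    """
    rows = []
    for t in sorted(tables):
        reps = tables[t]
        if len(reps) == 0:
            raise ValueError(f"no replicates at time {t}")
        counts = np.array([len(_sizes(r)) for r in reps], dtype=float)
        sem = float(counts.std(ddof=1) / math.sqrt(counts.size)) if counts.size > 1 else float("nan")
        rows.append(
            {
                "time": float(t),
                "n_replicates": counts.size,
                "counts": counts.tolist(),
                "mean": float(counts.mean()),
                "sem": sem,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SubsampleEnvelope:
    """Central estimate and 90% interval of a statistic under subsampling."""

    fraction: float
    n_draws: int
    median: float
    lower: float  # 5th percentile
    upper: float  # 95th percentile

    def __post_init__(self) -> None:
        if not self.lower <= self.median <= self.upper:
            raise ValueError("envelope must satisfy lower <= median <= upper")


def subsample_lineages(
    dist,
    fraction: float,
    n_draws: int,
    statistic: Callable[[np.ndarray], float],
    seed: int = 0,
    read_wise: bool = False,
) -> SubsampleEnvelope:
    """In-silico subsampling envelope of a statistic.

    Draws ``fraction`` of the lineages without replacement ``n_draws`` times
    (or, with ``read_wise=True``, binomially thins each lineage's size) and
    recomputes ``statistic`` on each draw.  Returns the median and the
    5th-95th percentile band.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    sizes = _sizes(dist)
    rng = np.random.default_rng(seed)
    if read_wise:
        vals = []
        for _ in range(n_draws):
            thinned = rng.binomial(np.round(sizes).astype(np.int64), fraction)
            thinned = thinned[thinned > 0]
            if thinned.size == 0:
                raise ValueError("read-wise thinning emptied the sample")
            vals.append(statistic(np.sort(thinned.astype(float))[::-1]))
    else:
        k = int(round(fraction * sizes.size))
        if k < 1:
            raise ValueError("fraction yields fewer than one lineage")
        vals = []
        for _ in range(n_draws):
            idx = rng.choice(sizes.size, size=k, replace=False)
            vals.append(statistic(np.sort(sizes[idx])[::-1]))
    vals_arr = np.asarray(vals, dtype=float)
    lo, med, hi = np.percentile(vals_arr, [5, 50, 95])
    return SubsampleEnvelope(
        fraction=fraction, n_draws=n_draws, median=float(med), lower=float(lo), upper=float(hi)
    )
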