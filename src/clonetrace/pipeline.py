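"""Read quantification: raw reads -> cleaned, thresholded, RPM lineage tables.

The pipeline order is fixed:

    extract -> correct sample indexes -> cluster viral barcodes
            -> cross-sample (20x) filter -> read-count threshold
            -> outlier-sample detection -> RPM normalization

Each stage only removes or merges read mass, never creates counts, and every
removal is recorded in provenance flags so a table can be audited after the
fact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import ReadSet, encode_seqs

UNASSIGNED = "__unassigned__"

FLAG_CROSS_SAMPLE = "removed_cross_sample"
FLAG_BELOW_THRESHOLD = "removed_below_threshold"
FLAG_OUTLIER = "outlier_sample"


@dataclass
class CountTable:
    """Per-sample barcode read counts with provenance flags.

    ``df`` is a long-format frame with columns ``sample``, ``barcode``,
    ``count`` and boolean flag columns naming the rule that zeroed a count.
    ``thresholds`` maps samples to their read-count threshold once
    :func:`apply_read_thresholds` has run.
    """

    df: pd.DataFrame
    thresholds: dict[str, int] = field(default_factory=dict)
    outliers: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        required = {"sample", "barcode", "count"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        if (self.df["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        for flag in (FLAG_CROSS_SAMPLE, FLAG_BELOW_THRESHOLD, FLAG_OUTLIER):
            if flag not in self.df.columns:
                self.df[flag] = False

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def counts(self, sample: str, surviving_only: bool = True) -> pd.Series:
        """Counts of one sample, indexed by barcode, sorted descending."""
        sub = self.df[self.df["sample"] == sample]
        if surviving_only:
            sub = sub[sub["count"] > 0]
        ser = sub.set_index("barcode")["count"]
        return ser.sort_values(ascending=False, kind="mergesort")

    def surviving(self) -> pd.DataFrame:
        """Rows with positive counts in non-outlier samples."""
        keep = (self.df["count"] > 0) & ~self.df["sample"].isin(self.outliers)
        return self.df[keep]

    def copy(self) -> "CountTable":
        return CountTable(self.df.copy(), dict(self.thresholds), set(self.outliers))


@dataclass
class LineageSizeDistribution:
    """A sample's surviving lineages as RPM-normalized sizes with ranks.

    ``df`` columns: ``barcode``, ``count``, ``rpm``, ``rank`` (1 = largest;
    ties broken by barcode lexicographic order).  ``read_threshold`` carries
    the sample threshold forward for transport-map harmonization.
    """

    sample: str
    df: pd.DataFrame
    read_threshold: int = 1

    def __post_init__(self) -> None:
        if len(self.df) and not math.isclose(self.df["rpm"].sum(), 1e6, rel_tol=1e-9):
            raise ValueError("RPM must sum to 1e6")

    @property
    def rpm(self) -> np.ndarray:
        """RPM sizes in rank order (descending)."""
        return self.df.sort_values("rank")["rpm"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# extraction and demultiplexing


def correct_sample_barcodes(
    observed: Iterable[str],
    known: Mapping[str, str],
    max_distance: int = 1,
) -> dict[str, str]:
    """Assign observed index sequences to known sample indexes.

    ``known`` maps sample name -> concatenated index sequence.  Each observed
    sequence is assigned to the unique known index within ``max_distance``
    mismatches; anything ambiguous or too far is left unassigned.  The known
    set must be pairwise separated by more than ``2 * max_distance``.
    """
    names = list(known)
    seqs = list(known.values())
    if len(set(len(s) for s in seqs)) > 1:
        raise ValueError("known indexes must share one length")
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if hamming(seqs[i], seqs[j]) <= 2 * max_distance:
                raise ValueError(
                    f"known indexes for {names[i]!r} and {names[j]!r} are too close "
                    f"for unambiguous correction at max_distance={max_distance}"
                )
    known_codes = encode_seqs(seqs)
    out: dict[str, str] = {}
    uniq = sorted(set(observed))
    if not uniq:
        return out
    obs_codes = encode_seqs(uniq)
    if obs_codes.shape[1] != known_codes.shape[1]:
        raise ValueError("observed index length differs from known index length")
    # distance of every observed index to every known one
    dist = (obs_codes[:, None, :] != known_codes[None, :, :]).sum(axis=2)
    best = dist.argmin(axis=1)
    bestd = dist[np.arange(len(uniq)), best]
    n_hit = (dist <= max_distance).sum(axis=1)
    for o, b, d, h in zip(uniq, best, bestd, n_hit):
        out[o] = names[b] if (d <= max_distance and h == 1) else UNASSIGNED
    return out


def extract_barcodes(
    reads: ReadSet,
    sample_sheet: pd.DataFrame,
    barcode_length: int = 50,
    max_index_distance: int = 1,
) -> CountTable:
    """Count (sample, viral barcode) pairs from raw reads.

    The viral barcode is the first ``barcode_length`` bases of read 1; the
    sample barcode is index 1 + index 2, error-corrected against the sample
    sheet.  Reads whose indexes cannot be assigned are kept under the
    ``__unassigned__`` pseudo-sample rather than dropped.
    """
    if len(reads) and len(reads.read1[0]) < barcode_length:
        raise ValueError("read 1 shorter than the barcode length")
    known = {
        row["sample"]: row["index1"] + row["index2"] for _, row in sample_sheet.iterrows()
    }
    pairs = [i1 + i2 for i1, i2 in zip(reads.index1, reads.index2)]
    assignment = correct_sample_barcodes(pairs, known, max_distance=max_index_distance)
    samples = [assignment[p] for p in pairs]
    barcodes = [r[:barcode_length] for r in reads.read1]
    df = (
        pd.DataFrame({"sample": samples, "barcode": barcodes})
        .groupby(["sample", "barcode"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return CountTable(df)


# ---------------------------------------------------------------------------
# viral-barcode clustering


def _segment_keys(bc: str, n_segments: int) -> list[tuple[int, str]]:
    L = len(bc)
    bounds = [round(i * L / n_segments) for i in range(n_segments + 1)]
    return [(i, bc[bounds[i] : bounds[i + 1]]) for i in range(n_segments)]


def cluster_viral_barcodes(
    counts: pd.Series,
    max_distance: int = 2,
    ratio: float = 10.0,
) -> pd.Series:
    """Directional error-correction clustering of one sample's barcode counts.

    Barcodes are visited from highest count to lowest.  A barcode is absorbed
    into an already-accepted seed when it lies within ``max_distance``
    mismatches and the seed's (running) count is at least ``ratio`` times its
    own; its reads are added to the seed.  Otherwise it becomes a new seed.
    Ties in count break lexicographically by barcode, so the result is
    deterministic.

    Candidate seeds are found by the pigeonhole principle: the barcode is cut
    into ``max_distance + 1`` segments, and any sequence within
    ``max_distance`` mismatches must match at least one segment exactly.
    """
    if counts.empty:
        return counts
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    order = counts.rename_axis("barcode").reset_index(name="cnt")
    order = order.sort_values(["cnt", "barcode"], ascending=[False, True], kind="mergesort")
    order = pd.Series(order["cnt"].to_numpy(), index=order["barcode"])
    n_seg = max_distance + 1
    seed_counts: dict[str, int] = {}
    seg_index: dict[tuple[int, str], list[str]] = {}
    merged_into: dict[str, str] = {}
    for bc, cnt in order.items():
        cands: set[str] = set()
        keys = _segment_keys(bc, n_seg)
        for key in keys:
            cands.update(seg_index.get(key, ()))
        target = None
        target_count = -1
        for seed in cands:
            if seed_counts[seed] >= ratio * cnt and hamming(bc, seed) <= max_distance:
                if seed_counts[seed] > target_count or (
                    seed_counts[seed] == target_count and seed < target
                ):
                    target, target_count = seed, seed_counts[seed]
        if target is not None:
            seed_counts[target] += int(cnt)
            merged_into[bc] = target
        else:
            seed_counts[bc] = int(cnt)
            for key in keys:
                seg_index.setdefault(key, []).append(bc)
    out = pd.Series(seed_counts, name=counts.name)
    return out.sort_values(ascending=False, kind="mergesort")


def cluster_table(table: CountTable, max_distance: int = 2, ratio: float = 10.0) -> CountTable:
    """Apply :func:`cluster_viral_barcodes` to every sample of a table."""
    frames = []
    for sample in table.df["sample"].unique():
        ser = table.counts(sample, surviving_only=False)
        clustered = cluster_viral_barcodes(ser, max_distance=max_distance, ratio=ratio)
        frames.append(
            pd.DataFrame(
                {"sample": sample, "barcode": clustered.index, "count": clustered.to_numpy()}
            )
        )
    return CountTable(pd.concat(frames, ignore_index=True), dict(table.thresholds), set(table.outliers))


# ---------------------------------------------------------------------------
# filtering


def filter_cross_sample(table: CountTable, factor: float = 20.0) -> CountTable:
    """Remove barcodes dominated ``factor``-fold by another sample.

    For every barcode present in two or more samples, its count is zeroed
    (and flagged) in any sample where some other sample carries it at
    ``factor`` times the count or more.  The comparison uses the pre-filter
    counts of all sample pairs, so the rule is symmetric and idempotent.
    """
    out = table.copy()
    df = out.df
    live = df["count"] > 0
    wide = df[live].pivot_table(index="barcode", columns="sample", values="count", fill_value=0)
    if wide.shape[1] < 2:
        return out
    vals = wide.to_numpy(dtype=float)
    # max over the *other* samples: where the row max is the own value, fall
    # back to the second largest
    sorted_vals = np.sort(vals, axis=1)
    top1 = sorted_vals[:, -1:]
    top2 = sorted_vals[:, -2:-1]
    max_other = np.where(vals == top1, top2, top1)
    remove = (vals > 0) & (max_other >= factor * vals)
    rm_frame = pd.DataFrame(remove, index=wide.index, columns=wide.columns)
    rm_long = rm_frame.stack()
    rm_long = rm_long[rm_long]
    rm_keys = set(rm_long.index)
    mask = np.array([(b, s) in rm_keys for b, s in zip(df["barcode"], df["sample"])])
    df.loc[mask, FLAG_CROSS_SAMPLE] = True
    df.loc[mask, "count"] = 0
    return out


def estimate_read_threshold(
    counts: pd.Series | np.ndarray,
    floor: int = 1,
    method: str = "valley",
    bin_width: float = 0.25,
) -> int:
    """Sample-specific read threshold separating true lineages from noise.

    ``method="valley"`` (default): histogram log10 counts in bins of
    ``bin_width`` and place the threshold at the deepest interior valley —
    the emptiest bin that has fuller bins on both sides, breaking ties
    toward the lowest count.  Sequencing-error residue piles up at low
    counts while true lineages sit higher, so the valley marks the
    noise/signal boundary; with no interior valley (unimodal or uniform
    counts) the result is ``floor``.

    ``method="knee"``: the point of maximal perpendicular distance from the
    chord of the (log10 rank, log10 count) curve, with runs of equal counts
    collapsed to one point.  Suited to plateau-cliff-floor shapes; on
    smoothly decaying distributions the chord crosses the curve and the
    knee drifts into the signal, which is why it is not the default.

    Barcodes with ``count >= threshold`` survive.  The result is clamped to
    at least ``floor``.
    """
    arr = np.sort(np.asarray(counts, dtype=float))[::-1]
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("sample has no nonzero counts")
    if arr.size == 1 or arr[0] == arr[-1]:
        return max(int(floor), 1)
    if method == "knee":
        ranks = np.arange(1, arr.size + 1)
        keep = np.concatenate([[True], arr[1:] != arr[:-1]])
        arr, ranks = arr[keep], ranks[keep]
        x = np.log10(ranks)
        y = np.log10(arr)
        dx, dy = x[-1] - x[0], y[-1] - y[0]
        norm = math.hypot(dx, dy)
        dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
        knee = int(np.argmax(dist))
        return max(int(arr[knee]), int(floor), 1)
    if method != "valley":
        raise ValueError(f"unknown threshold method {method!r}")
    logc = np.log10(arr)
    n_bins = max(2, int(math.ceil((logc.max() - logc.min()) / bin_width)) + 1)
    hist, edges = np.histogram(logc, bins=n_bins)
    best = None  # (depth, bin index)
    left_max = hist[0]
    right_max = np.maximum.accumulate(hist[::-1])[::-1]
    for i in range(1, len(hist) - 1):
        if left_max > hist[i] and right_max[i + 1] > hist[i]:
            if best is None or hist[i] < best[0]:
                best = (hist[i], i)
        left_max = max(left_max, hist[i])
    if best is None:
        return max(int(floor), 1)
    centre = (edges[best[1]] + edges[best[1] + 1]) / 2
    return max(int(math.ceil(10**centre)), int(floor), 1)


def apply_read_thresholds(
    table: CountTable,
    floor: int = 1,
    thresholds: Mapping[str, int] | None = None,
    method: str = "valley",
) -> CountTable:
    """Zero out counts below each sample's threshold and record thresholds."""
    out = table.copy()
    for sample in out.df["sample"].unique():
        ser = out.counts(sample)
        if thresholds is not None and sample in thresholds:
            thr = int(thresholds[sample])
        elif ser.empty:
            thr = floor
        else:
            thr = estimate_read_threshold(ser, floor=floor, method=method)
        out.thresholds[sample] = thr
        mask = (out.df["sample"] == sample) & (out.df["count"] > 0) & (out.df["count"] < thr)
        out.df.loc[mask, FLAG_BELOW_THRESHOLD] = True
        out.df.loc[mask, "count"] = 0
    return out


def detect_outlier_samples(
    table: CountTable,
    library_size: int,
    alpha: float = 1e-6,
    min_lineages: int = 1,
    min_reads: int = 1,
) -> CountTable:
    """Flag samples with excess cross-sample barcode overlap or low yield.

    Under independent barcode draws from a library of ``library_size``
    sequences, two samples with ``n_i`` and ``n_j`` surviving barcodes share
    ``n_i * n_j / L`` barcodes in expectation.  A pair whose observed overlap
    has a binomial tail probability below ``alpha`` flags both samples (the
    overlap itself cannot attribute blame).  Samples below ``min_lineages``
    surviving barcodes or ``min_reads`` total reads are flagged as
    low-yield.  Flagged samples stay in the table, marked, and are excluded
    from downstream distributions.
    """
    from scipy.stats import binom

    out = table.copy()
    samples = out.samples
    if len(samples) < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    bsets = {s: set(out.counts(s).index) for s in samples}
    reads = {s: int(out.counts(s).sum()) for s in samples}
    flagged: set[str] = set()
    for s in samples:
        if len(bsets[s]) < min_lineages or reads[s] < min_reads:
            flagged.add(s)
    for i, si in enumerate(samples):
        for sj in samples[i + 1 :]:
            ni, nj = len(bsets[si]), len(bsets[sj])
            if ni == 0 or nj == 0:
                continue
            overlap = len(bsets[si] & bsets[sj])
            p = min(1.0, nj / library_size)
            pval = float(binom.sf(overlap - 1, ni, p))
            if pval < alpha:
                flagged.update((si, sj))
    out.outliers |= flagged
    out.df.loc[out.df["sample"].isin(flagged), FLAG_OUTLIER] = True
    return out


# ---------------------------------------------------------------------------
# normalization and library diagnostics


def normalize_rpm(table: CountTable) -> dict[str, LineageSizeDistribution]:
    """RPM-normalize every surviving, non-outlier sample.

    RPM = count * 1e6 / sample total.  Ranks are assigned by descending RPM
    with ties broken by barcode lexicographic order.
    """
    out: dict[str, LineageSizeDistribution] = {}
    for sample in table.samples:
        if sample in table.outliers or sample == UNASSIGNED:
            continue
        ser = table.counts(sample)
        total = int(ser.sum())
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total reads after filtering")
        df = ser.reset_index()
        df.columns = ["barcode", "count"]
        df["rpm"] = df["count"] * 1e6 / total
        df = df.sort_values(["rpm", "barcode"], ascending=[False, True], kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        out[sample] = LineageSizeDistribution(
            sample=sample,
            df=df.reset_index(drop=True),
            read_threshold=table.thresholds.get(sample, 1),
        )
    return out


def hamming_distance_distribution(
    barcodes_a: Sequence[str],
    barcodes_b: Sequence[str] | None = None,
) -> pd.Series:
    """Histogram of pairwise Hamming distances.

    With one argument: all unordered pairs within the set (the
    within-replicate mode).  With two: all cross pairs (inter-replicate /
    inter-library mode).  Returns exact pair counts indexed by distance.
    """
    a = encode_seqs(list(barcodes_a))
    if barcodes_b is None:
        if a.shape[0] < 2:
            return pd.Series(dtype=int)
        dists = []
        for i in range(a.shape[0] - 1):
            dists.append((a[i + 1 :] != a[i]).sum(axis=1))
        d = np.concatenate(dists)
    else:
        b = encode_seqs(list(barcodes_b))
        if a.shape[1] != b.shape[1]:
            raise ValueError("barcode lengths differ between sets")
        d = (a[:, None, :] != b[None, :, :]).sum(axis=2).ravel()
    return pd.Series(d).value_counts().sort_index()


def run_quantification(
    reads: ReadSet,
    sample_sheet: pd.DataFrame,
    barcode_length: int = 50,
    max_index_distance: int = 1,
    cluster_max_distance: int = 2,
    cluster_ratio: float = 10.0,
    cross_sample_factor: float = 20.0,
    threshold_floor: int = 1,
    threshold_method: str = "valley",
    thresholds: Mapping[str, int] | None = None,
    library_size: int | None = None,
    outlier_alpha: float = 1e-6,
) -> tuple[CountTable, dict[str, LineageSizeDistribution], dict[str, int]]:
    """Full pipeline: reads -> filtered table + per-sample RPM distributions.

    Returns the final table, the RPM distributions, and a tally of reads/
    barcodes removed per rule (for audit logging).
    """
    raw = extract_barcodes(
        reads, sample_sheet, barcode_length=barcode_length, max_index_distance=max_index_distance
    )
    tally = {
        "reads_total": len(reads),
        "reads_unassigned": int(raw.df.loc[raw.df["sample"] == UNASSIGNED, "count"].sum()),
        "barcodes_raw": int((raw.df["sample"] != UNASSIGNED).sum()),
    }
    assigned = CountTable(raw.df[raw.df["sample"] != UNASSIGNED].copy())
    clustered = cluster_table(assigned, max_distance=cluster_max_distance, ratio=cluster_ratio)
    tally["barcodes_clustered"] = len(clustered.df)
    tally["barcodes_cluster_merged"] = tally["barcodes_raw"] - len(clustered.df)
    filtered = filter_cross_sample(clustered, factor=cross_sample_factor)
    tally["barcodes_cross_sample_removed"] = int(filtered.df[FLAG_CROSS_SAMPLE].sum())
    thresholded = apply_read_thresholds(
        filtered, floor=threshold_floor, thresholds=thresholds, method=threshold_method
    )
    tally["barcodes_below_threshold"] = int(thresholded.df[FLAG_BELOW_THRESHOLD].sum())
    if library_size is not None and len(thresholded.samples) >= 3:
        thresholded = detect_outlier_samples(
            thresholded, library_size=library_size, alpha=outlier_alpha
        )
    tally["samples_outlier_flagged"] = len(thresholded.outliers)
    dists = normalize_rpm(thresholded)
    tally["barcodes_surviving"] = int(sum(len(d) for d in dists.values()))
    return thresholded, dists, tally
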