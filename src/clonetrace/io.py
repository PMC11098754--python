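"""File formats and run configuration.

Tables are tab-separated UTF-8 with headers; FASTQ follows the Illumina
three-file convention (R1 with the viral barcode, I1/I2 with the sample
indexes) and round-trips losslessly through :class:`~clonetrace.synth.ReadSet`.
Gzip is handled transparently by file extension.
"""

from __future__ import annotations

import gzip
import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .pipeline import (
    FLAG_BELOW_THRESHOLD,
    FLAG_CROSS_SAMPLE,
    FLAG_OUTLIER,
    CountTable,
    LineageSizeDistribution,
)
from .synth import ReadSet

_COUNT_RE = re.compile(r"^\d+$")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a FASTQ file -> (ids, sequences); errors carry the record number."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    ids: list[str] = []
    seqs: list[str] = []
    with _open_text(path) as fh:
        try:
            for title, seq, _qual in FastqGeneralIterator(fh):
                ids.append(title)
                seqs.append(seq)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ {path} at record {len(ids) + 1}: {exc}") from exc
    return ids, seqs


def write_fastq(ids: Sequence[str], seqs: Sequence[str], path: str | Path) -> None:
    """Write sequences as FASTQ with constant placeholder qualities."""
    with _open_text(path, "wt") as fh:
        for rid, seq in zip(ids, seqs):
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_readset(reads: ReadSet, prefix: str | Path) -> dict[str, Path]:
    """Write a run as <prefix>_R1/_I1/_I2.fastq; returns the paths."""
    prefix = Path(prefix)
    ids = [f"read{i}" for i in range(len(reads))]
    paths = {}
    for tag, seqs in (("R1", reads.read1), ("I1", reads.index1), ("I2", reads.index2)):
        p = prefix.parent / f"{prefix.name}_{tag}.fastq"
        write_fastq(ids, seqs, p)
        paths[tag] = p
    return paths


def read_readset(r1: str | Path, i1: str | Path, i2: str | Path) -> ReadSet:
    """Read an R1/I1/I2 FASTQ triplet back into a :class:`ReadSet`."""
    out = ReadSet()
    ids = None
    for tag, path, dest in (("R1", r1, "read1"), ("I1", i1, "index1"), ("I2", i2, "index2")):
        file_ids, seqs = read_fastq(path)
        if ids is None:
            ids = file_ids
        elif file_ids != ids:
            raise ValueError(f"{tag} file {path} has read ids out of sync with R1")
        setattr(out, dest, seqs)
    return out


# ---------------------------------------------------------------------------
# tables

_FLAGS = (FLAG_CROSS_SAMPLE, FLAG_BELOW_THRESHOLD, FLAG_OUTLIER)


def write_counts_tsv(table: CountTable, path: str | Path) -> None:
    """Write a count table, its flags and its thresholds to one TSV.

    The per-sample threshold is repeated on each row (column
    ``read_threshold``); absent thresholds are written as 0.
    """
    df = table.df.copy()
    df["read_threshold"] = df["sample"].map(lambda s: table.thresholds.get(s, 0))
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> CountTable:
    """Read a count table, validating the schema and integer counts."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "barcode": str, "count": str})
    for col in ("sample", "barcode", "count"):
        if col not in df.columns:
            raise ValueError(f"count table {path} is missing required column {col!r}")
    bad = ~df["count"].map(lambda v: bool(_COUNT_RE.match(str(v))))
    if bad.any():
        first = df.loc[bad, "count"].iloc[0]
        raise ValueError(
            f"count table {path}: counts must be non-negative integers, got {first!r}"
        )
    df["count"] = df["count"].astype(np.int64)
    thresholds: dict[str, int] = {}
    if "read_threshold" in df.columns:
        thresholds = {
            s: int(t)
            for s, t in df.groupby("sample")["read_threshold"].first().items()
            if int(t) > 0
        }
        df = df.drop(columns=["read_threshold"])
    for flag in _FLAGS:
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    table = CountTable(df, thresholds)
    table.outliers = set(df.loc[df[FLAG_OUTLIER], "sample"].unique())
    return table


def write_rpm_tsv(dists: Mapping[str, LineageSizeDistribution], path: str | Path) -> None:
    """Write per-sample RPM distributions (6 decimal places) to one TSV."""
    frames = []
    for sample, d in sorted(dists.items()):
        df = d.df.copy()
        df.insert(0, "sample", sample)
        df["read_threshold"] = d.read_threshold
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_rpm_tsv(path: str | Path) -> dict[str, LineageSizeDistribution]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "barcode": str})
    needed = {"sample", "barcode", "count", "rpm", "rank"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"RPM table {path} is missing columns {sorted(missing)}")
    out = {}
    for sample, sub in df.groupby("sample"):
        thr = int(sub["read_threshold"].iloc[0]) if "read_threshold" in sub.columns else 1
        body = sub.drop(columns=["sample", "read_threshold"], errors="ignore").reset_index(drop=True)
        # repair floating drift from the fixed-precision write
        body["rpm"] = body["rpm"] * (1e6 / body["rpm"].sum())
        out[sample] = LineageSizeDistribution(sample=sample, df=body, read_threshold=thr)
    return out


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample": str, "index1": str, "index2": str})
    needed = {"sample", "index1", "index2"}
    missing = needed - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} is missing columns {sorted(missing)}")
    return sheet


# ---------------------------------------------------------------------------
# run configuration


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    """Growth-model stage: event rates (per day) and simulation layout."""

    r_s: float = 0.35
    r_a: float = 0.35
    r_n: float = 1.4
    r_dn: float = 0.0
    k: int = Field(2, ge=1)
    variant: str = "combined"
    t_end: float = 40.0
    n_lineages: int = Field(10_000, ge=1)
    record_times: list[float] = Field(default_factory=lambda: [11.0, 25.0, 40.0])


class GenerateConfig(_Strict):
    """Read-generation stage: library design and sequencing noise."""

    n_barcodes: int = Field(12_000, ge=1)
    barcode_length: int = Field(50, ge=8)
    identifier: str = "ACGTAC"
    replicates: int = Field(3, ge=1)
    depth: int = Field(1_000_000, ge=1)
    substitution_rate: float = Field(0.01, ge=0.0, le=1.0)
    cross_sample_rate: float = Field(0.001, ge=0.0, le=1.0)


class CountConfig(_Strict):
    barcode_length: int = 50
    max_index_distance: int = 1
    cluster_max_distance: int = 2
    cluster_ratio: float = 10.0


class FilterConfig(_Strict):
    cross_sample_factor: float = 20.0
    threshold_floor: int = 1
    threshold_method: str = "valley"
    outlier_alpha: float = 1e-6


class StatsConfig(_Strict):
    top_percent: float = 5.0
    subsample_fractions: list[float] = Field(default_factory=lambda: [0.01, 0.02, 0.05, 0.1])
    subsample_draws: int = 200


class CompareConfig(_Strict):
    lowess_frac: float = 0.3
    trim_top: float = 0.01


class RunConfig(_Strict):
    """Validated configuration for an end-to-end synthetic run."""

    seed: int = 0
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    generate: GenerateConfig = Field(default_factory=GenerateConfig)
    count: CountConfig = Field(default_factory=CountConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    compare: CompareConfig = Field(default_factory=CompareConfig)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration (unknown keys rejected)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def write_manifest(path: str | Path, payload: Mapping) -> None:
    """Record versions, seeds and parameters of a run."""
    import clonetrace

    meta = {"clonetrace_version": clonetrace.__version__}
    meta.update(payload)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
        fh.write("\n")
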