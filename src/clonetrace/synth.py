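"""Synthetic barcode libraries, clone tables and sequencing reads.

Emulates the data-generating process of a whole-organoid DNA-barcode
lineage-tracing experiment: semi-random viral barcode libraries carrying a
library-identifier tag, clone sizes taken from the stochastic growth model,
read counts multinomially proportional to clone size with per-base
substitution error and cross-sample contamination, and chimeric two-genotype
scenarios where one genotype's growth is penalized from a given day
(selection-drug analogue).

Everything is deterministic given seeds, so the whole quantification
pipeline is testable without any sequencing download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ModelParameters, OrganoidSimulation, _simulate_population

ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode_seqs(seqs: Sequence[str]) -> np.ndarray:
    """Sequences (equal length) -> uint8 code matrix (A,C,G,T -> 0..3)."""
    if len(seqs) == 0:
        return np.empty((0, 0), dtype=np.uint8)
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    return _CODE[arr]


def decode_seqs(codes: np.ndarray) -> list[str]:
    return [bytes(ALPHABET[row]).decode() for row in codes]


@dataclass(frozen=True)
class BarcodeLibrary:
    """A semi-random viral barcode library.

    All barcodes share a short fixed identifier tag at ``identifier_pos``
    (the feature that distinguishes the two co-infected libraries); the
    remaining positions are iid uniform over ACGT.
    """

    library_id: str
    identifier: str
    identifier_pos: int
    length: int
    barcodes: tuple[str, ...]

    def __post_init__(self) -> None:
        L = self.length
        for bc in self.barcodes:
            if len(bc) != L:
                raise ValueError("barcodes must all have the library length")
            if bc[self.identifier_pos : self.identifier_pos + len(self.identifier)] != self.identifier:
                raise ValueError("barcode lacks the library identifier at its position")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique within a library")

    @property
    def n_random_positions(self) -> int:
        return self.length - len(self.identifier)


def generate_barcode_library(
    n: int,
    library_id: str,
    identifier: str = "ACGTAC",
    identifier_pos: int = 0,
    length: int = 50,
    seed: int = 0,
) -> BarcodeLibrary:
    """Draw ``n`` unique semi-random barcodes of ``length`` bases."""
    if n < 1:
        raise ValueError("n must be >= 1")
    n_random = length - len(identifier)
    if n_random < 0:
        raise ValueError("length must be >= identifier length")
    if identifier_pos < 0 or identifier_pos + len(identifier) > length:
        raise ValueError("identifier does not fit at identifier_pos")
    if n_random < 32 and n > 4**n_random:
        raise ValueError(f"design space 4^{n_random} too small for {n} barcodes")
    rng = np.random.default_rng(seed)
    ident = np.frombuffer(identifier.encode(), dtype=np.uint8)
    ident_codes = _CODE[ident]
    seen: set[bytes] = set()
    rows: list[np.ndarray] = []
    while len(rows) < n:
        batch = rng.integers(0, 4, size=(max(n - len(rows), 16), length), dtype=np.uint8)
        batch[:, identifier_pos : identifier_pos + len(identifier)] = ident_codes
        for row in batch:
            key = row.tobytes()
            if key not in seen:
                seen.add(key)
                rows.append(row)
                if len(rows) == n:
                    break
    return BarcodeLibrary(
        library_id=library_id,
        identifier=identifier,
        identifier_pos=identifier_pos,
        length=length,
        barcodes=tuple(decode_seqs(np.array(rows))),
    )


def clones_from_simulation(
    sim: OrganoidSimulation,
    library: BarcodeLibrary,
    times: Sequence[float] | None = None,
    genotype: str = "WT",
) -> pd.DataFrame:
    """Assign one barcode per lineage; tabulate true cell counts over time.

    Returns a long-format table with columns ``barcode``, ``lineage_id``,
    ``genotype``, ``time``, ``cells``.
    """
    if len(library.barcodes) < sim.n_lineages:
        raise ValueError(
            f"library has {len(library.barcodes)} barcodes < {sim.n_lineages} lineages"
        )
    times = list(sim.times if times is None else times)
    frames = []
    for t in times:
        sizes = sim.sizes(t)
        frames.append(
            pd.DataFrame(
                {
                    "barcode": library.barcodes[: sim.n_lineages],
                    "lineage_id": np.arange(sim.n_lineages),
                    "genotype": genotype,
                    "time": t,
                    "cells": sizes,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class ReadSet:
    """One sequencing run: pooled records of (read 1, index 1, index 2).

    Read 1 carries the viral lineage barcode; the two index reads carry the
    sample barcode.  Stored as parallel lists in file order.
    """

    read1: list[str] = field(default_factory=list)
    index1: list[str] = field(default_factory=list)
    index2: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.read1)

    def extend(self, other: "ReadSet") -> None:
        self.read1.extend(other.read1)
        self.index1.extend(other.index1)
        self.index2.extend(other.index2)


def make_sample_sheet(
    samples: Sequence[str],
    index_length: int = 8,
    seed: int = 0,
    library_ids: Sequence[str] | None = None,
    conditions: Sequence[str] | None = None,
    timepoints: Sequence[float] | None = None,
    replicates: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Sample sheet with well-separated index pairs (pairwise Hamming > 2).

    Index pairs are drawn until every pair of samples differs at 3 or more
    positions of the concatenated index, so single-error correction is
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    while len(chosen) < len(samples):
        cand = rng.integers(0, 4, size=2 * index_length, dtype=np.uint8)
        if all(int((cand != c).sum()) > 2 for c in chosen):
            chosen.append(cand)
    seqs = decode_seqs(np.array(chosen))
    sheet = pd.DataFrame(
        {
            "sample": list(samples),
            "index1": [s[:index_length] for s in seqs],
            "index2": [s[index_length:] for s in seqs],
            "library_id": list(library_ids) if library_ids is not None else "lib1",
            "condition": list(conditions) if conditions is not None else "control",
            "timepoint": list(timepoints) if timepoints is not None else 0.0,
            "replicate": list(replicates) if replicates is not None else 1,
        }
    )
    return sheet


def _substitute(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-base substitutions to one of the three other bases."""
    if rate <= 0 or codes.size == 0:
        return codes
    mask = rng.random(codes.shape) < rate
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def generate_reads(
    clones: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    sample_clones: Mapping[str, pd.DataFrame] | None = None,
    depth: int = 1_000_000,
    substitution_rate: float = 0.0,
    cross_sample_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Sequence a clone table into reads.

    Per sample, ``depth`` reads are drawn multinomially with probabilities
    proportional to clone cell counts; each base of read 1 and of the index
    reads is substituted independently at ``substitution_rate``; a
    ``cross_sample_rate`` fraction of reads is reassigned to a random other
    sample (library contamination the downstream 20x rule must remove).

    ``clones`` needs columns ``barcode`` and ``cells``; the mapping from
    samples to clone tables is either one table for all samples (each sample
    resamples the same clones, e.g. replicates) or per-sample tables passed
    via ``sample_clones``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for r in (substitution_rate, cross_sample_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = list(sample_sheet["sample"])
    reads = ReadSet()
    true_sample: list[int] = []
    for si, sample in enumerate(samples):
        table = sample_clones[sample] if sample_clones is not None else clones
        table = table[table["cells"] > 0]
        if len(table) == 0:
            raise ValueError(f"no clones with positive cell count for sample {sample!r}")
        probs = table["cells"].to_numpy(dtype=float)
        probs = probs / probs.sum()
        counts = rng.multinomial(depth, probs)
        bc_codes = encode_seqs(list(table["barcode"]))
        row_idx = np.repeat(np.arange(len(table)), counts)
        reads.read1.extend(decode_seqs(_substitute(bc_codes[row_idx], substitution_rate, rng)))
        true_sample.extend([si] * depth)
    # index reads written after contamination reassignment
    assign = np.array(true_sample)
    if cross_sample_rate > 0 and len(samples) > 1:
        flip = rng.random(len(assign)) < cross_sample_rate
        other = rng.integers(0, len(samples) - 1, size=int(flip.sum()))
        cur = assign[flip]
        assign[flip] = np.where(other >= cur, other + 1, other)
    i1_codes = encode_seqs(list(sample_sheet["index1"]))
    i2_codes = encode_seqs(list(sample_sheet["index2"]))
    reads.index1 = decode_seqs(_substitute(i1_codes[assign], substitution_rate, rng))
    reads.index2 = decode_seqs(_substitute(i2_codes[assign], substitution_rate, rng))
    return reads


def generate_chimera_scenario(
    params_a: ModelParameters,
    params_b: ModelParameters,
    mix_fraction: float,
    ablation: Mapping[str, float],
    library_a: BarcodeLibrary,
    library_b: BarcodeLibrary,
    record_times: Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Two-genotype chimeric organoid with growth penalty on genotype A.

    Genotype A (fraction ``mix_fraction`` of starting cells) grows under
    ``params_a`` until ``ablation['start_day']``, then with all rates scaled
    by ``ablation['growth_penalty']`` (1 = no ablation, 0 = growth frozen).
    Genotype B is unaffected.  Returns a clone table (as
    :func:`clones_from_simulation`) with genotype labels ``A`` and ``B``.
    """
    if not 0.0 < mix_fraction < 1.0:
        raise ValueError("mix_fraction must be in (0, 1)")
    if set(library_a.barcodes) & set(library_b.barcodes):
        raise ValueError("genotype libraries share barcodes")
    start_day = float(ablation["start_day"])
    penalty = float(ablation["growth_penalty"])
    if penalty < 0:
        raise ValueError("growth_penalty must be >= 0")
    record_times = sorted(float(t) for t in record_times)
    t_end = record_times[-1]
    ss = np.random.SeedSequence(seed)
    rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(2))

    n_total = params_a.n_lineages
    n_a = max(1, int(round(mix_fraction * n_total)))
    n_b = max(1, n_total - n_a)

    pre_times = [t for t in record_times if t <= start_day]
    post_times = [t for t in record_times if t > start_day]
    # phase 1: unpenalized growth of A up to the ablation start; always record
    # the start-day state so phase 2 continues the same realization
    rec1 = list(pre_times)
    if not rec1 or not np.isclose(rec1[-1], start_day):
        rec1.append(start_day)
    pa1 = replace(params_a, n_lineages=n_a, t_end=start_day, record_times=tuple(rec1))
    sim_a1 = _simulate_population(pa1, rng_a)
    init = (sim_a1.s[-1], sim_a1.a[-1], sim_a1.n[-1])
    frames = []
    lib_a_codes = library_a.barcodes[:n_a]
    if pre_times:
        for i, t in enumerate(pre_times):
            frames.append(_clone_frame(lib_a_codes, "A", t, sim_a1.sizes(t)))
    if post_times:
        pa2 = replace(
            params_a,
            r_s=params_a.r_s * penalty,
            r_a=params_a.r_a * penalty,
            r_n=params_a.r_n * penalty,
            r_dn=params_a.r_dn * penalty,
            n_lineages=n_a,
            t_end=t_end - start_day,
            record_times=tuple(t - start_day for t in post_times),
        )
        if max(pa2.active_rates) > 0:
            sim_a2 = _simulate_population(pa2, rng_a, init=init)
            for t in post_times:
                frames.append(_clone_frame(lib_a_codes, "A", t, sim_a2.sizes(t - start_day)))
        else:  # growth frozen: sizes constant after start_day
            frozen = init[0] + init[1] + init[2]
            for t in post_times:
                frames.append(_clone_frame(lib_a_codes, "A", t, frozen))
    pb = replace(params_b, n_lineages=n_b, t_end=t_end, record_times=tuple(record_times))
    sim_b = _simulate_population(pb, rng_b)
    lib_b_codes = library_b.barcodes[:n_b]
    for t in record_times:
        frames.append(_clone_frame(lib_b_codes, "B", t, sim_b.sizes(t)))
    return pd.concat(frames, ignore_index=True)


def _clone_frame(barcodes: Sequence[str], genotype: str, time: float, cells) -> pd.DataFrame:
    cells = np.broadcast_to(np.asarray(cells), (len(barcodes),))
    return pd.DataFrame(
        {
            "barcode": list(barcodes),
            "lineage_id": np.arange(len(barcodes)),
            "genotype": genotype,
            "time": time,
            "cells": cells,
        }
    )
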