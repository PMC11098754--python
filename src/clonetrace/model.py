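"""Stochastic model of clonal growth through stem-cell division events.

A lineage (clone) is the progeny of one barcoded starting cell, described by
three integer counts:

* ``s`` — symmetrically dividing progenitors (one S divides into two S),
* ``a`` — asymmetrically dividing progenitors that self-renew while producing
  non-dividing progeny,
* ``n`` — non-dividing (postmitotic) cells, e.g. neurons.

Three event channels change the counts, each with a rate in events per cell
per day: symmetric division (``+1 S``, rate ``r_s``), transition
(``-1 S, +1 A``, rate ``r_a``) and asymmetric division (``+k N``, rate
``r_n``, drawn per A cell).  The optional direct-neurogenesis channel turns
one S cell into two N cells at rate ``r_dn``.  Time is advanced in fixed
steps ``dt = 0.01 / max(rates)``, and the number of events per channel per
step is drawn from a binomial distribution over the originating cells, so the
per-cell event probability per channel never exceeds 1% per step.

An organoid is simulated as many (by default 10,000) statistically
independent lineages, each starting from a single S cell.  An exact
event-by-event (Gillespie) sampler of the same continuous-time Markov chain
is provided as a validation oracle for the binomial stepper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VARIANTS = ("symmetric_only", "combined", "direct_neurogenesis")


class DegenerateModelError(ValueError):
    """All event rates are zero: no time step can be chosen."""


@dataclass(frozen=True)
class LineageState:
    """Cell counts of one lineage at one instant."""

    s: int
    a: int = 0
    n: int = 0

    def __post_init__(self) -> None:
        if min(self.s, self.a, self.n) < 0:
            raise ValueError(f"negative cell count in {self!r}")

    @property
    def size(self) -> int:
        return self.s + self.a + self.n


@dataclass(frozen=True)
class ModelParameters:
    """Rates (events per day), event multiplier and simulation layout.

    ``k`` is the number of postmitotic cells produced per asymmetric
    division event, abstracting intermediate-progenitor amplification.
    ``r_dn`` is only active in the ``direct_neurogenesis`` variant
    (one S cell turns into two N cells).
    """

    r_s: float
    r_a: float = 0.0
    r_n: float = 0.0
    r_dn: float = 0.0
    k: int = 1
    variant: str = "combined"
    t_end: float = 40.0
    n_lineages: int = 10_000
    record_times: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if min(self.r_s, self.r_a, self.r_n, self.r_dn) < 0:
            raise ValueError("rates must be non-negative")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if not self.record_times:
            object.__setattr__(self, "record_times", (self.t_end,))
        times = tuple(float(t) for t in self.record_times)
        if any(t < 0 or t > self.t_end for t in times):
            raise ValueError("record_times must lie in [0, t_end]")
        if list(times) != sorted(set(times)):
            raise ValueError("record_times must be strictly increasing")
        object.__setattr__(self, "record_times", times)

    @property
    def active_rates(self) -> tuple[float, ...]:
        """Rates of the channels that exist under the chosen variant."""
        if self.variant == "symmetric_only":
            return (self.r_s,)
        if self.variant == "combined":
            return (self.r_s, self.r_a, self.r_n)
        return (self.r_s, self.r_a, self.r_n, self.r_dn)

    def effective(self) -> "ModelParameters":
        """Parameters with variant-inactive channels zeroed out."""
        if self.variant == "symmetric_only":
            return replace(self, r_a=0.0, r_n=0.0, r_dn=0.0)
        if self.variant == "combined":
            return replace(self, r_dn=0.0)
        return self


@dataclass(frozen=True)
class LineageTrajectory:
    """States of one lineage at the requested record times."""

    times: tuple[float, ...]
    states: tuple[LineageState, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")
        if any(t1 <= t0 for t0, t1 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    @property
    def final_state(self) -> LineageState:
        return self.states[-1]


class OrganoidSimulation:
    """Result of simulating ``n_lineages`` independent lineages.

    Counts are stored as dense arrays of shape ``(n_times, n_lineages)``;
    ``trajectory(i)`` materializes one lineage's record on demand.
    """

    def __init__(
        self,
        params: ModelParameters,
        times: Sequence[float],
        s: np.ndarray,
        a: np.ndarray,
        n: np.ndarray,
    ) -> None:
        self.params = params
        self.times = tuple(float(t) for t in times)
        self.s = np.asarray(s)
        self.a = np.asarray(a)
        self.n = np.asarray(n)
        if not (self.s.shape == self.a.shape == self.n.shape):
            raise ValueError("count array shapes differ")
        if self.s.shape != (len(self.times), params.n_lineages):
            raise ValueError("count arrays do not match (n_times, n_lineages)")

    @property
    def n_lineages(self) -> int:
        return self.params.n_lineages

    def _time_index(self, time: float) -> int:
        for i, t in enumerate(self.times):
            if math.isclose(t, time, rel_tol=0.0, abs_tol=1e-9):
                return i
        raise KeyError(f"time {time} was not recorded (have {self.times})")

    def sizes(self, time: float) -> np.ndarray:
        """Total cells per lineage at a recorded time."""
        i = self._time_index(time)
        return self.s[i] + self.a[i] + self.n[i]

    def trajectory(self, lineage: int) -> LineageTrajectory:
        states = tuple(
            LineageState(int(self.s[t, lineage]), int(self.a[t, lineage]), int(self.n[t, lineage]))
            for t in range(len(self.times))
        )
        return LineageTrajectory(self.times, states)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: lineage_id, time, s, a, n."""
        n_t, n_l = self.s.shape
        return pd.DataFrame(
            {
                "lineage_id": np.tile(np.arange(n_l), n_t),
                "time": np.repeat(np.asarray(self.times), n_l),
                "s": self.s.ravel(),
                "a": self.a.ravel(),
                "n": self.n.ravel(),
            }
        )


def choose_time_step(params: ModelParameters) -> float:
    """Time step (days) guaranteeing <=1% per-cell event probability per channel.

    ``dt = 0.01 / max(rates)`` over the channels active under the variant.
    """
    rmax = max(params.active_rates)
    if rmax <= 0:
        raise DegenerateModelError(
            "all event rates are zero; no events can occur (trajectory is constant)"
        )
    return 0.01 / rmax


def double_event_probability(rate: float, dt: float) -> float:
    """P(one cell has >=2 events of a channel within dt), exponential waiting times.

    The binomial stepper allows at most one event per cell per channel per
    step; this closed form bounds the resulting truncation error:
    ``1 - exp(-r dt) - r dt exp(-r dt)``.
    """
    x = rate * dt
    return float(1.0 - math.exp(-x) - x * math.exp(-x))


def _step_arrays(
    s: np.ndarray,
    a: np.ndarray,
    n: np.ndarray,
    params: ModelParameters,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One binomial step applied to parallel lineage arrays (in place safe)."""
    p = params.effective()
    for r in (p.r_s, p.r_a, p.r_n, p.r_dn):
        if r * dt > 1.0:
            raise ValueError(f"rate*dt = {r * dt} > 1: binomial probability invalid")
    d_s = rng.binomial(s, p.r_s * dt) if p.r_s > 0 else np.zeros_like(s)
    d_a = rng.binomial(s, p.r_a * dt) if p.r_a > 0 else np.zeros_like(s)
    d_n = rng.binomial(a, p.r_n * dt) if p.r_n > 0 else np.zeros_like(a)
    if p.variant == "direct_neurogenesis" and p.r_dn > 0:
        d_dn = rng.binomial(s, p.r_dn * dt)
    else:
        d_dn = np.zeros_like(s)
    # All draws use the step-start state; S-removing draws may jointly
    # oversubscribe s + d_s and are capped to keep counts non-negative.
    avail = s + d_s
    d_a = np.minimum(d_a, avail)
    d_dn = np.minimum(d_dn, avail - d_a)
    s2 = s + d_s - d_a - d_dn
    a2 = a + d_a
    n2 = n + p.k * d_n + 2 * d_dn
    return s2, a2, n2


def step(
    state: LineageState, params: ModelParameters, dt: float, rng: np.random.Generator
) -> LineageState:
    """Advance one lineage by one binomial time step."""
    s = np.array([state.s], dtype=np.int64)
    a = np.array([state.a], dtype=np.int64)
    n = np.array([state.n], dtype=np.int64)
    s2, a2, n2 = _step_arrays(s, a, n, params, dt, rng)
    return LineageState(int(s2[0]), int(a2[0]), int(n2[0]))


def _step_schedule(params: ModelParameters) -> tuple[float, list[int]]:
    """dt and the cumulative step count at which each record time is reached.

    Record times are snapped to the nearest step boundary (the grid is fixed
    by the dt rule, so requested times may fall between steps).
    """
    try:
        dt = choose_time_step(params)
    except DegenerateModelError:
        # No events possible: constant trajectory, a single dummy step suffices.
        return float("inf"), [0 for _ in params.record_times]
    return dt, [int(round(t / dt)) for t in params.record_times]


def _simulate_population(
    params: ModelParameters,
    rng: np.random.Generator,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> OrganoidSimulation:
    """Vectorized binomial-step simulation of all lineages at once."""
    n_l = params.n_lineages
    if init is None:
        s = np.ones(n_l, dtype=np.int64)
        a = np.zeros(n_l, dtype=np.int64)
        n = np.zeros(n_l, dtype=np.int64)
    else:
        s, a, n = (np.array(x, dtype=np.int64, copy=True) for x in init)
    dt, marks = _step_schedule(params)
    out_s = np.empty((len(marks), n_l), dtype=np.int64)
    out_a = np.empty_like(out_s)
    out_n = np.empty_like(out_s)
    step_i = 0
    for rec, mark in enumerate(marks):
        while step_i < mark:
            s, a, n = _step_arrays(s, a, n, params, dt, rng)
            step_i += 1
        out_s[rec], out_a[rec], out_n[rec] = s, a, n
    return OrganoidSimulation(params, params.record_times, out_s, out_a, out_n)


def simulate_organoid(params: ModelParameters) -> OrganoidSimulation:
    """Simulate ``params.n_lineages`` independent lineages from single S cells.

    Deterministic given ``params.seed``.  Lineages are stepped as parallel
    arrays drawing from one generator; they remain statistically independent
    because every draw is conditionally independent across lineages.
    """
    rng = np.random.default_rng(params.seed)
    return _simulate_population(params, rng)


def simulate_lineage(
    params: ModelParameters, rng: np.random.Generator | None = None
) -> LineageTrajectory:
    """Simulate a single lineage from one S cell with the binomial stepper."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    one = replace(params, n_lineages=1)
    sim = _simulate_population(one, rng)
    return sim.trajectory(0)


def exact_ssa_reference(
    params: ModelParameters, rng: np.random.Generator | None = None
) -> LineageTrajectory:
    """Exact event-by-event (Gillespie) simulation of one lineage.

    Samples exponential waiting times with propensities ``r_s*s``, ``r_a*s``,
    ``r_n*a`` (and ``r_dn*s`` in the direct-neurogenesis variant); exact for
    the continuous-time Markov chain the binomial stepper approximates.
    Used as a validation oracle.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = params.effective()
    t = 0.0
    s, a, n = 1, 0, 0
    rec: list[LineageState] = []
    times = list(p.record_times)
    next_rec = 0

    def record_until(up_to: float) -> None:
        nonlocal next_rec
        while next_rec < len(times) and times[next_rec] <= up_to + 1e-12:
            rec.append(LineageState(s, a, n))
            next_rec += 1

    while t < p.t_end:
        props = (p.r_s * s, p.r_a * s, p.r_dn * s, p.r_n * a)
        total = sum(props)
        if total <= 0:
            break
        wait = rng.exponential(1.0 / total)
        record_until(min(t + wait, p.t_end))
        t += wait
        if t >= p.t_end:
            break
        u = rng.random() * total
        if u < props[0]:
            s += 1
        elif u < props[0] + props[1]:
            s -= 1
            a += 1
        elif u < props[0] + props[1] + props[2]:
            s -= 1
            n += 2
        else:
            n += p.k
    record_until(p.t_end)
    return LineageTrajectory(tuple(times), tuple(rec))


def cell_type_composition(sim: OrganoidSimulation, time: float) -> pd.DataFrame:
    """Per-lineage progenitor/postmitotic split at a recorded time.

    Columns: ``lineage_id``, ``progenitors`` (= s + a), ``postmitotic`` (= n),
    ``contains_s`` (lineage still holds symmetrically dividing cells).
    Cell totals over lineages are conserved by construction.
    """
    i = sim._time_index(time)
    return pd.DataFrame(
        {
            "lineage_id": np.arange(sim.n_lineages),
            "progenitors": sim.s[i] + sim.a[i],
            "postmitotic": sim.n[i],
            "contains_s": sim.s[i] > 0,
        }
    )


def _ranked_log_sizes(sizes: np.ndarray) -> np.ndarray:
    sizes = np.asarray(sizes, dtype=float)
    sizes = sizes[sizes > 0]
    return np.log(np.sort(sizes)[::-1])


def fit_rates_grid(
    observed_sizes: Iterable[float],
    grid: Iterable[tuple[float, float, float]],
    template: ModelParameters,
    observed_count: int | None = None,
) -> tuple[ModelParameters, float, pd.DataFrame]:
    """Grid-search event rates against an observed lineage-size distribution.

    For each candidate ``(r_s, r_a, r_n)`` an organoid is simulated from the
    template (same variant, horizon, lineage number and seed) and scored by
    the two-sample Kolmogorov-Smirnov statistic between ranked log sizes plus
    the relative error of the surviving-lineage count.  Returns the best
    parameters, their score, and the full score table.  Ties break toward the
    lexicographically smallest ``(r_s, r_a, r_n)``.
    """
    from scipy.stats import ks_2samp

    obs = np.asarray(list(observed_sizes), dtype=float)
    if obs.size == 0:
        raise ValueError("observed distribution is empty")
    grid = sorted(set((float(a_), float(b), float(c)) for a_, b, c in grid))
    if not grid:
        raise ValueError("rate grid is empty")
    n_obs = observed_count if observed_count is not None else int(obs.size)
    log_obs = np.log(obs[obs > 0])
    rows = []
    for r_s, r_a, r_n in grid:
        cand = replace(template, r_s=r_s, r_a=r_a, r_n=r_n)
        sim = simulate_organoid(cand)
        sizes = sim.sizes(cand.record_times[-1])
        log_sim = _ranked_log_sizes(sizes)
        ks = float(ks_2samp(log_obs, log_sim).statistic)
        count_err = abs(log_sim.size - n_obs) / n_obs
        rows.append((r_s, r_a, r_n, ks, count_err, ks + count_err))
    table = pd.DataFrame(
        rows, columns=["r_s", "r_a", "r_n", "ks", "count_rel_err", "score"]
    )
    best = table.sort_values(["score", "r_s", "r_a", "r_n"], kind="mergesort").iloc[0]
    best_params = replace(template, r_s=best.r_s, r_a=best.r_a, r_n=best.r_n)
    return best_params, float(best.score), table
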