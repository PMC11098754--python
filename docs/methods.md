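# Methods

## The clonal growth model

Each lineage is a continuous-time Markov chain on cell counts `(s, a, n)`
with event channels

* symmetric division: `s → s + 1`, propensity `r_s · s`,
* transition: `(s, a) → (s − 1, a + 1)`, propensity `r_a · s`,
* asymmetric division: `n → n + k`, propensity `r_n · a`,
* direct neurogenesis (optional variant): `(s, n) → (s − 1, n + 2)`,
  propensity `r_dn · s`.

There are no death events, so every lineage started from one S cell keeps
size ≥ 1, `n` is non-decreasing, and `a` is non-decreasing (the
asymmetrically dividing cell self-renews; the asymmetric event only adds
postmitotic cells).  `k` collapses intermediate-progenitor amplification
into a single instantaneous burst of `k` postmitotic cells; the
intermediate progenitors themselves are not tracked.

### Time stepping

The simulator advances all lineages in fixed steps `dt = 0.01 /
max(active rates)` and draws the number of events per channel per step
from a binomial distribution over the originating cells of the step-start
state (parallel update).  With at most a 1% per-cell event probability per
channel per step, the probability that one cell fires twice within a step
— which the binomial draw cannot represent — is
`1 − e^(−0.01) − 0.01·e^(−0.01) ≈ 4.97×10⁻⁵`, evaluated analytically by
`double_event_probability` and reported by `scripts/acceptance.py`.

Because symmetric division and the S-removing channels draw independently
from the same `s`, the removals can in principle oversubscribe
`s + d_s`; draws are then capped (transition first, then direct
neurogenesis) so counts stay non-negative.  Under the `dt` rule the cap
triggers with probability < 10⁻⁴ and is a bias-free tie-break in practice.

Requested record times are snapped to the nearest step boundary of the
fixed `dt` grid.

### Validation oracle

`exact_ssa_reference` implements the exact Gillespie algorithm for the
same chain (exponential waiting times over summed propensities).  The test
suite checks the binomial stepper against it distribution-wise
(two-sample Kolmogorov–Smirnov on final sizes, 10⁴ replicates, mixed
rates) and against the pure-birth (Yule) closed forms: mean size
`e^(r_s t)` and the geometric size law `P(size = m) = q(1−q)^(m−1)` with
`q = e^(−t r_s)`.

### Random numbers

`simulate_organoid` steps all lineages as parallel arrays drawing from a
single PCG64 generator seeded by `params.seed`.  Lineages remain
statistically independent (every draw is conditionally independent across
lineages) and runs are bit-reproducible given the seed; the array
formulation is what makes 10⁴ lineages over thousands of steps tractable.
`simulate_lineage` (single-trajectory API) spawns an independent
substream per call.  Every higher-level generator derives child seeds from
one root `SeedSequence`.

### Rate defaults

The default parameters (`r_s = r_a = 0.35`/day, `r_n = 1.4`/day, `k = 2`)
encode the regime in which the combined model reproduces organoid-like
clone-size distributions: symmetric-division and transition rates equal —
the regime diagnostics in the tests show that `r_s > r_a` drives
S-domination (the distribution approaches the symmetric-only shape) while
`r_s < r_a` depletes S cells and uniformizes sizes — with magnitudes
chosen so that a 40-day organoid reaches realistic sizes (S-retaining
lineages of 10³–10⁵ cells and a multi-order size spread).  They are
defaults of the synthetic scenario, not fitted constants;
`fit_rates_grid` exists to fit rates to a measured distribution by grid
search (two-sample KS distance on log sizes plus the relative error of
the surviving-lineage count, equal weights — an artifact scoring choice,
ties broken to the lexicographically smallest rate triple).

## The synthetic data generator

The generator emulates the statistical structure the pipeline assumes:

* semi-random 50-base barcode libraries with a fixed library-identifier
  tag (position and sequence configurable, since real oligo designs vary)
  and iid-uniform remaining positions;
* clone tables tied 1:1 to simulated lineages; whole-tissue sampling is
  destructive, so each (timepoint, replicate) sample is an independent
  organoid with its own barcode block;
* reads multinomial in clone cell counts at a configured depth, with
  independent per-base substitutions (default 1%) on barcode and index
  reads, and a configurable fraction of reads reassigned to a random
  other sample (default 0.1%) to model cross-sample contamination;
* chimeric two-genotype scenarios: genotype A simulated normally until an
  ablation start day, then with all rates scaled by a growth penalty
  (selection drugs are modelled as growth inhibition, not explicit death,
  because the growth model has no death channel); genotype B untouched;
  disjoint libraries keep genotypes separable.

Quality strings are constant placeholders — the pipeline is count-based
and never reads them.  Not modelled: PCR duplicates/UMIs, chimeric PCR
artifacts, quality-dependent error profiles, indels, lineage loss during
aggregate formation, spatial structure.  Passing tests on generated data
therefore demonstrate correctness of the quantification logic under
multinomial sampling with substitution noise and contamination — not
robustness to every artefact of real libraries.

## Quantification pipeline

Fixed stage order; each stage only removes or merges read mass and leaves
a provenance flag, so tallies reconcile exactly:

1. **Extraction** — barcode = first 50 bases of read 1 (0-based, half-open
   offsets in config); sample index = index 1 + index 2.  Unassignable
   reads go to an `__unassigned__` bucket, never silently dropped.
2. **Index correction** — assign to the unique known index within Hamming
   distance 1; the known set must be pairwise separated by more than
   twice that distance, making correction unambiguous.
3. **Viral-barcode clustering** — directional merge: visiting barcodes
   from highest count down, a barcode is absorbed by an accepted seed
   within Hamming distance 2 whose running count is ≥ 10× its own.
   Candidate seeds are found by pigeonhole segmentation (distance ≤ d
   implies an exact match in one of d+1 segments).  Ties break
   lexicographically; the result is deterministic.  The distance/ratio
   defaults are artifact choices and configurable.
4. **20× cross-sample rule** — a barcode is removed from any sample where
   some other sample carries it at ≥ 20× the count ("20× or higher" read
   inclusively), computed on pre-filter counts over all sample pairs, so
   the rule is symmetric and idempotent.
5. **Read threshold** — per sample.  Default method `valley`: histogram
   of log10 counts (0.25-wide bins); the threshold sits at the deepest
   interior valley (ties toward the lowest count), i.e. the gap between
   the error-residue mode at low counts and the true-lineage mode above
   it; with no interior valley the configurable floor applies.  A
   chord-knee method on the log-log rank-count curve (maximal
   perpendicular distance to the chord, equal-count runs collapsed) is
   available via `method="knee"`; it suits plateau–cliff–floor shapes but
   drifts into the signal on smoothly decaying distributions, which is
   why it is not the default.  Survivors satisfy `count ≥ threshold`.
6. **Outlier samples** — a sample pair whose barcode overlap exceeds the
   independent-draw expectation `n_i · n_j / L` (library complexity `L`)
   at a binomial tail probability below α (default 10⁻⁶) flags both
   members — overlap alone cannot attribute blame, a deliberate
   simplification; low lineage-count or low read-count floors also flag.
   Flagged samples stay in the table, marked, and are excluded from
   distributions.
7. **RPM** — `count × 10⁶ / sample total`; ranks descend by RPM with ties
   broken by barcode lexicographic order.

## Distribution statistics

Top-percentile share uses a ceiling on the lineage count (`ceil(p%·N)`
largest lineages).  The s.e.m. over replicates uses the n−1 denominator
and is reported as absent for a single replicate.  Subsampling envelopes
draw lineages without replacement (read-wise binomial thinning is an
option), recompute the statistic per draw, and report the median with the
5th–95th percentile band.  All statistics are invariant to barcode
relabeling and proportional count rescaling.

## Optimal transport

The comparison is strictly 1-D over lineage sizes.  Numerical choices:

* **Cost.** The minimized objective is `Σ |log2 x_i − log2 T(x_i)|`.
  Without the absolute value the sum is the same for every bijection
  (it telescopes to the difference of the two samples' log-size totals),
  so only a convex cost makes the rank-wise map the unique optimum; the
  absolute log fold change is the natural choice on log-scaled clone
  sizes.  Rank-wise optimality is verified against an exhaustive
  assignment-problem oracle in the tests.
* **lcm weighting.** Each of N source lineages counts as `lcm(N,M)/N`
  units, each of M target lineages as `lcm(N,M)/M`.  The expansion is
  virtual — sorted lists are merged into weighted pairs — because
  `lcm(N,M)` can be astronomically large; equality with the materialized
  expansion is asserted on small instances.
* **Threshold harmonization** applies the higher of the two read
  thresholds to both samples before RPM renormalization, so both
  distributions are truncated at the same detection limit.
* **Curves.** The top 1% of source lineages (ceiling, source side only;
  symmetric trim available) is removed as few and volatile; the weighted
  pair graph is resampled at 2,000 equally spaced transport units (an
  equal-weight representation of the lcm weights), LOWESS-smoothed
  against log10 source size (default fraction 0.3 — a smoothing-span
  choice, not a fitted constant), interpolated onto a common 200-point
  log-spaced grid and averaged across replicates; per-grid-point unit
  density is returned as the curve-thickness weight.
* **Densities** are unit-weighted histograms over log2 fold change; a
  degenerate result occupies a single bin.
* **Null interval.** `permutation_null_interval` pools the two samples,
  re-splits at random and recomputes the mean fold change, giving the
  no-shift band used by the control comparisons.
* Ties in size rank break by barcode identity; all orderings are
  deterministic.

## Problem sizes in the shipped tests

The test suite simulates organoids of 2,000–10,000 lineages over 25–40
model days, end-to-end read recovery at 10⁶ reads per sample (500 clones
spanning three orders of magnitude, 1% substitution, 0.1% cross-sample
bleed), transport oracles at N ≤ 8 with 100 random instances, and SSA
comparisons at 10⁴ replicates — sizes chosen to match the study-scale
conditions the defaults encode while keeping each check self-contained.

## Known limitations

* The growth model has no cell death, spatial structure, or molecular
  cell-type identity; `S/A` labels are division behaviours, not
  transcriptomic states.
* The relation between `k` and the number of intermediate-progenitor
  divisions is implemented literally as `k` postmitotic cells per event.
* Outlier flagging cannot attribute contamination to one member of a
  pair; manual QC calls (e.g. failed amplification) are only partially
  covered by the floor parameters.
* The knee threshold variant is shape-sensitive (see above); the valley
  default assumes error residue and true lineages form separable count
  modes, which very shallow sequencing can violate.
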