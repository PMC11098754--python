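# clonetrace

Whole-tissue DNA-barcode lineage tracing, in silico: stochastic models of
clonal growth by stem-cell division, a quantification pipeline that turns
barcode-sequencing reads into clone-size tables, distribution statistics
for clonal dominance, and a one-dimensional optimal-transport framework for
comparing lineage populations across conditions.

## Who this is for

In lineage-tracing experiments (e.g. cerebral organoids grown from ~24,000
starting cells, each carrying a unique 50-base viral DNA barcode), every
surviving clone's size is read out as the number of sequencing reads of its
barcode. `clonetrace` is for analysts of such data and for modellers who
want to test which division behaviours could produce an observed clone-size
distribution — without needing any sequencing download, since a synthetic
generator reproduces the statistical structure of the raw data end to end.

## The model

A lineage is a vector of cell counts `(s, a, n)`:

* `s` — symmetrically dividing progenitors,
* `a` — asymmetrically dividing progenitors (self-renewing),
* `n` — non-dividing (postmitotic) cells.

Three event channels with rates in events per cell per day:

| event | effect | rate | drawn per |
|---|---|---|---|
| symmetric division | `+1 S` | `r_s` | S cell |
| transition | `−1 S, +1 A` | `r_a` | S cell |
| asymmetric division | `+k N` | `r_n` | A cell |

(`k` abstracts intermediate-progenitor amplification; an optional direct
neurogenesis channel turns `1 S → 2 N` at rate `r_dn`.)  Time advances in
steps `dt = 0.01 / max(rates)`; event numbers per step are binomial with
mean `r·x` over the `x` originating cells, so the per-cell event
probability per channel is at most 1% per step and the probability of a
double event is ≈ 5×10⁻⁵.  An organoid is 10,000 independent lineages, each
started from one S cell.  An exact event-by-event (Gillespie) sampler of
the same Markov chain serves as a validation oracle.

The quantification pipeline implements, in fixed order: barcode extraction
(50 bases of read 1; sample indexes from the two index reads),
sample-index error correction, directional Hamming clustering of viral
barcodes (distance ≤ 2, 10× count ratio), the 20× cross-sample
contamination rule, per-sample read-count thresholds, outlier-sample
detection, and reads-per-million (RPM) normalization.

To compare two clone-size distributions `{x_i}` (N lineages) and `{y_j}`
(M lineages), both are re-thresholded at the higher of the two read
thresholds and RPM-renormalized; each x-lineage counts as `lcm(N,M)/N`
transport units and each y-lineage as `lcm(N,M)/M`; the transport map
minimizing `Σ |log2 x − log2 T(x)|` is the rank-wise pairing, whose
per-pair `log2` fold changes are summarized as LOWESS-smoothed curves over
source size (top 1% of source lineages removed, replicate-averaged) and as
unit-weighted densities.

## Worked example

`examples/01_growth_modes.py` contrasts pure symmetric division with the
combined S/A/N model at equal symmetric-division and transition rates:

```
symmetric-only model (rates in events/day: r_s=0.35, r_a=0.0, r_n=0.0, k=1)
  day   11: top-5% lineages hold 19.5% of cells | mean/median =  1.44 | size range = 2.68 orders
  day   25: top-5% lineages hold 19.6% of cells | mean/median =  1.43 | size range = 4.77 orders
  day   40: top-5% lineages hold 19.6% of cells | mean/median =  1.43 | size range = 4.65 orders

combined S/A/N model (rates in events/day: r_s=0.35, r_a=0.35, r_n=1.4, k=2)
  day   11: top-5% lineages hold 20.8% of cells | mean/median =  1.65 | size range = 2.82 orders
  day   25: top-5% lineages hold 34.1% of cells | mean/median =  3.29 | size range = 2.62 orders
  day   40: top-5% lineages hold 45.5% of cells | mean/median =  5.36 | size range = 2.74 orders
```

Under pure symmetric division the concentration statistics are stationary;
in the combined model the top-5% share and the mean/median ratio keep
rising, because lineages that lose their symmetrically dividing cells stall
while S-retaining lineages keep growing.  The other examples cover read
quantification on noisy synthetic FASTQ (`02`), in-silico subsampling
envelopes (`03`), and optimal-transport comparison of an ablated chimera
(`04`).

A thin CLI mirrors the library:

```bash
clonetrace simulate --r-s 0.35 --r-a 0.35 --r-n 1.4 --k 2 --t-end 40 \
    --record-times 11,25,40 --seed 1 --out sim.tsv
clonetrace run --config config.yaml --out-dir out/   # full synthetic run
```

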