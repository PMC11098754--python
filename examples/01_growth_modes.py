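"""Clonal growth modes: pure symmetric division vs the combined S/A/N model.

Simulates two organoids of 10,000 barcoded lineages each and prints how
concentrated the clone-size distribution becomes over time.  Pure symmetric
division (a Yule process) stays comparatively equipotent; the combined
model — symmetric division, S-to-A transition at an equal rate, and
asymmetric production of postmitotic cells — drives a growing share of the
tissue into a small set of dominant clones.
"""

import numpy as np

from clonetrace import ModelParameters, divergence_summary, simulate_organoid, top_percentile_share

TIMES = (11.0, 25.0, 40.0)

symmetric = ModelParameters(
    r_s=0.35, variant="symmetric_only", t_end=40.0, n_lineages=10_000,
    record_times=TIMES, seed=1,
)
combined = ModelParameters(
    r_s=0.35, r_a=0.35, r_n=1.4, k=2, t_end=40.0, n_lineages=10_000,
    record_times=TIMES, seed=1,
)

for name, params in [("symmetric-only", symmetric), ("combined S/A/N", combined)]:
    sim = simulate_organoid(params)
    print(f"\n{name} model (rates in events/day: "
          f"r_s={params.r_s}, r_a={params.r_a}, r_n={params.r_n}, k={params.k})")
    for t in TIMES:
        sizes = sim.sizes(t).astype(float)
        share = top_percentile_share(sizes, 5)
        ratio = divergence_summary(sizes)["mean_median_ratio"]
        orders = np.log10(sizes.max() / sizes.min())
        print(f"  day {t:4.0f}: top-5% lineages hold {share:5.1%} of cells | "
              f"mean/median = {ratio:5.2f} | size range = {orders:4.2f} orders")

print(
    "\nUnder pure symmetric division the top-5% share and mean/median ratio"
    "\nstay constant in time; in the combined model both keep rising as"
    "\nlineages that lose their symmetrically dividing cells stall while"
    "\nS-retaining lineages keep growing — a few clones end up dominating."
)
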