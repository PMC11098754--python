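"""Barcode-read quantification: from noisy reads back to clone sizes.

Builds two samples of 300 known clones each, sequences them to 200,000
reads per sample with 1% per-base substitution error and 0.1% cross-sample
contamination, then runs the full cleaning pipeline — index correction,
viral-barcode clustering, the 20x cross-sample rule, read-count
thresholding and RPM normalization — and compares the result to the truth.
"""

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from clonetrace import generate_barcode_library, generate_reads, make_sample_sheet, run_quantification

rng = np.random.default_rng(0)
library = generate_barcode_library(600, "lib1", seed=1)
sheet = make_sample_sheet(["organoid_1", "organoid_2"], seed=2)
truth = {
    "organoid_1": pd.DataFrame(
        {"barcode": library.barcodes[:300], "cells": 10 ** rng.uniform(0, 3, 300)}
    ),
    "organoid_2": pd.DataFrame(
        {"barcode": library.barcodes[300:], "cells": 10 ** rng.uniform(0, 3, 300)}
    ),
}
reads = generate_reads(
    None, sheet, sample_clones=truth, depth=200_000,
    substitution_rate=0.01, cross_sample_rate=0.001, seed=3,
)

table, dists, tally = run_quantification(reads, sheet)

print(f"reads total      : {tally['reads_total']}")
print(f"reads unassigned : {tally['reads_unassigned']} (index uncorrectable)")
print(f"raw barcodes     : {tally['barcodes_raw']}")
print(f"after clustering : {tally['barcodes_clustered']} "
      f"({tally['barcodes_cluster_merged']} error barcodes merged)")
print(f"20x rule removed : {tally['barcodes_cross_sample_removed']} cross-sample entries")
print(f"below threshold  : {tally['barcodes_below_threshold']}")
for sample in ("organoid_1", "organoid_2"):
    d = dists[sample]
    joined = d.df.set_index("barcode").join(truth[sample].set_index("barcode"), how="inner")
    rho = spearmanr(joined["rpm"], joined["cells"]).statistic
    print(f"{sample}: threshold={table.thresholds[sample]}, "
          f"recovered {len(d)}/300 lineages, Spearman(RPM, true size) = {rho:.4f}")

print(
    "\nSpearman near 1 means the size ranking survives sequencing error and"
    "\ncontamination intact.  The recovered count falls short of 300 only by"
    "\nthe smallest clones, whose handful of reads sits below the per-sample"
    "\ndetection threshold at this depth; deeper sequencing recovers them."
)
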