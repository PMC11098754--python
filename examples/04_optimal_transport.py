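"""Optimal transport between lineage populations: drug-ablation chimera.

Grows a chimeric organoid of two barcoded genotypes (50:50).  From day 11,
genotype A's division rates are scaled down to 30% (a selection-drug
analogue); genotype B is untouched.  Rank-wise 1-D optimal transport then
quantifies, per clone size, the minimal log2 fold change by which B
lineages outgrow their A counterparts — and a control comparison of B
against B from an untreated chimera shows no shift.
"""

import numpy as np

from clonetrace import (
    ModelParameters,
    generate_barcode_library,
    generate_chimera_scenario,
    permutation_null_interval,
    rank_transport,
)

params = ModelParameters(r_s=0.35, r_a=0.35, r_n=1.4, k=2, t_end=35.0, n_lineages=2000)
lib_a = generate_barcode_library(1000, "libA", identifier="AAACCC", seed=1)
lib_b = generate_barcode_library(1000, "libB", identifier="GGGTTT", seed=2)


def scenario(penalty, seed):
    return generate_chimera_scenario(
        params, params, mix_fraction=0.5,
        ablation={"start_day": 11.0, "growth_penalty": penalty},
        library_a=lib_a, library_b=lib_b,
        record_times=[15.0, 25.0, 35.0], seed=seed,
    )


treated = scenario(penalty=0.3, seed=10)
control = scenario(penalty=1.0, seed=11)

print("treated chimera (A rates x0.3 from day 11), transport A -> B:")
for t in (15.0, 25.0, 35.0):
    a = treated.query("genotype == 'A' and time == @t")["cells"].to_numpy(float)
    b = treated.query("genotype == 'B' and time == @t")["cells"].to_numpy(float)
    res = rank_transport(a, b)
    print(f"  day {t:4.0f}: mean log2 fold change = {res.mean_fold_change():+.2f}")

b_treated = treated.query("genotype == 'B' and time == 35.0")["cells"].to_numpy(float)
b_control = control.query("genotype == 'B' and time == 35.0")["cells"].to_numpy(float)
mean_fc = rank_transport(b_treated, b_control).mean_fold_change()
lo, hi = permutation_null_interval(b_treated, b_control, n_permutations=200, seed=12)
print(f"\ncontrol, B (treated run) vs B (untreated run) at day 35: "
      f"mean log2 fc = {mean_fc:+.3f}, permutation null [{lo:+.3f}, {hi:+.3f}]")

print(
    "\nA positive, growing mean fold change means the untouched genotype"
    "\nprogressively outgrows the ablated one clone-for-clone, while the"
    "\nB-vs-B control staying inside the null shows no intrinsic difference."
)
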