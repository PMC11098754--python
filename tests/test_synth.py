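"""Synthetic data generators: libraries, clone tables, reads, chimeras."""

import math

import numpy as np
import pandas as pd
import pytest

from clonetrace.model import ModelParameters, simulate_organoid
from clonetrace.pipeline import hamming_distance_distribution
from clonetrace.synth import (
    clones_from_simulation,
    generate_barcode_library,
    generate_chimera_scenario,
    generate_reads,
    make_sample_sheet,
)


class TestBarcodeLibrary:
    def test_single_barcode_carries_identifier(self):
        lib = generate_barcode_library(1, "lib1", identifier="ACGTAC", seed=0)
        assert len(lib.barcodes) == 1
        assert lib.barcodes[0].startswith("ACGTAC")
        assert len(lib.barcodes[0]) == 50

    def test_barcodes_unique_and_deterministic(self):
        a = generate_barcode_library(500, "lib1", seed=7)
        b = generate_barcode_library(500, "lib1", seed=7)
        assert a.barcodes == b.barcodes
        assert len(set(a.barcodes)) == 500

    def test_two_libraries_classifiable_by_identifier(self):
        l1 = generate_barcode_library(100, "lib1", identifier="AAACCC", seed=1)
        l2 = generate_barcode_library(100, "lib2", identifier="GGGTTT", seed=2)
        for bc in l1.barcodes:
            assert bc.startswith("AAACCC") and not bc.startswith("GGGTTT")
        for bc in l2.barcodes:
            assert bc.startswith("GGGTTT")

    def test_mean_pairwise_hamming(self):
        # iid uniform bases differ with probability 3/4 per random position
        lib = generate_barcode_library(300, "lib1", identifier="ACGTAC", seed=3)
        n_random = lib.n_random_positions
        hist = hamming_distance_distribution(lib.barcodes)
        mean = (hist.index.to_numpy() * hist.to_numpy()).sum() / hist.sum()
        expected = 0.75 * n_random
        sd = math.sqrt(n_random * 0.75 * 0.25)
        assert abs(mean - expected) <= 3 * sd / math.sqrt(300)

    def test_design_space_exhaustion(self):
        with pytest.raises(ValueError, match="design space"):
            generate_barcode_library(17, "lib1", identifier="ACGTAC", length=8, seed=0)


class TestClonesFromSimulation:
    def test_unit_clones_and_conservation(self):
        p = ModelParameters(r_s=0.0, t_end=2.0, n_lineages=50, record_times=(1.0, 2.0), seed=0)
        sim = simulate_organoid(p)
        lib = generate_barcode_library(50, "lib1", seed=1)
        clones = clones_from_simulation(sim, lib)
        assert (clones["cells"] == 1).all()
        for t in (1.0, 2.0):
            assert clones.loc[clones["time"] == t, "cells"].sum() == sim.sizes(t).sum()

    def test_deterministic(self):
        p = ModelParameters(r_s=0.5, r_a=0.5, r_n=1.0, t_end=3.0, n_lineages=40, seed=5)
        lib = generate_barcode_library(40, "lib1", seed=2)
        a = clones_from_simulation(simulate_organoid(p), lib)
        b = clones_from_simulation(simulate_organoid(p), lib)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_barcodes(self):
        p = ModelParameters(r_s=0.5, t_end=1.0, n_lineages=100, seed=0)
        lib = generate_barcode_library(10, "lib1", seed=1)
        with pytest.raises(ValueError, match="barcodes"):
            clones_from_simulation(simulate_organoid(p), lib)


class TestGenerateReads:
    def _sheet(self, n=1, seed=0):
        return make_sample_sheet([f"s{i}" for i in range(1, n + 1)], seed=seed)

    def test_single_clone_exact_reads(self):
        lib = generate_barcode_library(1, "lib1", seed=0)
        clones = pd.DataFrame({"barcode": [lib.barcodes[0]], "cells": [5]})
        reads = generate_reads(clones, self._sheet(), depth=100, seed=1)
        assert len(reads) == 100
        assert set(reads.read1) == {lib.barcodes[0]}

    def test_multinomial_proportions(self):
        lib = generate_barcode_library(2, "lib1", seed=0)
        clones = pd.DataFrame({"barcode": list(lib.barcodes), "cells": [9000, 1000]})
        depth = 100_000
        reads = generate_reads(clones, self._sheet(), depth=depth, seed=2)
        frac = np.mean([r == lib.barcodes[0] for r in reads.read1])
        se = math.sqrt(0.9 * 0.1 / depth)
        assert abs(frac - 0.9) <= 3 * se

    def test_substitution_error_fraction(self):
        # P(>=1 error) = 1 - (1-rate)^L
        lib = generate_barcode_library(1, "lib1", seed=0)
        clones = pd.DataFrame({"barcode": [lib.barcodes[0]], "cells": [1]})
        depth = 50_000
        reads = generate_reads(clones, self._sheet(), depth=depth, substitution_rate=0.01, seed=3)
        frac = np.mean([r != lib.barcodes[0] for r in reads.read1])
        expected = 1 - 0.99**50
        se = math.sqrt(expected * (1 - expected) / depth)
        assert abs(frac - expected) <= 3 * se

    def test_cross_sample_reassignment_rate(self):
        lib = generate_barcode_library(2, "lib1", seed=0)
        sheet = self._sheet(2, seed=4)
        sc = {
            "s1": pd.DataFrame({"barcode": [lib.barcodes[0]], "cells": [1]}),
            "s2": pd.DataFrame({"barcode": [lib.barcodes[1]], "cells": [1]}),
        }
        depth = 50_000
        reads = generate_reads(None, sheet, sample_clones=sc, depth=depth,
                               cross_sample_rate=0.01, seed=5)
        # reads carrying s1's clone but s2's indexes are contamination
        i1 = sheet.set_index("sample")["index1"]
        moved = sum(
            1 for r, ix in zip(reads.read1, reads.index1)
            if r == lib.barcodes[0] and ix == i1["s2"]
        )
        se = math.sqrt(0.01 * 0.99 * depth)
        assert abs(moved - 0.01 * depth) <= 4 * se

    def test_empty_clone_set_rejected(self):
        clones = pd.DataFrame({"barcode": [], "cells": []})
        with pytest.raises(ValueError, match="clones"):
            generate_reads(clones, self._sheet(), depth=10, seed=0)


class TestChimeraScenario:
    def _setup(self, penalty, seed=0, t_end=20.0):
        pa = ModelParameters(r_s=0.35, r_a=0.35, r_n=1.4, k=2, t_end=t_end, n_lineages=400)
        la = generate_barcode_library(200, "libA", identifier="AAACCC", seed=1)
        lb = generate_barcode_library(200, "libB", identifier="GGGTTT", seed=2)
        return generate_chimera_scenario(
            pa, pa, mix_fraction=0.5,
            ablation={"start_day": 11.0, "growth_penalty": penalty},
            library_a=la, library_b=lb,
            record_times=[11.0, t_end], seed=seed,
        )

    def test_zero_penalty_freezes_genotype_a(self):
        clones = self._setup(penalty=0.0)
        a = clones[clones["genotype"] == "A"].pivot(index="barcode", columns="time", values="cells")
        assert (a[20.0] == a[11.0]).all()
        b = clones[clones["genotype"] == "B"].pivot(index="barcode", columns="time", values="cells")
        assert b[20.0].sum() > b[11.0].sum()

    def test_identity_penalty_keeps_growing(self):
        clones = self._setup(penalty=1.0)
        a = clones[clones["genotype"] == "A"].pivot(index="barcode", columns="time", values="cells")
        assert a[20.0].sum() > a[11.0].sum()
        # per-lineage sizes never shrink (no death events)
        assert (a[20.0] >= a[11.0]).all()

    def test_genotype_labels_and_disjoint_barcodes(self):
        clones = self._setup(penalty=0.5)
        by_geno = clones.groupby("genotype")["barcode"].apply(set)
        assert not (by_geno["A"] & by_geno["B"])

    def test_overlapping_libraries_rejected(self):
        pa = ModelParameters(r_s=0.3, t_end=5.0, n_lineages=10)
        lib = generate_barcode_library(10, "libA", seed=1)
        with pytest.raises(ValueError, match="share"):
            generate_chimera_scenario(
                pa, pa, 0.5, {"start_day": 2.0, "growth_penalty": 0.5},
                lib, lib, record_times=[5.0], seed=0,
            )
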