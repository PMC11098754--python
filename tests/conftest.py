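import numpy as np
import pandas as pd
import pytest

from clonetrace.pipeline import LineageSizeDistribution


def dist_from_sizes(sizes, sample="s", read_threshold=1) -> LineageSizeDistribution:
    """Build an RPM distribution directly from integer lineage sizes."""
    sizes = np.asarray(sizes)
    df = pd.DataFrame(
        {"barcode": [f"bc{i:06d}" for i in range(sizes.size)], "count": sizes.astype(np.int64)}
    )
    df = df[df["count"] > 0].copy()
    df["rpm"] = df["count"] * 1e6 / df["count"].sum()
    df = df.sort_values(["rpm", "barcode"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return LineageSizeDistribution(
        sample=sample, df=df.reset_index(drop=True), read_threshold=read_threshold
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
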