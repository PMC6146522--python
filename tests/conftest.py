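import numpy as np
import pandas as pd
import pytest

from mutspot import BaseCountMatrix, VariantTable


def make_variant_table(rows, samples=("2D", "SP4")):
    """Build a VariantTable from (chrom, pos, ref, alt, *counts) tuples.

    counts are (ref, alt) pairs in sample order.
    """
    data = {"chrom": [], "pos": [], "ref": [], "alt": []}
    for s in samples:
        data[f"{s}_ref_count"] = []
        data[f"{s}_alt_count"] = []
    for row in rows:
        chrom, pos, ref, alt, *counts = row
        data["chrom"].append(chrom)
        data["pos"].append(pos)
        data["ref"].append(ref)
        data["alt"].append(alt)
        for s, (rc, ac) in zip(samples, counts):
            data[f"{s}_ref_count"].append(rc)
            data[f"{s}_alt_count"].append(ac)
    return VariantTable(pd.DataFrame(data), list(samples))


@pytest.fixture
def small_matrix():
    """3 positions x 5 samples, clean coverage, no background."""
    counts = np.zeros((3, 5, 4), dtype=np.int64)
    counts[:, :, 0] = 1000  # all A
    positions = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10, 20, 30]})
    return BaseCountMatrix(counts, positions, ["T1", "T2", "T3", "R1", "R2"])
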