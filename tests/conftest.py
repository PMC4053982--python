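import numpy as np
import pandas as pd
import pytest

from ascn import simulate


@pytest.fixture
def flat_bias():
    """GC bias that does nothing, for tests about count expectations."""
    return lambda gc: np.ones_like(np.asarray(gc, dtype=float))


@pytest.fixture
def small_profile():
    """A 20 Mb single-chromosome genome with balanced, LOH and gained states.

    The LOH region occupies a whole arm: diploid LOH has the same coverage
    as balanced diploid, so segmentation can only separate the two at a
    coverage boundary (here, the centromere).
    """
    mb = 1_000_000
    return pd.DataFrame(
        [
            ("chr1", "p", 0, 10 * mb, 2, 0),
            ("chr1", "q", 10 * mb, 16 * mb, 2, 1),
            ("chr1", "q", 16 * mb, 20 * mb, 3, 1),
        ],
        columns=["chrom", "arm", "start", "end", "total_cn", "minor_cn"],
    )


@pytest.fixture
def uniform_profile():
    """Copy-neutral diploid genome, 4 Mb."""
    mb = 1_000_000
    return pd.DataFrame(
        [("chr1", "p", 0, 2 * mb, 2, 1), ("chr1", "q", 2 * mb, 4 * mb, 2, 1)],
        columns=["chrom", "arm", "start", "end", "total_cn", "minor_cn"],
    )


def make_bins(values, chrom="chr1", arm="p", bin_size=10_000, start=0):
    """Bin table from an array of ratios (nan = missing)."""
    values = np.asarray(values, dtype=float)
    starts = start + np.arange(len(values)) * bin_size
    return pd.DataFrame({
        "chrom": chrom, "arm": arm,
        "start": starts, "end": starts + bin_size,
        "ratio": values,
        "n_windows_used": np.where(np.isfinite(values), 50, 0),
    })
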