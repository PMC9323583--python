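import numpy as np
import pytest

from fdretina.synthetic import VesselTreeParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_tree_params():
    """Reduced vessel tree for fast unit tests."""
    return VesselTreeParams(size_px=128, n_roots=4, max_segments=400,
                            max_depth=18)


def brute_force_box_counts(mask, sizes):
    """Independent oracle: per-cell occupancy scan, top-left anchored grid,
    partial edge cells included."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    counts = []
    for s in sizes:
        n = 0
        for r0 in range(0, h, s):
            for c0 in range(0, w, s):
                if mask[r0:r0 + s, c0:c0 + s].any():
                    n += 1
        counts.append(n)
    return counts


def brute_force_icc(y, model):
    """Independent ICC oracle from explicitly summed ANOVA mean squares."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = sum(k * (sum(y[i, :]) / k - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (sum(y[:, j]) / n - grand) ** 2 for j in range(k))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_cols + ss_err) / (n * (k - 1))
    if model == "ICC_1_1":
        return (msr - msw) / (msr + (k - 1) * msw)
    if model == "ICC_3_1":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
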