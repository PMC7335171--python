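import itertools

import numpy as np
import pandas as pd
import pytest

from nmdquant import FeatureCountTable, SampleSheet


@pytest.fixture
def two_gene_table() -> FeatureCountTable:
    """Two genes x (exon, intron) x two samples."""
    return FeatureCountTable(
        pd.DataFrame(
            {
                "gene_id": ["A", "A", "B", "B"],
                "feature_type": ["exon", "intron", "exon", "intron"],
                "length_bp": [1000, 2000, 500, 4000],
                "s1": [10, 2, 100, 5],
                "s2": [12, 3, 90, 4],
            }
        )
    )


@pytest.fixture
def two_group_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "group": ["case", "control"],
                "library_size": [1_000_000, 1_000_000],
            }
        )
    )


def mann_whitney_enumeration(a, b, alternative: str) -> float:
    """Brute-force exact Mann-Whitney p over all labelings (oracle)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    combined = np.concatenate([a, b])
    na = a.size

    def u_stat(x, y):
        gt = sum(1 for xi in x for yi in y if xi > yi)
        eq = sum(1 for xi in x for yi in y if xi == yi)
        return gt + 0.5 * eq

    u_obs = u_stat(a, b)
    us = np.array(
        [
            u_stat(combined[list(idx)], np.delete(combined, list(idx)))
            for idx in itertools.combinations(range(combined.size), na)
        ]
    )
    p_ge = float(np.mean(us >= u_obs))
    p_le = float(np.mean(us <= u_obs))
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def grid_search_zero_intercept(x, y, points=2001, passes=4) -> float:
    """SSE-minimising slope by coarse-to-fine grid search (oracle).

    The initial bracket uses the Cauchy-Schwarz bound
    |beta| <= sqrt(sum(y^2) / sum(x^2)), which always contains the
    minimiser of the through-origin SSE.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bound = 1.0 + float(np.sqrt((y @ y) / (x @ x)))
    lo, hi = -bound, bound
    for _ in range(passes):
        grid = np.linspace(lo, hi, points)
        sse = ((y[None, :] - grid[:, None] * x[None, :]) ** 2).sum(axis=1)
        best = grid[np.argmin(sse)]
        half = (hi - lo) / (points - 1)
        lo, hi = best - 2 * half, best + 2 * half
    return float(best)
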