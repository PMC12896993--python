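"""VAF distribution comparison (two-sample Kolmogorov-Smirnov) and histograms."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RsMutError
from .model import VariantSet

#: Below this smaller-sample size the exact KS null distribution is used.
EXACT_KS_MAX_N = 25


@dataclass(frozen=True)
class KsResult:
    d_statistic: float
    p_value: float
    n_a: int
    n_b: int


def ks_compare(vafs_a: Sequence[float], vafs_b: Sequence[float]) -> KsResult:
    """Two-sided two-sample KS test on VAF samples.

    D is the exact supremum of the ECDF difference; the p-value uses the
    exact null distribution when min(n) <= 25 and the asymptotic Kolmogorov
    distribution otherwise.  Ties follow the usual ECDF convention.
    """
    a = np.asarray(list(vafs_a), dtype=float)
    b = np.asarray(list(vafs_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise RsMutError("ks_compare requires two non-empty samples")
    method = "exact" if min(a.size, b.size) <= EXACT_KS_MAX_N else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return KsResult(float(res.statistic), float(min(res.pvalue, 1.0)), a.size, b.size)


def vaf_histogram(vs: VariantSet | Sequence[float], bin_width: float = 0.05) -> pd.DataFrame:
    """Histogram of VAFs over [0, 1] with the last bin closed at 1.

    Returns (bin_left, bin_right, count, frequency); frequencies sum to 1
    for non-empty input.
    """
    vafs = vs.vafs() if isinstance(vs, VariantSet) else list(vs)
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 12)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    counts, _ = np.histogram(np.asarray(vafs, dtype=float), bins=edges)
    total = counts.sum()
    freq = counts / total if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": freq,
        }
    )
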