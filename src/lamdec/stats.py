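"""Compartment-level hypothesis tests and depth-resolved summaries.

Kruskal-Wallis omnibus comparisons (tie-corrected, df = groups - 1),
two-tailed Wilcoxon rank-sum / signed-rank pairwise tests, the Fano-factor
vs decoding-performance correlation, and running-window kurtosis of metric
profiles across depth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CompartmentComparison:
    metric: str
    groups: dict
    h_statistic: float
    p_value: float
    df: int
    medians: dict
    mean_se: dict
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def omnibus_compare(samples: dict, metric: str = "",
                    pairwise: bool = True) -> CompartmentComparison:
    """Kruskal-Wallis across compartments plus pairwise rank-sum follow-ups."""
    names = list(samples)
    groups = [np.asarray(samples[k], dtype=float) for k in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    pw = []
    if pairwise:
        for a, b in itertools.combinations(names, 2):
            s, pv = pairwise_compare(samples[a], samples[b], paired=False)
            pw.append(dict(a=a, b=b, statistic=s, p=pv))
    return CompartmentComparison(
        metric=metric, groups=samples, h_statistic=float(h),
        p_value=float(p), df=len(groups) - 1,
        medians={k: float(np.median(g)) for k, g in zip(names, groups)},
        mean_se={k: (float(np.mean(g)),
                     float(np.std(g, ddof=1) / np.sqrt(len(g))))
                 for k, g in zip(names, groups)},
        pairwise=pd.DataFrame(pw))


def pairwise_compare(a, b, paired: bool = False):
    """Two-tailed Wilcoxon test: rank-sum (unpaired) or signed-rank (paired).

    Exact p-values below n = 25 per group, normal approximation with
    continuity correction above.  Identical paired vectors (all-zero
    differences) return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        method = "exact" if len(d) <= 25 and not np.any(d == 0) else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                             correction=(method == "approx"))
        return float(res.statistic), float(res.pvalue)
    method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if method == "exact" and ties:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def ff_performance_correlation(mean_ff, mean_accuracy,
                               method: str = "pearson"):
    """Correlation between per-subpopulation mean Fano factor and accuracy."""
    x = np.asarray(mean_ff, dtype=float)
    y = np.asarray(mean_accuracy, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


def running_kurtosis(values, depths, window: float = 100.0,
                     min_count: int = 4, centers=None) -> pd.DataFrame:
    """Sample (Pearson, non-excess) kurtosis in a sliding depth window.

    Windows with fewer than ``min_count`` values, or degenerate (constant)
    windows, are skipped.
    """
    values = np.asarray(values, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if centers is None:
        centers = np.sort(np.unique(depths))
    rows = []
    for c in np.asarray(centers, dtype=float):
        mask = np.abs(depths - c) <= window / 2.0
        v = values[mask]
        if len(v) < min_count or np.all(v == v[0]):
            continue
        k = stats.kurtosis(v, fisher=False, bias=True)
        rows.append(dict(depth=float(c), kurtosis=float(k), n=int(len(v))))
    return pd.DataFrame(rows, columns=["depth", "kurtosis", "n"])
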