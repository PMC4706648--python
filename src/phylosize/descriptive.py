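"""Descriptive layer: skewness, the D'Agostino skew test, weighted moments.

Body-size macroevolution arguments often start from the shape of the size
frequency distribution: strong right skew on the log scale is the classic
vertebrate pattern. This module provides the moment-ratio sample skewness
g1, its D'Agostino (1970) normality test, a richness-weighted variant in
which each terminal taxon is represented proportionally to its species
richness, and per-clade location/spread summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SkewTestResult",
    "sample_skewness",
    "dagostino_skew_test",
    "richness_weighted_skewness",
    "clade_summary",
    "histogram_table",
]

MIN_SKEWTEST_N = 9


@dataclass(frozen=True)
class SkewTestResult:
    """Two-sided D'Agostino test of zero skewness."""

    g1: float
    z: float
    p: float
    n: int


def _check_values(values, min_n: int) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite value in input")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: all values identical")
    return x


def sample_skewness(values) -> float:
    """Moment-ratio skewness g1 = m3 / m2^(3/2), biased central moments."""
    x = _check_values(values, 3)
    return float(stats.skew(x, bias=True))


def dagostino_skew_test(values) -> SkewTestResult:
    """D'Agostino (1970) normalizing transformation of g1; two-sided p.

    Requires n >= 9 for the transformation to be trustworthy.
    """
    x = _check_values(values, MIN_SKEWTEST_N)
    z, p = stats.skewtest(x)
    return SkewTestResult(g1=sample_skewness(x), z=float(z), p=float(p), n=x.size)


def richness_weighted_skewness(values, weights) -> float:
    """g1 from weighted central moments, frequency-weight semantics.

    With integer weights this equals :func:`sample_skewness` of the list in
    which each value is replicated ``weight`` times; equal weights recover
    the unweighted statistic exactly.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1:
        raise ValueError("values and weights must be 1-d and the same length")
    if np.any(w < 0):
        raise ValueError("negative weight")
    wtot = w.sum()
    if wtot <= 0:
        raise ValueError("total weight must be positive")
    mean = np.sum(w * x) / wtot
    d = x - mean
    m2 = np.sum(w * d**2) / wtot
    m3 = np.sum(w * d**3) / wtot
    if m2 == 0:
        raise ValueError("zero weighted variance")
    return float(m3 / m2**1.5)


def clade_summary(tips, clade_of=None) -> pd.DataFrame:
    """Per-clade count, mean and sd (n-1 denominator) of tip log-means.

    Parameters
    ----------
    tips : list of TipDistribution
    clade_of : mapping taxon -> clade, optional
        Overrides the ``clade`` attribute carried by the tips.
    """
    rows = []
    for t in tips:
        clade = clade_of[t.taxon] if clade_of is not None else t.clade
        if clade is None or clade == "":
            raise ValueError(f"tip {t.taxon!r} has no clade assignment")
        rows.append((clade, t.log_mean))
    if not rows:
        raise ValueError("no tips")
    df = pd.DataFrame(rows, columns=["clade", "log_mean"])
    out = (
        df.groupby("clade", sort=True)["log_mean"]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return out


def histogram_table(values, bins: int = 30) -> pd.DataFrame:
    """Bin edges/counts for external plotting (no figure rendering here)."""
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
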