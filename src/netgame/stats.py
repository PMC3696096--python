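"""Rank-association and comparison statistics used to validate game centrality.

Game-centrality sweeps produce many tied values (and so do degree and
betweenness on real networks), which is why the rank association of choice
here is the Goodman–Kruskal gamma: it is computed from concordant and
discordant pairs only and ignores ties entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GammaResult",
    "goodman_kruskal_gamma",
    "chi_square_gc",
    "mean_sem",
    "steiger_test",
]


@dataclass
class GammaResult:
    """Goodman–Kruskal gamma with its asymptotic uncertainty.

    gamma = (C - D) / (C + D) over concordant (C) and discordant (D)
    unordered index pairs; pairs tied in either variable count for neither.
    """

    gamma: float
    standard_error: float
    p_value: float
    concordant: int
    discordant: int


def goodman_kruskal_gamma(x: Sequence[float], y: Sequence[float]) -> GammaResult:
    """Goodman–Kruskal rank association between two equal-length sequences.

    The asymptotic standard error follows Goodman & Kruskal's per-observation
    formula; the two-sided p-value uses the normal approximation under the
    null gamma = 0.

    Raises
    ------
    ValueError
        If every pair is tied (gamma undefined) or lengths differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    prod = dx * dy
    # per-observation concordance counts (each unordered pair seen twice)
    c_i = (prod > 0).sum(axis=1)
    d_i = (prod < 0).sum(axis=1)
    C = int(c_i.sum()) // 2
    D = int(d_i.sum()) // 2
    if C + D == 0:
        raise ValueError("gamma undefined: every pair is tied")
    gamma = (C - D) / (C + D)
    # Goodman-Kruskal asymptotic SE (raw data: one observation per cell;
    # c_i/d_i count each unordered pair from both sides, hence the factors)
    se = 2.0 * np.sqrt(np.sum((D * c_i - C * d_i) ** 2.0)) / (C + D) ** 2
    # variance under the null gamma = 0, for the test statistic
    var0 = np.sum((c_i - d_i) ** 2.0) - 4.0 * (C - D) ** 2 / n
    if var0 > 0:
        z = (C - D) / np.sqrt(var0)
        p = 2.0 * sps.norm.sf(abs(z))
    else:
        p = 1.0
    return GammaResult(
        gamma=float(gamma),
        standard_error=float(se),
        p_value=float(p),
        concordant=C,
        discordant=D,
    )


def chi_square_gc(
    dist_a: Sequence[float],
    dist_b: Sequence[float],
    bins: int = 10,
) -> tuple[float, float]:
    """Two-sample homogeneity chi-square between two GC distributions.

    Both samples are binned on a shared equal-width grid over [0, 1];
    adjacent bins are pooled left-to-right until every expected count is at
    least 5, then the standard contingency chi-square is computed.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    edges = np.linspace(0.0, 1.0, bins + 1)
    ha, _ = np.histogram(np.clip(a, 0, 1), bins=edges)
    hb, _ = np.histogram(np.clip(b, 0, 1), bins=edges)
    table = np.vstack([ha, hb]).astype(float)

    def expected(t: np.ndarray) -> np.ndarray:
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()

    # pool sparse bins into their right neighbor (last bin pools leftward)
    while table.shape[1] > 1 and (expected(table) < 5).any():
        j = int(np.flatnonzero((expected(table) < 5).any(axis=0))[0])
        k = j + 1 if j + 1 < table.shape[1] else j - 1
        table[:, k] += table[:, j]
        table = np.delete(table, j, axis=1)
    if table.shape[1] < 2:
        raise ValueError("all mass in a single pooled bin; chi-square undefined")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error (sample SD / sqrt(n)).

    A single value yields SEM = nan; identical values yield SEM = 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sequence")
    if v.size == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def steiger_test(
    r_jk: float, r_jh: float, r_kh: float, n: int
) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing one variable.

    Compares corr(j, k) against corr(j, h) given corr(k, h) on the same n
    observations; returns (z, two-sided p).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r_jk, r_jh, r_kh):
        if not -1 <= r <= 1:
            raise ValueError("correlations must lie in [-1, 1]")
    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    rm2 = (r_jk**2 + r_jh**2) / 2.0
    f = min((1.0 - r_kh) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z_jk - z_jh) * np.sqrt((n - 3) / (2.0 * (1.0 - r_kh) * h))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
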