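"""Shared statistical primitives: exact Wilcoxon signed-rank and t tests.

The Wilcoxon signed-rank test is the group-level workhorse of the
searchlight analysis, so it is implemented here with an exact null
distribution for small samples.  "Exact" means the full distribution of the
positive-rank sum over all 2^n sign assignments, computed by dynamic
programming (a generating-function convolution, equivalent to brute-force
enumeration but polynomial time).  Midranks are used for tied absolute
values and zeros are dropped before ranking, so the exact distribution is
conditional on the observed rank multiset.  Above ``EXACT_WILCOXON_MAX_N``
the normal approximation with tie correction and a 0.5 continuity
correction is used.

scipy's :func:`scipy.stats.wilcoxon` cannot compute exact p-values in the
presence of ties, which are ubiquitous for the discrete tau-a values the
searchlight produces; that is why the test is authored here.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_signrank",
    "wilcoxon_signrank_many",
    "one_sample_t",
    "paired_t",
    "EXACT_WILCOXON_MAX_N",
]

#: largest n for which the exact signed-rank null distribution is used
EXACT_WILCOXON_MAX_N = 25

ONE_SIDED_GREATER = "one_sided_greater"
TWO_SIDED = "two_sided"
_TAILS = (ONE_SIDED_GREATER, TWO_SIDED)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a univariate test.

    ``exact`` is True only when the p-value comes from full enumeration of
    the null distribution.  ``degenerate`` marks zero-variance inputs, whose
    p-value is NaN and which callers must treat as non-significant.
    """

    statistic: float
    pvalue: float
    tail: str
    n: int
    df: int | None = None
    exact: bool = False
    degenerate: bool = False


@lru_cache(maxsize=4096)
def _signed_rank_sf(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Survival function P(W+ >= w) of the signed-rank sum.

    ``doubled_ranks`` are 2x the (mid)ranks so that they are integers even
    with ties; the returned array is indexed by the doubled statistic.
    Equivalent to enumerating all 2^n sign assignments.
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    pmf = counts / counts.sum()
    # sf[w] = P(W+ >= w), inclusive
    return np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])


def _exact_wilcoxon_p(doubled_ranks: np.ndarray, doubled_w: int, tail: str) -> float:
    sf = _signed_rank_sf(tuple(int(r) for r in np.sort(doubled_ranks)))
    p_greater = float(sf[doubled_w])
    if tail == ONE_SIDED_GREATER:
        return p_greater
    p_less = float(1.0 - sf[doubled_w + 1])
    return min(1.0, 2.0 * min(p_greater, p_less))


def _approx_wilcoxon_p(ranks: np.ndarray, w: float, tail: str) -> float:
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    if tail == ONE_SIDED_GREATER:
        return float(sps.norm.sf((w - mean - 0.5) / sd))
    z = (abs(w - mean) - 0.5) / sd
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def wilcoxon_signrank(
    values, mu0: float = 0.0, tail: str = ONE_SIDED_GREATER
) -> TestResult:
    """One-sample Wilcoxon signed-rank test of symmetric location ``mu0``.

    Zero differences are dropped (Wilcoxon's convention); tied absolute
    differences receive midranks.  Exact for n <= ``EXACT_WILCOXON_MAX_N``.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}, got {tail!r}")
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all values equal mu0: empty signed-rank test")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        doubled = np.rint(2.0 * ranks).astype(int)
        p = _exact_wilcoxon_p(doubled, int(round(2.0 * w)), tail)
        return TestResult(statistic=w, pvalue=p, tail=tail, n=n, exact=True)
    p = _approx_wilcoxon_p(ranks, w, tail)
    return TestResult(statistic=w, pvalue=p, tail=tail, n=n, exact=False)


def wilcoxon_signrank_many(
    samples: np.ndarray, mu0: float = 0.0, tail: str = ONE_SIDED_GREATER
) -> np.ndarray:
    """Column-wise :func:`wilcoxon_signrank` over an (n, m) array.

    Vectorizes the ranking; the exact survival function is cached per rank
    multiset, which makes whole-brain maps cheap because most voxels share
    their tie pattern.  Columns containing zeros (after subtracting mu0)
    fall back to the scalar routine.  Returns an array of m p-values.
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}, got {tail!r}")
    d = np.asarray(samples, dtype=float) - mu0
    if d.ndim != 2:
        raise ValueError("samples must be 2-D (observations x columns)")
    n, m = d.shape
    out = np.empty(m)
    has_zero = (d == 0.0).any(axis=0)
    clean = ~has_zero
    if clean.any():
        dc = d[:, clean]
        ranks = sps.rankdata(np.abs(dc), axis=0)
        w = np.where(dc > 0, ranks, 0.0).sum(axis=0)
        pc = np.empty(w.size)
        if n <= EXACT_WILCOXON_MAX_N:
            doubled = np.rint(2.0 * ranks).astype(int)
            doubled_sorted = np.sort(doubled, axis=0)
            dw = np.rint(2.0 * w).astype(int)
            for j in range(w.size):
                sf = _signed_rank_sf(tuple(doubled_sorted[:, j]))
                if tail == ONE_SIDED_GREATER:
                    pc[j] = sf[dw[j]]
                else:
                    pc[j] = min(1.0, 2.0 * min(sf[dw[j]], 1.0 - sf[dw[j] + 1]))
        else:
            for j in range(w.size):
                pc[j] = _approx_wilcoxon_p(ranks[:, j], w[j], tail)
        out[clean] = pc
    for j in np.flatnonzero(has_zero):
        out[j] = wilcoxon_signrank(samples[:, j], mu0=mu0, tail=tail).pvalue
    return out


def one_sample_t(values, mu0: float = 0.0, tail: str = TWO_SIDED) -> TestResult:
    """One-sample t test, t = (mean - mu0) / (sd / sqrt(n)), df = n - 1."""
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}, got {tail!r}")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("one-sample t test needs at least 2 observations")
    sd = x.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        # degenerate: no variability.  Data exactly at mu0 are maximally
        # consistent with it (t=0, p=1); a constant offset has no finite t.
        if x.mean() == mu0:
            return TestResult(
                statistic=0.0, pvalue=1.0, tail=tail, n=n, df=df, degenerate=True
            )
        sign = 1.0 if x.mean() > mu0 else -1.0
        return TestResult(
            statistic=sign * np.inf, pvalue=np.nan, tail=tail, n=n, df=df,
            degenerate=True,
        )
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    if tail == ONE_SIDED_GREATER:
        p = float(sps.t.sf(t, df))
    else:
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(statistic=float(t), pvalue=p, tail=tail, n=n, df=df)


def paired_t(a, b, tail: str = TWO_SIDED) -> TestResult:
    """Paired t test: one-sample t on the differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in shape: {a.shape} vs {b.shape}")
    return one_sample_t(a - b, 0.0, tail)
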