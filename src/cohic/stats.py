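"""Nonparametric and parametric tests used throughout the pipeline.

Implemented directly from their definitions: exact two-sided sign test,
Mood's median test (multi-group and pairwise-vs-control), Benjamini-
Hochberg step-up adjustment, Student's t-tests, Kruskal-Wallis with Dunn's
post hoc z-tests, and the t-test for a Pearson correlation. Only the
reference distributions (binomial, chi-square, t, normal) come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str
    notes: str = ""
    statistic_extra: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return bool(self.notes)


def sign_test(differences) -> TestResult:
    """Exact two-sided sign test on paired differences; zeros are dropped.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) for k positives among the
    n nonzero differences under Binomial(n, 1/2).
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return TestResult(np.nan, np.nan, 0, "sign", notes="no nonzero differences")
    k = int((nz > 0).sum())
    p_low = sps.binom.cdf(k, n, 0.5)
    p_high = sps.binom.sf(k - 1, n, 0.5)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return TestResult(float(k), float(p), n, "sign")


def moods_median_test(groups, pairwise_vs_control: bool = False,
                      continuity_correction: bool | None = None):
    """Mood's median test on two or more unpaired samples.

    Pools the data, dichotomizes each observation as above vs not-above the
    grand median (ties count as not-above), and tests the groups x 2
    contingency table with a chi-square statistic on (groups - 1) df. For
    two groups the Yates continuity correction is applied by default (the
    uncorrected 2x2 chi-square is anti-conservative at moderate n); pass
    ``continuity_correction=False`` for the raw statistic. Multi-group
    tables are never corrected. With ``pairwise_vs_control`` the first
    group is the control and one 2x2 test per remaining group is returned
    (raw p's, ready for bh_adjust).
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if pairwise_vs_control:
        control = samples[0]
        return [moods_median_test([control, g], continuity_correction=continuity_correction)
                for g in samples[1:]]
    pooled = np.concatenate(samples)
    grand = np.median(pooled)
    above = np.array([(g > grand).sum() for g in samples], dtype=float)
    below = np.array([len(g) - a for g, a in zip(samples, above)], dtype=float)
    notes = ""
    if any((g <= grand).all() and (g >= grand).all() for g in samples):
        notes = "a group is entirely at the grand median"
    table = np.vstack([above, below])
    col_tot = table.sum(axis=0)
    row_tot = table.sum(axis=1)
    total = table.sum()
    expected = np.outer(row_tot, col_tot) / total
    if (expected == 0).any():
        return TestResult(np.nan, np.nan, int(total), "moods-median",
                          notes="degenerate table (empty margin)")
    if continuity_correction is None:
        continuity_correction = len(samples) == 2
    resid = np.abs(table - expected)
    if continuity_correction and len(samples) == 2:
        resid = np.maximum(resid - 0.5, 0.0)
    chi2 = float((resid ** 2 / expected).sum())
    df = len(samples) - 1
    p = float(sps.chi2.sf(chi2, df))
    if (expected < 5).any():
        notes = (notes + "; " if notes else "") + "expected cell < 5"
    return TestResult(chi2, p, int(total), "moods-median", notes=notes,
                      statistic_extra={"df": df})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min_{j >= i} (p_(j) * m / j), capped at 1. NaN inputs stay NaN
    and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


def two_sample_t(a, b, paired: bool = False) -> TestResult:
    """Student's t-test: pooled-variance unpaired, or paired on differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        d = a - b
        n = d.size
        if n < 2:
            return TestResult(np.nan, np.nan, n, "paired-t", notes="n < 2")
        sd = d.std(ddof=1)
        if sd == 0:
            p = 1.0 if d.mean() == 0 else 0.0
            return TestResult(np.inf if d.mean() else 0.0, p, n, "paired-t",
                              notes="zero-variance differences")
        t = d.mean() / (sd / np.sqrt(n))
        p = 2 * sps.t.sf(abs(t), n - 1)
        return TestResult(float(t), float(p), n, "paired-t")
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return TestResult(np.nan, np.nan, na + nb, "unpaired-t", notes="group n < 2")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        same = a.mean() == b.mean()
        return TestResult(0.0 if same else np.inf, 1.0 if same else 0.0,
                          na + nb, "unpaired-t", notes="zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(p), na + nb, "unpaired-t",
                      statistic_extra={"df": df})


def _rank_with_ties(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    sx = x[order]
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1
        i = j + 1
    return ranks


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on (k-1) df."""
    samples = [np.asarray(g, dtype=float) for g in groups]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks = _rank_with_ties(pooled)
    h = 0.0
    start = 0
    for g in samples:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    correction = 1.0 - tie_term
    notes = ""
    if correction == 0:
        return TestResult(0.0, 1.0, n, "kruskal-wallis", notes="all values identical")
    h /= correction
    p = float(sps.chi2.sf(h, k - 1))
    if h == 0:
        p = 1.0
    return TestResult(float(h), p, n, "kruskal-wallis",
                      statistic_extra={"df": k - 1})


def kruskal_dunn(groups) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis followed by Dunn's pairwise z-tests, BH-adjusted.

    Returns the omnibus result and one TestResult per unordered group pair
    (i, j), i < j, with BH-adjusted two-sided p-values.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    omnibus = kruskal_wallis(samples)
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks = _rank_with_ties(pooled)
    mean_ranks = []
    start = 0
    for g in samples:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (12.0 * (n - 1))
    pairs = []
    raw_p = []
    k = len(samples)
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = samples[i].size, samples[j].size
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2 * sps.norm.sf(abs(z))
            pairs.append((i, j, float(z), ni + nj))
            raw_p.append(p)
    adj = bh_adjust(raw_p)
    results = [
        TestResult(z, float(q), n_eff, "dunn", statistic_extra={"pair": (i, j), "p_raw": float(p)})
        for (i, j, z, n_eff), p, q in zip(pairs, raw_p, adj)
    ]
    return omnibus, results


def correlation_t_test(x, y) -> TestResult:
    """Pearson r with the t-test t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return TestResult(np.nan, np.nan, n, "correlation-t", notes="n < 3 (df <= 0)")
    if x.std() == 0 or y.std() == 0:
        return TestResult(0.0, 1.0, n, "correlation-t", notes="zero-variance input",
                          statistic_extra={"r": 0.0})
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        return TestResult(np.inf if r > 0 else -np.inf, 0.0, n, "correlation-t",
                          notes="exact linear fit", statistic_extra={"r": r})
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return TestResult(float(t), float(p), n, "correlation-t",
                      statistic_extra={"r": r, "df": n - 2})
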