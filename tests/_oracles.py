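"""Naive, independent reimplementations used as oracles in the tests.

Everything here is deliberately brute force: explicit mid-rank formulas,
explicit sums of squared deviations, explicit dummy-coded least squares —
no calls into the package under test and no scipy/statsmodels shortcuts
for the quantity being checked.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def midranks(x) -> list[float]:
    """Average ranks (1-based); tied values share the mean of their ranks."""
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return math.nan
    return sxy / math.sqrt(sxx * syy)


def naive_spearman(x, y) -> float:
    return pearson(midranks(x), midranks(y))


def naive_synchrony(grid) -> tuple[float, int, int]:
    """Mean |rho| over plant pairs, skipping all-zero plants and NaN pairs."""
    rows = [row for row in grid if sum(row) > 0]
    vals, dropped = [], 0
    for a, b in combinations(rows, 2):
        rho = naive_spearman(a, b)
        if math.isnan(rho):
            dropped += 1
        else:
            vals.append(abs(rho))
    if not vals:
        return math.nan, 0, dropped
    return sum(vals) / len(vals), len(vals), dropped


def naive_cv(x, ddof: int = 1) -> float:
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - ddof)
    return math.sqrt(var) / mean


def naive_cvi(grid, ddof: int = 1) -> float:
    rows = [row for row in grid if sum(row) > 0]
    return sum(naive_cv(r, ddof) for r in rows) / len(rows)


def dummy_design(levels: list, values) -> np.ndarray:
    """Treatment (drop-first) dummy coding of a factor column."""
    uniq = sorted(set(levels))
    return np.column_stack(
        [[1.0 if v == u else 0.0 for v in levels] for u in uniq[1:]]
    ) if len(uniq) > 1 else np.empty((len(levels), 0))


def rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and residual df of a least-squares fit."""
    X = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), len(y) - int(np.linalg.matrix_rank(X))


def naive_type2_twoway(a, b, y) -> dict[str, tuple[float, float, float]]:
    """Type-II two-way ANOVA by explicit full/reduced model comparison.

    Returns {term: (ss, df, F)} for A, B and A:B with the F denominator
    taken from the full interaction model.
    """
    from scipy import stats

    y = np.asarray(y, dtype=float)
    A = dummy_design(list(a), a)
    B = dummy_design(list(b), b)
    AB = np.column_stack(
        [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    ) if A.shape[1] and B.shape[1] else np.empty((len(y), 0))
    full_rss, full_df = rss(np.column_stack([A, B, AB]), y)
    mse = full_rss / full_df

    out = {}
    for name, base, term in (
        ("a", B, A),
        ("b", A, B),
        ("a:b", np.column_stack([A, B]), AB),
    ):
        r0, d0 = rss(base, y)
        r1, d1 = rss(np.column_stack([base, term]), y)
        ss, df = r0 - r1, d0 - d1
        f = (ss / df) / mse
        p = float(stats.f.sf(f, df, full_df))
        out[name] = (ss, df, f, p)
    out["resid"] = (full_rss, full_df)
    return out


def naive_oneway(groups) -> tuple[float, float, float]:
    """One-way ANOVA F from explicit between/within sums of squares."""
    from scipy import stats

    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, df_b, float(stats.f.sf(f, df_b, df_w))


def naive_pooled_t(x, y) -> tuple[float, float]:
    """Two-sample pooled-variance t statistic and two-sided p."""
    from scipy import stats

    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    sp2 = (
        sum((v - mx) ** 2 for v in x) + sum((v - my) ** 2 for v in y)
    ) / (nx + ny - 2)
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, float(2 * stats.t.sf(abs(t), nx + ny - 2))
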