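"""Factorial inference on the descriptor table.

The workflow mirrors a two-step fixed-effects analysis of the flowering
descriptors: a three-factor screen (site, semester, accession with all
two-way interactions) to test whether accession carries any signal, then a
two-factor model (site, semester, site x semester) for the descriptors
``r_i`` and ``CV_i``, both with Type-II sums of squares.  A significant
site x semester interaction is decomposed by simple effects of site within
each semester and by all pairwise site comparisons per semester, with
Bonferroni adjustment.  The significance threshold for inference is
alpha = 0.005 (guarding against false positives across separately modelled
responses); model assumptions (Shapiro-Wilk normality of residuals,
Levene homogeneity across cells) are checked at 0.05 and annotate, never
block, the pipeline.

Type-II sums of squares test each term against the model containing every
other term that does not contain it, which makes main-effect tests
order-invariant and, on balanced designs, identical to the sequential
(Type-I) decomposition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

#: Inference threshold used throughout the two-step procedure.
DEFAULT_ALPHA = 0.005
#: Threshold for assumption (diagnostic) checks.
ASSUMPTION_ALPHA = 0.05


@dataclass(frozen=True)
class AovResult:
    """A Type-II ANOVA table plus the residuals of the underlying fit."""

    table: pd.DataFrame  # index: term names + 'Residual'; columns sum_sq, df, F, p
    response: str
    formula: str
    nobs: int
    residuals: np.ndarray = field(repr=False)
    ss_type: str = "II"

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def f_value(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table.index if t != "Residual"]


@dataclass(frozen=True)
class ComparisonSet:
    """Bonferroni-adjusted pairwise comparisons, organised by stratum."""

    frame: pd.DataFrame  # columns: stratum, group_a, group_b, n_a, n_b, t, p_raw, p_adj, significant
    m: int
    alpha: float
    response: str


@dataclass(frozen=True)
class AssumptionReport:
    """Diagnostics of an ANOVA: residual normality and variance homogeneity."""

    shapiro_p: float
    levene_p: float
    alpha: float
    n_groups: int

    @property
    def passed(self) -> bool:
        return (
            not math.isnan(self.shapiro_p)
            and not math.isnan(self.levene_p)
            and self.shapiro_p > self.alpha
            and self.levene_p > self.alpha
        )


def bonferroni(p: float | np.ndarray, m: int) -> np.ndarray:
    """Bonferroni adjustment over a family of ``m`` tests, capped at 1."""
    return np.minimum(1.0, m * np.asarray(p, dtype=float))


def _term_patsy(term: tuple[str, ...]) -> str:
    return ":".join(f'C(Q("{f}"))' for f in term)


def _formula(response: str, terms: Sequence[tuple[str, ...]]) -> str:
    rhs = " + ".join(_term_patsy(t) for t in terms) if terms else "1"
    return f'Q("{response}") ~ ' + rhs


def _aliased_columns(exog: np.ndarray, names: Sequence[str]) -> list[str]:
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(exog)
    _, _, piv = qr(exog, mode="economic", pivoting=True)
    return [names[j] for j in sorted(piv[rank:])]


def fit_aov(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    interactions: Sequence[tuple[str, ...]] = (),
    on_aliased: str = "raise",
) -> AovResult:
    """Fit a fixed-effects linear model and its Type-II ANOVA table.

    Each term's sum of squares is the residual-SS drop when the term is
    added to the model containing every other term that does not contain
    it; F statistics use the full-model mean squared error.  On balanced
    designs this coincides with the sequential (Type-I) decomposition.

    Parameters
    ----------
    table
        Descriptor table (one row per census cell) holding the response and
        the factor columns.
    response
        Column to analyse, e.g. ``"r_i"`` or ``"cv_i"``.
    factors
        Main-effect factor columns; each needs at least two observed levels.
    interactions
        Tuples of factor names whose interactions enter the model.
    on_aliased
        ``"raise"`` (default) errors on a rank-deficient design, naming the
        aliased model columns; ``"drop"`` proceeds with the aliased
        contrasts removed (pseudoinverse fit, rank-based degrees of
        freedom), as R's ``lm`` does — appropriate when empty cells are
        structural, e.g. a site that does not flower in one period.

    Raises
    ------
    ValueError
        For factors with fewer than two levels, insufficient residual
        degrees of freedom, or (with ``on_aliased="raise"``) an aliased
        design.
    """
    data = table.dropna(subset=[response]).copy()
    for f in factors:
        n_levels = data[f].nunique()
        if n_levels < 2:
            raise ValueError(f"factor {f!r} has {n_levels} level(s); need >= 2")
    terms: list[tuple[str, ...]] = [(f,) for f in factors] + [
        tuple(i) for i in interactions
    ]
    formula = _formula(response, terms)
    model = smf.ols(formula, data=data)
    exog = np.asarray(model.exog)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        aliased = _aliased_columns(exog, list(model.exog_names))
        if on_aliased != "drop":
            raise ValueError(
                f"rank-deficient design for {formula!r}: aliased column(s) "
                f"{aliased} (empty factor-level combinations); refit without "
                "the aliased interaction(s) or pass on_aliased='drop'"
            )
        logger.warning("dropping aliased design column(s): %s", aliased)
    full = model.fit()
    if full.df_resid < 1:
        raise ValueError(
            f"no residual degrees of freedom (N={int(full.nobs)}, "
            f"model df={int(full.df_model)})"
        )
    mse = full.ssr / full.df_resid

    rows = []
    for term in terms:
        base = [
            other
            for other in terms
            if other != term and not set(term) <= set(other)
        ]
        reduced = smf.ols(_formula(response, base), data=data).fit()
        augmented = smf.ols(_formula(response, base + [term]), data=data).fit()
        ss = max(0.0, reduced.ssr - augmented.ssr)
        df = reduced.df_resid - augmented.df_resid
        if df < 1:
            logger.warning("term %s is fully aliased; no testable contrast", term)
            rows.append({"term": ":".join(term), "sum_sq": ss, "df": 0.0,
                         "F": math.nan, "p": math.nan})
            continue
        f_stat = (ss / df) / mse
        p = float(stats.f.sf(f_stat, df, full.df_resid))
        rows.append(
            {"term": ":".join(term), "sum_sq": ss, "df": df, "F": f_stat, "p": p}
        )
    rows.append(
        {
            "term": "Residual",
            "sum_sq": full.ssr,
            "df": full.df_resid,
            "F": math.nan,
            "p": math.nan,
        }
    )
    aov = pd.DataFrame(rows).set_index("term")
    return AovResult(
        table=aov,
        response=response,
        formula=formula,
        nobs=int(full.nobs),
        residuals=np.asarray(full.resid),
    )


def three_factor_screen(
    table: pd.DataFrame,
    response: str,
    site: str = "department",
    semester: str = "semester",
    accession: str = "accession",
    on_aliased: str = "raise",
) -> AovResult:
    """Screening model: three main effects and all two-way interactions.

    Used to decide whether accession (and its interactions) carries signal;
    the decision to drop accession and refit the two-factor model is left
    to the caller.
    """
    return fit_aov(
        table,
        response,
        [site, semester, accession],
        [(site, semester), (site, accession), (semester, accession)],
        on_aliased=on_aliased,
    )


def two_factor_aov(
    table: pd.DataFrame,
    response: str,
    site: str = "department",
    semester: str = "semester",
    on_aliased: str = "raise",
) -> AovResult:
    """The two-factor model: site + semester + site x semester, Type-II SS."""
    return fit_aov(
        table, response, [site, semester], [(site, semester)], on_aliased=on_aliased
    )


def simple_effects(
    table: pd.DataFrame,
    response: str,
    within: str = "semester",
    across: str = "department",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Simple effects of ``across`` within each level of ``within``.

    One-way ANOVA of the site effect inside each semester stratum, with the
    stratum p-values Bonferroni-adjusted over the number of strata tested.
    Intended for decomposing a significant interaction (the caller checks
    interaction significance first). Strata with fewer than two ``across``
    levels are skipped with a warning.
    """
    rows = []
    data = table.dropna(subset=[response])
    for stratum, sub in data.groupby(within, sort=True):
        if sub[across].nunique() < 2:
            logger.warning(
                "stratum %s=%r has < 2 %s levels; skipped", within, stratum, across
            )
            continue
        res = fit_aov(sub, response, [across])
        rows.append(
            {
                within: stratum,
                "df_num": res.table.loc[across, "df"],
                "df_den": res.table.loc["Residual", "df"],
                "F": res.f_value(across),
                "p_raw": res.p_value(across),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["m"] = len(out)
        out["p_adj"] = bonferroni(out["p_raw"].to_numpy(), len(out))
        out["significant"] = out["p_adj"] < alpha
    return out


def pairwise_bonferroni(
    table: pd.DataFrame,
    response: str,
    within: str = "semester",
    across: str = "department",
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> ComparisonSet:
    """All pairwise ``across`` comparisons organised by ``within`` stratum.

    Two-sample t tests (pooled variance by default, the classical
    post-ANOVA form; Welch with ``equal_var=False``), Bonferroni-adjusted
    over the whole family of performed comparisons (pairs x strata).
    Groups with fewer than two observations are skipped with a warning.
    """
    rows = []
    data = table.dropna(subset=[response])
    for stratum, sub in data.groupby(within, sort=True):
        groups = {
            level: g[response].to_numpy() for level, g in sub.groupby(across, sort=True)
        }
        for a, b in combinations(sorted(groups), 2):
            xa, xb = groups[a], groups[b]
            if len(xa) < 2 or len(xb) < 2:
                logger.warning(
                    "comparison %r vs %r in %s=%r skipped: group with < 2 obs",
                    a,
                    b,
                    within,
                    stratum,
                )
                continue
            t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
            rows.append(
                {
                    within: stratum,
                    "group_a": a,
                    "group_b": b,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "mean_a": xa.mean(),
                    "mean_b": xb.mean(),
                    "t": float(t),
                    "p_raw": float(p),
                }
            )
    frame = pd.DataFrame(rows)
    m = len(frame)
    if m:
        frame["p_adj"] = bonferroni(frame["p_raw"].to_numpy(), m)
        frame["significant"] = frame["p_adj"] < alpha
    return ComparisonSet(frame=frame, m=m, alpha=alpha, response=response)


def check_assumptions(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    alpha: float = ASSUMPTION_ALPHA,
) -> AssumptionReport:
    """Shapiro-Wilk on full-model residuals, Levene across factor cells.

    Residuals come from the saturated cell-means fit of the crossed
    ``factors``; Levene uses the median-centred form (robust to
    non-normality, as in R's ``car::leveneTest``).  A degenerate (constant)
    response yields NaN p-values with a warning rather than an error: the
    report annotates the analysis, it never blocks it.
    """
    data = table.dropna(subset=[response])
    y = data[response].to_numpy(dtype=float)
    cells = data.groupby(list(factors), sort=True)[response]
    residuals = y - cells.transform("mean").to_numpy(dtype=float)
    groups = [g.to_numpy(dtype=float) for _, g in cells if len(g) >= 2]
    if len(residuals) < 3 or len(groups) < 2:
        raise ValueError("need >= 3 residuals and >= 2 groups of size >= 2")
    if np.ptp(y) == 0:
        logger.warning("constant response %r: assumption tests undefined", response)
        return AssumptionReport(math.nan, math.nan, alpha, len(groups))
    shapiro_p = float(stats.shapiro(residuals).pvalue)
    levene_p = float(stats.levene(*groups, center="median").pvalue)
    return AssumptionReport(shapiro_p, levene_p, alpha, len(groups))


def event_summary(
    table: pd.DataFrame,
    site: str = "department",
    semester: str = "semester",
    accession: str = "accession",
) -> Mapping[str, pd.Series | float]:
    """Descriptive medians of the event descriptor.

    The event count is a bounded discrete descriptor and is summarised by
    medians (per site x semester cell, per accession, and overall) rather
    than modelled.
    """
    if table.empty:
        raise ValueError("empty descriptor table")
    return {
        "by_site_semester": table.groupby([site, semester], sort=True)["event"].median(),
        "by_accession": table.groupby(accession, sort=True)["event"].median(),
        "overall": float(table["event"].median()),
    }
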