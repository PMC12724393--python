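"""Statistical models for mtDNA aging analyses.

The toolkit mirrors what the analyses need and nothing more:

* ordinary least squares with covariates (age models of copy number and
  SNV counts);
* exponential ("log-linear") regression, i.e. OLS on ``ln(metric + 0.01)``,
  used for deletion metrics whose burden grows multiplicatively with age;
* 15-year age-bin changes evaluated from a fitted model;
* rank-based regression with Wilcoxon scores (Jaeckel dispersion), the
  non-parametric estimator used for between-group comparisons, with Wald
  tests based on the tau scale parameter;
* Kruskal-Wallis with Dunn's post hoc z tests (Bonferroni adjusted);
* Pearson's chi-squared with Yates' continuity correction for 2x2 tables;
* the Bonferroni threshold helper.

Percent-type responses are kept on the percent scale (0-100) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

ModelKind = Literal["ols", "log_linear", "rank_based"]

DEFAULT_PSEUDO_COUNT = 0.01


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    p_values: Mapping[str, float]
    model_kind: ModelKind
    n: int
    pseudo_count: float | None = None
    term_means: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "n": self.n,
            "pseudo_count": self.pseudo_count,
            "coefficients": dict(self.coefficients),
            "standard_errors": dict(self.standard_errors),
            "p_values": dict(self.p_values),
        }


def _design(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    X = data[list(terms)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise StatsError("missing values in design terms")
    return X


def ols_fit(
    data: pd.DataFrame, response: str, terms: Sequence[str]
) -> RegressionResult:
    """OLS of ``response`` on ``terms`` plus an intercept, with two-sided
    t-test p-values per coefficient."""
    y = data[response].to_numpy(dtype=float)
    X = _design(data, terms)
    n, p = X.shape
    if n <= p + 1:
        raise StatsError(f"n={n} too small for {p} terms")
    constant = [t for t, col in zip(terms, X.T) if np.ptp(col) == 0]
    if constant:
        raise StatsError(f"constant design column(s) besides intercept: {constant}")
    Xc = sm.add_constant(X, has_constant="raise")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise StatsError("rank-deficient design (collinear terms?)")
    fit = sm.OLS(y, Xc).fit()
    names = ["intercept", *terms]
    if np.ptp(y) == 0.0:
        # constant response: slopes are exactly 0 and carry no evidence
        # against the null; the 0/0 t-statistics are meaningless
        pvals = [float("nan"), *[1.0] * len(terms)]
    else:
        pvals = [
            (1.0 if np.isclose(b, 0.0) else 0.0) if (se == 0 or np.isnan(pv))
            else float(pv)
            for b, se, pv in zip(fit.params, fit.bse, fit.pvalues)
        ]
    return RegressionResult(
        coefficients=dict(zip(names, fit.params)),
        standard_errors=dict(zip(names, fit.bse)),
        p_values=dict(zip(names, pvals)),
        model_kind="ols",
        n=n,
        term_means={t: float(np.mean(data[t])) for t in terms},
    )


def exp_regression(
    data: pd.DataFrame,
    metric: str,
    age: str,
    covariates: Sequence[str] = (),
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
) -> RegressionResult:
    """Exponential age regression: OLS on ``ln(metric + pseudo_count)``.

    The pseudo-count makes zero burdens representable; the default 0.01 is
    far below any observable deletion read percent.
    """
    vals = data[metric].to_numpy(dtype=float)
    if (vals < 0).any():
        raise StatsError(f"{metric} has negative values; log model undefined")
    if pseudo_count <= 0:
        raise StatsError("pseudo_count must be > 0")
    work = data.copy()
    work["_ln_metric"] = np.log(vals + pseudo_count)
    base = ols_fit(work, "_ln_metric", [age, *covariates])
    return RegressionResult(
        coefficients=base.coefficients,
        standard_errors=base.standard_errors,
        p_values=base.p_values,
        model_kind="log_linear",
        n=base.n,
        pseudo_count=pseudo_count,
        term_means=base.term_means,
    )


def bin_delta(
    result: RegressionResult,
    age_start: float,
    width: float = 15.0,
    age_term: str = "age",
    covariate_profile: Mapping[str, float] | None = None,
) -> float:
    """Change of the modelled metric across an age bin [age_start,
    age_start + width].

    For an OLS fit this is slope x width.  For a log-linear fit the linear
    predictor is evaluated at both bin edges (covariates fixed at
    ``covariate_profile``, defaulting to their sample means) and the metric
    change is the difference of the back-transformed values.
    """
    if result.model_kind == "ols":
        return result.coefficients[age_term] * width
    if result.model_kind != "log_linear":
        raise StatsError("bin_delta requires an ols or log_linear result")
    profile = dict(result.term_means)
    if covariate_profile:
        profile.update(covariate_profile)
    missing = [t for t in result.coefficients
               if t not in ("intercept", age_term) and t not in profile]
    if missing:
        raise StatsError(f"no covariate values for {missing}")

    def eta(a: float) -> float:
        total = result.coefficients["intercept"]
        total += result.coefficients[age_term] * a
        for term, beta in result.coefficients.items():
            if term in ("intercept", age_term):
                continue
            total += beta * profile[term]
        return total

    pseudo = result.pseudo_count or 0.0
    return (np.exp(eta(age_start + width)) - pseudo) - (np.exp(eta(age_start)) - pseudo)


# ---------------------------------------------------------------------------
# rank-based (Wilcoxon-score) regression
# ---------------------------------------------------------------------------

def _wilcoxon_dispersion(e: np.ndarray) -> float:
    n = e.size
    ranks = stats.rankdata(e)
    scores = np.sqrt(12.0) * (ranks / (n + 1) - 0.5)
    return float(np.sum(scores * e))


def _tau_wilcoxon(residuals: np.ndarray, p: int) -> float:
    """Scale parameter tau = [sqrt(12) * integral f^2]^-1 for Wald tests.

    The density overlap integral f^2 is estimated with a window (kernel)
    estimator on the fitted residuals, with a degrees-of-freedom correction;
    this is the standard consistent window approach and the main source of
    small p-value differences between rank-regression implementations.
    """
    n = residuals.size
    kde = stats.gaussian_kde(residuals)
    int_f_sq = float(np.mean(kde(residuals)))
    tau = 1.0 / (np.sqrt(12.0) * int_f_sq)
    return tau * np.sqrt(n / max(n - p - 1, 1))


def rank_fit(
    data: pd.DataFrame, response: str, terms: Sequence[str]
) -> RegressionResult:
    """Rank-based linear regression with Wilcoxon scores.

    Slopes minimise Jaeckel's dispersion ``sum a(R(e_i)) e_i`` with
    ``a(i) = sqrt(12) (i/(n+1) - 1/2)``; the intercept is the median of the
    residuals.  Wald p-values use the tau scale estimate.  With a single
    binary predictor the slope equals the Hodges-Lehmann two-sample shift
    estimator.
    """
    y = data[response].to_numpy(dtype=float)
    X = _design(data, terms)
    n, p = X.shape
    if n < 10:
        raise StatsError("rank_fit requires n >= 10")
    if p < 1:
        raise StatsError("rank_fit requires at least one non-intercept term")
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < p:
        raise StatsError("rank-deficient design (collinear terms?)")

    beta0, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), X]), y, rcond=None)
    start = beta0[1:]

    def objective(b: np.ndarray) -> float:
        return _wilcoxon_dispersion(y - X @ np.atleast_1d(b))

    # The objective is convex and piecewise linear; a derivative-free Powell
    # search from the OLS solution converges reliably.
    res = optimize.minimize(objective, start, method="Powell",
                            options={"xtol": 1e-10, "ftol": 1e-12,
                                     "maxiter": 10_000})
    if not res.success and res.fun > objective(start) + 1e-8:
        raise StatsError(f"dispersion minimisation failed: {res.message}")
    beta = np.atleast_1d(res.x)
    residuals = y - X @ beta
    intercept = float(np.median(residuals))
    residuals_centred = residuals - intercept

    tau = _tau_wilcoxon(residuals_centred, p)
    XtX_inv = np.linalg.inv(Xc.T @ Xc)
    ses = tau * np.sqrt(np.diag(XtX_inv))
    tvals = beta / ses
    df = max(n - p - 1, 1)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    # intercept inference via the sign-score scale tau_s = 1 / (2 f(0))
    f0 = float(stats.gaussian_kde(residuals_centred)(0.0)[0])
    tau_s = 1.0 / max(2.0 * f0, 1e-12)
    se_int = tau_s / np.sqrt(n)
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), df)

    names = ["intercept", *terms]
    return RegressionResult(
        coefficients=dict(zip(names, [intercept, *beta])),
        standard_errors=dict(zip(names, [se_int, *ses])),
        p_values=dict(zip(names, [p_int, *pvals])),
        model_kind="rank_based",
        n=n,
        term_means={t: float(np.mean(data[t])) for t in terms},
    )


def hodges_lehmann_shift(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Median of all pairwise differences b - a (two-sample HL estimator)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    return float(np.median(np.subtract.outer(b, a)))


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    H_statistic: float
    H_p_value: float
    pairwise: tuple[tuple[str, str, float, float, float], ...]
    adjustment: str = "bonferroni"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairwise,
            columns=["group_i", "group_j", "z", "raw_p", "adjusted_p"],
        )


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis H (tie corrected) plus Dunn's pairwise post hoc tests
    with Bonferroni adjustment."""
    names = list(groups)
    if len(names) < 2:
        raise StatsError("need at least two groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size == 0 for a in arrays):
        raise StatsError("empty group")
    pooled = np.concatenate(arrays)
    N = pooled.size
    if np.all(pooled == pooled[0]):
        pairs = tuple(
            (names[i], names[j], 0.0, 1.0, 1.0)
            for i, j in combinations(range(len(names)), 2)
        )
        return GroupComparison(0.0, 1.0, pairs)

    H, H_p = stats.kruskal(*arrays)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    offset = 0
    for a in arrays:
        mean_ranks.append(ranks[offset : offset + a.size].mean())
        offset += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    pairs = []
    for i, j in combinations(range(len(names)), 2):
        denom = np.sqrt(base_var * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / denom
        raw = 2.0 * stats.norm.sf(abs(z))
        pairs.append((names[i], names[j], float(z), float(raw),
                      float(min(1.0, raw * m))))
    return GroupComparison(float(H), float(H_p), tuple(pairs))


def chisq_yates(table_2x2: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson's chi-squared with Yates' continuity correction on a 2x2 table
    (the correction is capped so it never overshoots zero)."""
    t = np.asarray(table_2x2, dtype=float)
    if t.shape != (2, 2):
        raise StatsError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise StatsError("table entries must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("zero margin in contingency table")
    res = stats.chi2_contingency(t, correction=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0 < alpha <= 1:
        raise StatsError("alpha must be in (0, 1]")
    if m < 1:
        raise StatsError("m must be >= 1")
    return alpha / m
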