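"""Age-regression models, F-test against a constant model, one-way ANOVA
with Tukey-Kramer post hoc comparisons, and reporting conventions.

Two regression models relate a morphometric response y to postmenstrual
age (months):

    linear:      y(age) = a + b * age
    logarithmic: y(age) = a + b * log(age)

Both are ordinary least squares; the logarithmic model is the linear
model on log(age) (natural log by default). A model is significantly
different from the constant model y = mean(y) when the F statistic with
(1, n-2) degrees of freedom yields P < 0.05. R^2 = 1 - SSE/SST measures
goodness of fit.

Reporting convention: P > 0.05 is printed as "P>0.05", P < 0.001 as
"P<0.001", otherwise "P = x.xxx" with three decimals.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "GroupComparison",
    "Summary",
    "fit_model",
    "f_test_vs_constant",
    "anova_tukey",
    "format_p",
    "summarize",
]

_SST_FLOOR = 1e-12


@dataclass
class RegressionResult:
    model_kind: str  # "linear" | "log"
    a: float
    b: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int
    residual_sd: float
    b_se: float
    log_base: float | None = None
    perfect_fit: bool = False

    def b_confint(self, level: float = 0.95) -> tuple[float, float]:
        """Analytic t-based confidence interval for the rate b."""
        t_crit = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        return self.b - t_crit * self.b_se, self.b + t_crit * self.b_se


@dataclass
class GroupComparison:
    labels: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    anova_f: float
    anova_p: float
    pairwise_p: dict[tuple[str, str], float]

    def p(self, g1: str, g2: str) -> float:
        key = tuple(sorted((g1, g2)))
        return self.pairwise_p[key]


@dataclass
class Summary:
    n: int
    mean: float
    sd: float | None  # absent (None) for a single value, never 0
    min: float
    max: float


def fit_model(
    ages_months: Sequence[float],
    values: Sequence[float],
    model_kind: str = "log",
    log_base: float = math.e,
) -> RegressionResult:
    """Least-squares fit of y = a + b*age or y = a + b*log(age).

    Switching ``log_base`` rescales b (and shifts nothing else): R^2, F
    and P are invariant because the regressor changes by a constant
    factor. Degenerate designs (n < 3, constant ages, nonpositive ages
    under the log model) raise ``ValueError``. A constant response has
    SST = 0; by convention it yields b = 0, R^2 = 0, F = 0, P = 1.
    """
    ages = np.asarray(ages_months, dtype=float)
    y = np.asarray(values, dtype=float)
    if ages.shape != y.shape or ages.ndim != 1:
        raise ValueError("ages and values must be 1-D of equal length")
    n = ages.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if model_kind == "linear":
        x = ages
    elif model_kind == "log":
        if np.any(ages <= 0):
            raise ValueError("log model requires strictly positive ages")
        x = np.log(ages) / math.log(log_base)
    else:
        raise ValueError(f"model_kind must be 'linear' or 'log', got {model_kind!r}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all ages equal")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    a, b = float(res.params[0]), float(res.params[1])
    sse = float(res.ssr)
    sst = float(res.centered_tss)

    if sst <= _SST_FLOOR * max(1.0, float(np.mean(y * y))):
        # constant response: the constant model is already exact
        return RegressionResult(
            model_kind=model_kind, a=float(np.mean(y)), b=0.0, r_squared=0.0,
            f_stat=0.0, p_value=1.0, n=n, residual_sd=0.0, b_se=0.0,
            log_base=log_base if model_kind == "log" else None,
        )

    perfect = sse <= _SST_FLOOR * sst
    if perfect:
        r2, f, p = 1.0, math.inf, sys.float_info.min
        residual_sd = 0.0
    else:
        r2 = 1.0 - sse / sst
        f = ((sst - sse) / 1.0) / (sse / (n - 2))
        p = float(sps.f.sf(f, 1, n - 2))
        residual_sd = math.sqrt(sse / (n - 2))
    return RegressionResult(
        model_kind=model_kind,
        a=a,
        b=b,
        r_squared=r2,
        f_stat=f,
        p_value=p,
        n=n,
        residual_sd=residual_sd,
        b_se=float(res.bse[1]),
        log_base=log_base if model_kind == "log" else None,
        perfect_fit=perfect,
    )


def f_test_vs_constant(result: RegressionResult) -> float:
    """P-value of the fitted model against the constant model.

    F = ((SST - SSE)/1) / (SSE/(n-2)) with P from F(1, n-2); for a
    perfect fit (SSE = 0) P is reported at the machine floor with
    ``result.perfect_fit`` set.
    """
    return result.p_value


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA with Tukey-Kramer post hoc pairwise comparisons.

    The Kramer adjustment supports unequal group sizes: for groups i, j

        q_ij = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))

    with adjusted P from the studentized range distribution with k
    groups and N - k degrees of freedom (scipy's numerical quadrature,
    absolute tolerance ~1e-10).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    labels = list(arrays)
    k = len(labels)
    N = sum(v.size for v in arrays.values())
    dof = N - k
    f, p = sps.f_oneway(*arrays.values())
    mse = sum(((v - v.mean()) ** 2).sum() for v in arrays.values()) / dof

    pairwise: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = labels[i], labels[j]
            vi, vj = arrays[gi], arrays[gj]
            se = math.sqrt(mse / 2.0 * (1.0 / vi.size + 1.0 / vj.size))
            if se == 0:
                padj = 1.0 if vi.mean() == vj.mean() else sys.float_info.min
            else:
                q = abs(vi.mean() - vj.mean()) / se
                padj = float(np.clip(sps.studentized_range.sf(q, k, dof), 0.0, 1.0))
            # adjusted P lives in (0, 1]: report underflow at the machine floor
            pairwise[tuple(sorted((gi, gj)))] = max(padj, sys.float_info.min)
    return GroupComparison(
        labels=labels,
        means={g: float(v.mean()) for g, v in arrays.items()},
        sds={g: float(v.std(ddof=1)) for g, v in arrays.items()},
        ns={g: int(v.size) for g, v in arrays.items()},
        anova_f=float(f),
        anova_p=max(float(p), sys.float_info.min),
        pairwise_p=pairwise,
    )


def format_p(p: float) -> str:
    """Render a P-value under the reporting convention."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if p > 0.05:
        return "P>0.05"
    if p < 0.001:
        return "P<0.001"
    return f"P = {p:.3f}"


def summarize(values: Sequence[float]) -> Summary:
    """Mean, sample SD (n-1 denominator), min and max.

    For a single value the SD is reported absent (None), not 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    return Summary(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else None,
        min=float(v.min()),
        max=float(v.max()),
    )
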