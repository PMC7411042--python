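"""Survival and fecundity statistics implemented from their formulas.

Contents:

* Kaplan-Meier product-limit survival curves,
* the two-group log-rank test (pooled-tie hypergeometric moments) and
  its Bonferroni-corrected pairwise form,
* the Kruskal-Wallis rank ANOVA with tie correction,
* pairwise Wilcoxon rank-sum (Mann-Whitney) tests — exact null
  distribution when both groups have n <= 8 and there are no ties,
  otherwise the tie-corrected normal approximation with continuity
  correction — with Bonferroni adjustment,
* generalized linear models (gaussian/identity, poisson/log) fitted by
  iteratively reweighted least squares, and minimum-AIC selection over a
  candidate lattice of species/temperature effects.

All tests are two-sided.  p-values are floored at the smallest positive
float rather than reported as zero.  Established library routines
(lifelines, scipy.stats, statsmodels) are deliberately not called here;
they serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata

__all__ = [
    "KMCurve",
    "TestResult",
    "GLMResults",
    "GLM",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "pairwise_wilcoxon",
    "glm_fit",
    "select_model_aic",
    "candidate_models",
    "StatsError",
]

_P_FLOOR = float(np.finfo(float).tiny)


class StatsError(ValueError):
    pass


def _clip_p(p: float) -> float:
    return float(min(max(p, _P_FLOOR), 1.0))


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate.

    ``survival[i]`` is S(t) just after ``event_times[i]``; the curve is 1
    before the first event time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): probability of surviving beyond time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(durations: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier estimator from (duration, event) pairs.

    ``events`` marks deaths (True) versus right-censoring (False).  At
    each distinct death time t_i with d_i deaths among n_i at risk, the
    survival multiplies by (1 - d_i / n_i).
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise StatsError("empty survival data")
    if t.size != e.size:
        raise StatsError("durations and events differ in length")
    if np.any(t <= 0):
        raise StatsError("durations must be positive")

    death_times = np.unique(t[e])
    surv = []
    at_risk = []
    n_events = []
    s = 1.0
    for ti in death_times:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & e))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        n_events.append(d_i)
    return KMCurve(
        event_times=death_times,
        survival=np.asarray(surv),
        n_at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_events, dtype=int),
    )


# ---------------------------------------------------------------------------
# test result container

@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class despite the name

    statistic: float
    df: int
    p_raw: float
    method: str
    p_adjusted: float | None = None
    group_a: str | None = None
    group_b: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0:
            raise StatsError("p_raw outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-15:
            raise StatsError("adjusted p below raw p")


def _bonferroni(results: list[TestResult]) -> list[TestResult]:
    m = len(results)
    return [
        TestResult(
            statistic=res.statistic, df=res.df, p_raw=res.p_raw,
            method=res.method, p_adjusted=min(1.0, m * res.p_raw),
            group_a=res.group_a, group_b=res.group_b,
        )
        for res in results
    ]


# ---------------------------------------------------------------------------
# log-rank

def logrank_test(
    durations_a: Sequence[float],
    events_a: Sequence[bool],
    durations_b: Sequence[float],
    events_b: Sequence[bool],
) -> TestResult:
    """Two-group log-rank test with pooled-tie hypergeometric moments.

    At each distinct death time the observed deaths in group A are
    compared with the hypergeometric expectation given the pooled risk
    set; the statistic is (sum(O - E))^2 / sum(V) on 1 df.
    """
    ta = np.asarray(durations_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(durations_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise StatsError("both groups must be non-empty")

    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    death_times = np.unique(t_all[e_all])
    if death_times.size == 0:
        raise StatsError("no events in either group: log-rank undefined")

    o_minus_e = 0.0
    var = 0.0
    for ti in death_times:
        n1 = int(np.sum(ta >= ti))
        n2 = int(np.sum(tb >= ti))
        n = n1 + n2
        d = int(np.sum((t_all == ti) & e_all))
        d1 = int(np.sum((ta == ti) & ea))
        if n <= 1:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        o_minus_e += d1 - e1
        var += v
    if var <= 0.0:
        # all deaths occur where one group has the entire risk set
        return TestResult(statistic=0.0, df=1, p_raw=1.0, method="logrank")
    stat = o_minus_e**2 / var
    p = _clip_p(float(chi2_dist.sf(stat, 1)))
    return TestResult(statistic=float(stat), df=1, p_raw=p, method="logrank")


def pairwise_logrank(
    groups: dict[str, tuple[Sequence[float], Sequence[bool]]],
    correction: str = "bonferroni",
) -> list[TestResult]:
    """All unordered pairwise log-rank tests with Bonferroni adjustment."""
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    results = []
    for (ka, a), (kb, b) in itertools.combinations(sorted(groups.items()), 2):
        res = logrank_test(a[0], a[1], b[0], b[1])
        results.append(
            TestResult(statistic=res.statistic, df=res.df, p_raw=res.p_raw,
                       method=res.method, group_a=ka, group_b=kb)
        )
    if correction == "bonferroni":
        return _bonferroni(results)
    if correction in (None, "none"):
        return results
    raise StatsError(f"unknown correction {correction!r}")


# ---------------------------------------------------------------------------
# Kruskal-Wallis

def _tie_term(values: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: dict[str, Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank one-way ANOVA with average ranks and tie
    correction; H is referred to chi-square on k-1 df."""
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    keys = sorted(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    if any(a.size == 0 for a in arrays):
        raise StatsError("empty group")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r_sum = float(np.sum(ranks[start:start + a.size]))
        h += r_sum**2 / a.size
        start += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0.0:
        # every observation identical
        return TestResult(statistic=0.0, df=len(keys) - 1, p_raw=1.0,
                          method="kruskal-wallis")
    h /= correction
    h = max(h, 0.0)
    df = len(keys) - 1
    p = 1.0 if h == 0.0 else _clip_p(float(chi2_dist.sf(h, df)))
    return TestResult(statistic=float(h), df=df, p_raw=p,
                      method="kruskal-wallis")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)

def _exact_rank_sum_counts(n1: int, n_total: int) -> np.ndarray:
    """Distribution of the rank sum of a group of size n1 among ranks
    1..n_total under the null, by dynamic programming.

    Returns counts[s] = number of size-n1 subsets of {1..n_total} with
    rank sum s (index 0..max_sum).
    """
    max_sum = n1 * n_total
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for value in range(1, n_total + 1):
        for k in range(min(value, n1), 0, -1):
            counts[k, value:] += counts[k - 1, :-value or None]
    return counts[n1]


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 8
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    The exact null distribution is enumerated when both groups have at
    most ``exact_max_n`` observations and the pooled sample has no ties;
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction is used.  The reported statistic is U of the
    first group.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise StatsError("empty group")
    n1, n2 = xa.size, xb.size
    pooled = np.concatenate([xa, xb])
    ranks = rankdata(pooled)
    r1 = float(np.sum(ranks[:n1]))
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size

    if n1 <= exact_max_n and n2 <= exact_max_n and not has_ties:
        n_total = n1 + n2
        counts = _exact_rank_sum_counts(n1, n_total)
        total = counts.sum()
        offset = n1 * (n1 + 1) // 2  # rank sum -> U shift
        u_probs = counts[offset:] / total  # index = U value
        u_int = int(round(u1))
        p_le = float(np.sum(u_probs[: u_int + 1]))
        p_ge = float(np.sum(u_probs[u_int:]))
        p = _clip_p(2.0 * min(p_le, p_ge))
        return TestResult(statistic=float(u1), df=0, p_raw=p,
                          method="wilcoxon-exact")

    mu = n1 * n2 / 2.0
    n_total = n1 + n2
    sigma2 = (n1 * n2 / 12.0) * (
        (n_total + 1) - _tie_term(pooled) / (n_total * (n_total - 1))
    )
    if sigma2 <= 0.0:
        return TestResult(statistic=float(u1), df=0, p_raw=1.0,
                          method="wilcoxon-normal")
    diff = u1 - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2)
    p = _clip_p(2.0 * float(norm_dist.sf(abs(z))))
    return TestResult(statistic=float(u1), df=0, p_raw=p,
                      method="wilcoxon-normal")


def pairwise_wilcoxon(
    groups: dict[str, Sequence[float]],
    correction: str = "bonferroni",
) -> list[TestResult]:
    """All unordered pairwise rank-sum tests with Bonferroni adjustment."""
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    results = []
    for (ka, a), (kb, b) in itertools.combinations(sorted(groups.items()), 2):
        res = wilcoxon_rank_sum(a, b)
        results.append(
            TestResult(statistic=res.statistic, df=res.df, p_raw=res.p_raw,
                       method=res.method, group_a=ka, group_b=kb)
        )
    if correction == "bonferroni":
        return _bonferroni(results)
    if correction in (None, "none"):
        return results
    raise StatsError(f"unknown correction {correction!r}")


# ---------------------------------------------------------------------------
# GLM by IRLS

@dataclass(frozen=True)
class GLMResults:
    """A fitted generalized linear model.

    ``aic = 2k - 2*log_likelihood`` with ``k`` the number of estimated
    parameters (coefficients, plus the dispersion for the gaussian
    family, matching the usual likelihood-based convention).
    """

    family: str
    params: pd.Series
    log_likelihood: float
    deviance: float
    aic: float
    converged: bool
    n_obs: int
    n_iter: int
    name: str = ""

    @property
    def k_params(self) -> int:
        return len(self.params) + (1 if self.family == "gaussian" else 0)

    def summary(self) -> str:
        lines = [
            f"GLM ({self.family})" + (f" — {self.name}" if self.name else ""),
            "=" * 46,
        ]
        for term, beta in self.params.items():
            lines.append(f"{term:<30}{beta:>16.6f}")
        lines += [
            "-" * 46,
            f"{'log-likelihood':<30}{self.log_likelihood:>16.4f}",
            f"{'deviance':<30}{self.deviance:>16.4f}",
            f"{'AIC':<30}{self.aic:>16.4f}",
        ]
        return "\n".join(lines)


def glm_fit(
    exog: np.ndarray | pd.DataFrame,
    endog: np.ndarray | pd.Series,
    family: str = "gaussian",
    names: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    model_name: str = "",
) -> GLMResults:
    """Fit a GLM by iteratively reweighted least squares.

    Families: ``gaussian`` (identity link; equivalent to OLS) and
    ``poisson`` (log link).  The design must be full rank.
    """
    x = np.asarray(exog, dtype=float)
    y = np.asarray(endog, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if y.shape[0] != n:
        raise StatsError("design and response lengths differ")
    if np.linalg.matrix_rank(x) < p:
        raise StatsError("rank-deficient design matrix")
    if names is None:
        if isinstance(exog, pd.DataFrame):
            names = list(exog.columns)
        else:
            names = [f"x{i}" for i in range(p)]

    if family == "gaussian":
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        mu = x @ beta
        rss = float(np.sum((y - mu) ** 2))
        sigma2 = max(rss / n, 1e-300)
        llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        dev = rss
        aic = 2.0 * (p + 1) - 2.0 * llf
        return GLMResults(family="gaussian", params=pd.Series(beta, index=list(names)),
                          log_likelihood=llf, deviance=dev, aic=aic,
                          converged=True, n_obs=n, n_iter=1, name=model_name)

    if family != "poisson":
        raise StatsError(f"unsupported family {family!r}")
    if np.any(y < 0):
        raise StatsError("poisson responses must be non-negative")

    # IRLS with log link: W = mu, working response z = eta + (y - mu)/mu
    beta = np.zeros(p)
    eta = np.log(np.clip(y, 0.1, None).mean()) * np.ones(n)
    dev_old = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.exp(np.clip(eta, -700, 700))
        w = np.clip(mu, 1e-10, None)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(x * sw[:, None], z * sw, rcond=None)
        eta = x @ beta
        mu = np.exp(np.clip(eta, -700, 700))
        with np.errstate(divide="ignore", invalid="ignore"):
            y_log = np.where(y > 0, y * np.log(y / mu), 0.0)
        dev = 2.0 * float(np.sum(y_log - (y - mu)))
        if abs(dev - dev_old) < tol * (abs(dev) + tol):
            converged = True
            break
        dev_old = dev
    if not converged:
        raise StatsError(f"IRLS failed to converge in {max_iter} iterations")
    llf = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    aic = 2.0 * p - 2.0 * llf
    return GLMResults(family="poisson", params=pd.Series(beta, index=list(names)),
                      log_likelihood=llf, deviance=dev, aic=aic,
                      converged=converged, n_obs=n, n_iter=it, name=model_name)


class GLM:
    """Thin model wrapper around :func:`glm_fit` (statsmodels-style)."""

    def __init__(self, endog, exog, family: str = "gaussian",
                 names: Sequence[str] | None = None, name: str = ""):
        self.endog = endog
        self.exog = exog
        self.family = family
        self.names = names
        self.name = name

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> GLMResults:
        return glm_fit(self.exog, self.endog, family=self.family,
                       names=self.names, tol=tol, max_iter=max_iter,
                       model_name=self.name)


def candidate_models(
    frame: pd.DataFrame,
    response: str,
    family: str = "gaussian",
    species_col: str = "species",
    temperature_col: str = "temperature_C",
) -> list[GLM]:
    """The nested candidate lattice for species/temperature effects.

    Models: temperature; species; temperature + species;
    temperature + species + interaction.  Temperature enters as a
    numeric covariate; species as treatment-coded dummies.
    """
    temp = frame[temperature_col].to_numpy(dtype=float)
    levels = sorted(frame[species_col].unique())
    dummies = {
        f"species[{lev}]": (frame[species_col] == lev).to_numpy(dtype=float)
        for lev in levels[1:]
    }
    y = frame[response]
    n = len(frame)
    icept = np.ones(n)

    def design(cols: dict[str, np.ndarray], name: str) -> GLM:
        mat = np.column_stack([icept] + list(cols.values()))
        return GLM(y, mat, family=family,
                   names=["intercept"] + list(cols.keys()), name=name)

    inter = {
        f"temp:{key}": temp * val for key, val in dummies.items()
    }
    return [
        design({"temperature": temp}, "temperature"),
        design(dict(dummies), "species"),
        design({"temperature": temp, **dummies}, "temperature+species"),
        design({"temperature": temp, **dummies, **inter},
               "temperature+species+interaction"),
    ]


def select_model_aic(fits: Sequence[GLMResults]) -> GLMResults:
    """Return the minimum-AIC fit; exact ties go to the smaller model."""
    fits = list(fits)
    if not fits:
        raise StatsError("empty candidate list")
    best = fits[0]
    for fit in fits[1:]:
        if fit.aic < best.aic - 1e-9:
            best = fit
        elif abs(fit.aic - best.aic) <= 1e-9 and fit.k_params < best.k_params:
            best = fit
    return best
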