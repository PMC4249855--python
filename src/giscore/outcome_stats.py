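"""Survival and association statistics for the outcome analyses.

The estimators here are the ones the cohort reports are built from:
Kaplan-Meier curves with Greenwood / log-log 95% bands and 5-year rates,
the log-rank test (asymptotic chi-square, with an exact permutation option
for very small groups), Cox proportional-hazards regression (Efron or
Breslow ties), the Wilcoxon rank-sum test (exact enumeration for small
samples, tie-corrected normal approximation otherwise), Fisher's exact
test for 2x2 tables, and the equal-interval response-trend summary used to
relate the instability score to complete-response and platinum-sensitivity
rates.

All tests are two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger("giscore")

FIVE_YEARS_DAYS = 5 * 365.25  # 1826.25


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed to converge."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMEstimate:
    """Product-limit estimate with pointwise 95% confidence bands."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    median_days: float

    def rate_at(self, t_days: float) -> tuple[float, float, float]:
        """Survival probability (and CI) at time t, reading the step function."""
        idx = np.searchsorted(self.event_times, t_days, side="right") - 1
        if idx < 0:
            return 1.0, 1.0, 1.0
        return (float(self.survival[idx]), float(self.ci_low[idx]),
                float(self.ci_high[idx]))

    def five_year_rate(self) -> tuple[float, float, float]:
        return self.rate_at(FIVE_YEARS_DAYS)


def km_fit(times, events, alpha: float = 0.05) -> KMEstimate:
    """Kaplan-Meier fit.

    Confidence bands use the log-log (exponential Greenwood)
    transformation.  With no events the survival function is identically 1
    (CI undefined, reported as [1, 1]).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no subjects")
    if np.any(times < 0):
        raise ValueError("negative survival times")

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    tbl = kmf.event_table
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    lo = np.nan_to_num(ci.iloc[:, 0].to_numpy(dtype=float), nan=1.0) \
        if not events.any() else ci.iloc[:, 0].to_numpy(dtype=float)
    hi = np.nan_to_num(ci.iloc[:, 1].to_numpy(dtype=float), nan=1.0) \
        if not events.any() else ci.iloc[:, 1].to_numpy(dtype=float)
    at_risk = tbl["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    med = kmf.median_survival_time_
    return KMEstimate(grid, surv, at_risk, lo, hi, float(med))


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


def _two_group_logrank_chi2(times, events, in_group1) -> float:
    """O−E chi-square for two groups (hypergeometric variance)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    in_group1 = np.asarray(in_group1, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & in_group1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return float(o_minus_e**2 / var)


def logrank_test(groups, method: str = "asymptotic",
                 max_permutation_n: int = 14) -> LogRankResult:
    """Two-sided log-rank test across >= 2 groups of (times, events).

    ``method='asymptotic'`` uses the chi-square reference with
    df = groups − 1.  ``method='permutation'`` (two groups, combined
    n <= ``max_permutation_n``) enumerates every relabelling of subjects
    into groups of the observed sizes and reports the fraction whose
    chi-square statistic is at least the observed one.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = [len(np.asarray(t)) for t, _ in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("a group has zero subjects")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, dtype=bool) for _, e in groups])
    labels = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
    if not events.any():
        raise ValueError("no events in any group")

    if method == "asymptotic":
        res = multivariate_logrank_test(times, labels, events)
        return LogRankResult(float(res.test_statistic), len(groups) - 1,
                             float(res.p_value))
    if method == "permutation":
        if len(groups) != 2:
            raise ValueError("permutation method supports exactly two groups")
        n = len(times)
        if n > max_permutation_n:
            raise ValueError(f"permutation enumeration limited to n <= {max_permutation_n}")
        obs = _two_group_logrank_chi2(times, events, labels == 0)
        n1 = sizes[0]
        hits = 0
        total = comb(n, n1)
        for idx in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            if _two_group_logrank_chi2(times, events, mask) >= obs - 1e-12:
                hits += 1
        return LogRankResult(obs, 1, hits / total)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Per-covariate coefficients, hazard ratios, Wald CIs and p-values."""

    summary: pd.DataFrame  # index: covariate; columns: coef, hr, ci95_low, ci95_high, p
    n: int
    n_events: int
    ties: str

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(design: pd.DataFrame, times, events,
            ties: str = "efron") -> CoxResult:
    """Cox proportional-hazards regression (partial likelihood).

    ``design`` holds numeric covariate columns (categorical covariates are
    expanded against their reference level by the caller).  Ties are
    handled by Efron's method by default; Breslow is available.
    """
    from statsmodels.duration.hazard_regression import PHReg

    if ties not in {"efron", "breslow"}:
        raise ValueError(f"unknown tie method {ties!r}")
    design = pd.DataFrame(design)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise ValueError(f"covariate(s) constant across subjects: {constant}")
    n_events = int(events.sum())
    if n_events < design.shape[1]:
        warnings.warn(
            f"only {n_events} events for {design.shape[1]} covariates; "
            "estimates may be unstable", stacklevel=2)

    model = PHReg(times, design.to_numpy(dtype=float), status=events, ties=ties)
    res = model.fit(disp=False)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        raise ConvergenceError(
            f"non-finite estimates (params={params}, se={bse})")
    if np.any(np.abs(params) > 15):
        warnings.warn("extreme coefficient magnitude; possible complete separation",
                      stacklevel=2)
    z = stats.norm.ppf(0.975)
    summary = pd.DataFrame({
        "coef": params,
        "hr": np.exp(params),
        "ci95_low": np.exp(params - z * bse),
        "ci95_high": np.exp(params + z * bse),
        "p": 2 * stats.norm.sf(np.abs(params / bse)),
    }, index=list(design.columns))
    return CoxResult(summary, n=len(times), n_events=n_events, ties=ties)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a, b, exact_limit: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Midranks are used for ties.  When the combined sample size is at most
    ``exact_limit`` the null distribution of the rank sum is enumerated
    exactly over all group assignments; otherwise a normal approximation
    with tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n = a.size, pooled.size
    w_obs = ranks[:n_a].sum()
    expect = n_a * (n + 1) / 2

    if n <= exact_limit:
        dev = abs(w_obs - expect)
        hits = sum(
            1 for idx in combinations(range(n), n_a)
            if abs(ranks[list(idx)].sum() - expect) >= dev - 1e-9
        )
        return hits / comb(n, n_a)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n_a * (n - n_a) / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (w_obs - expect - 0.5 * np.sign(w_obs - expect)) / np.sqrt(var)
    return min(1.0, 2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    p: float
    odds_ratio: float  # sample odds ratio ad/bc


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher exact test for a 2x2 count table.

    The p-value sums hypergeometric probabilities no larger than the
    observed table's; a zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    (a, b), (c, d) = t
    with np.errstate(divide="ignore", invalid="ignore"):
        orr = float(a * d / (b * c)) if b * c > 0 else (
            np.inf if a * d > 0 else np.nan)
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return FisherResult(1.0, orr)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(float(p), orr)


# ---------------------------------------------------------------------------
# equal-interval response trend
# ---------------------------------------------------------------------------

@dataclass
class BinTrend:
    """Response rates over equal-width score intervals plus a linear trend.

    The trend line is an unweighted least-squares fit of rate against bin
    index over non-empty bins (empty bins have undefined rates and are
    excluded, reported as NaN).
    """

    bin_edges: np.ndarray
    n: np.ndarray
    responders: np.ndarray
    rate: np.ndarray
    slope: float
    intercept: float


def bin_response_trend(scores, outcome, n_bins: int = 12) -> BinTrend:
    """Divide scores into ``n_bins`` equal intervals and trend the response rate.

    Bins are left-closed with the right edge of the last bin closed, so
    together they cover [min score, max score].
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    if scores.size != outcome.size:
        raise ValueError("scores and outcome must align")
    lo, hi = scores.min(), scores.max()
    if lo == hi:
        raise ValueError("all scores identical; bins would have zero width")
    if np.unique(scores).size < n_bins:
        warnings.warn(f"fewer than {n_bins} distinct scores; bins will be sparse",
                      stacklevel=2)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(scores, edges[1:-1], right=False)  # 0 .. n_bins-1
    n = np.bincount(idx, minlength=n_bins)
    responders = np.bincount(idx, weights=outcome.astype(float),
                             minlength=n_bins)
    with np.errstate(invalid="ignore"):
        rate = np.where(n > 0, responders / np.maximum(n, 1), np.nan)
    nonempty = n > 0
    slope, intercept = np.polyfit(np.arange(n_bins)[nonempty], rate[nonempty], 1)
    return BinTrend(edges, n, responders.astype(int), rate,
                    float(slope), float(intercept))
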