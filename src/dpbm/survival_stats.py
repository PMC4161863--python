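"""Survival-analysis primitives used throughout the pipeline.

Everything here operates on right-censored data: a follow-up ``time`` per
sample and a binary ``event`` indicator (1 = the event of interest, e.g. bone
metastasis as the first metastatic site, was observed; 0 = censored).

The module provides

* univariate Cox proportional-hazards fitting (Newton–Raphson on the partial
  likelihood, Efron or Breslow tie handling), both for a single covariate and
  vectorised across thousands of covariates sharing one risk-set structure —
  the workhorse of bootstrap gene selection;
* the Kaplan–Meier product-limit estimator;
* the Mantel–Cox (log-rank) two-group test;
* a two-group hazard ratio with Wald confidence interval (via the Cox fit on
  a group indicator);
* the Mann–Whitney–Wilcoxon rank-sum test with exact small-sample enumeration.

These are deliberately self-contained (no model-fitting dependency) so that
every number the pipeline reports is produced by code under test here;
external packages serve as independent cross-checks in the test suite only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

__all__ = [
    "CoxFit",
    "KMCurve",
    "LogRankResult",
    "HazardRatioResult",
    "fit_univariate_cox",
    "fit_univariate_cox_many",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "mann_whitney",
]

_MAX_ABS_BETA = 15.0  # |beta| beyond this is treated as monotone-likelihood divergence


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFit:
    """Result of a univariate Cox proportional-hazards fit.

    ``beta`` is the log hazard ratio per unit covariate, ``se`` its standard
    error from the observed information, ``p_value`` the two-sided Wald test.
    ``flag`` is empty for a clean fit, or one of ``"zero_variance"`` /
    ``"monotone"`` / ``"no_converge"`` for degenerate fits (which callers
    should treat as non-informative).
    """

    beta: float
    se: float
    p_value: float
    converged: bool
    n_events: int
    n_iter: int = 0
    loglik: float = float("nan")
    flag: str = ""


@dataclass(frozen=True)
class KMCurve:
    """Kaplan–Meier product-limit curve evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    """Mantel–Cox test: chi-squared statistic (1 df) and two-group O/E counts."""

    statistic: float
    p_value: float
    observed: np.ndarray  # events per group (group 0, group 1)
    expected: np.ndarray


@dataclass(frozen=True)
class HazardRatioResult:
    """Hazard ratio of group 1 vs group 0 with 95% Wald confidence interval."""

    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float = float("nan")
    se: float = float("nan")
    flag: str = ""


# ---------------------------------------------------------------------------
# input validation helpers
# ---------------------------------------------------------------------------

def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or event.shape != time.shape:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if time.size == 0:
        raise ValueError("empty survival data")
    if not np.all(np.isfinite(time)) or np.any(time < 0):
        raise ValueError("follow-up times must be finite and non-negative")
    ev = event.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise ValueError("event indicator must be binary (0/1)")
    return time, ev.astype(np.int64)


# ---------------------------------------------------------------------------
# Cox partial likelihood machinery
# ---------------------------------------------------------------------------

class _RiskSetLayout:
    """Precomputed ordering/tie structure shared by all covariates of a cohort.

    Samples are sorted by time ascending; the risk set at an event time t is
    the suffix of the sorted arrays starting at the first sample with time
    >= t.  Efron's correction needs, per tied-event group of size d, the
    fractions l/d for l = 0..d-1; these are laid out flat so that all
    denominator terms for all event times form one vector operation.
    """

    def __init__(self, time, event, ties="efron"):
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie rule: {ties!r}")
        order = np.argsort(time, kind="stable")
        self.order = order
        self.time = time[order]
        self.event = event[order]
        self.n = time.size
        self.n_events = int(self.event.sum())
        # distinct-time groups
        starts = np.flatnonzero(np.r_[True, self.time[1:] != self.time[:-1]])
        self.group_starts = starts
        group_id = np.cumsum(np.r_[True, self.time[1:] != self.time[:-1]]) - 1
        # per-group event counts
        n_groups = starts.size
        d = np.bincount(group_id, weights=self.event, minlength=n_groups)
        self.event_groups = np.flatnonzero(d > 0)  # groups containing >=1 event
        self.d = d[self.event_groups].astype(np.int64)
        self.risk_start = starts[self.event_groups]
        # event rows (sorted by time, hence grouped) and their reduceat bounds
        ev_rows = np.flatnonzero(self.event == 1)
        self.event_rows = ev_rows
        ev_group = group_id[ev_rows]
        self.event_group_bounds = np.flatnonzero(
            np.r_[True, ev_group[1:] != ev_group[:-1]]
        )
        # flat Efron layout: for event group k, rows l = 0..d_k-1
        self.rep = np.repeat(np.arange(self.event_groups.size), self.d)
        if ties == "efron":
            self.frac = (
                np.concatenate([np.arange(dk) / dk for dk in self.d])
                if self.d.size
                else np.empty(0)
            )
        else:  # breslow: no tie adjustment of the denominator
            self.frac = np.zeros(int(self.d.sum()))
        self.ties = ties

    # -- per-beta quantities ------------------------------------------------

    def _sums(self, Xs, beta):
        """Return (loglik, score, info) arrays of shape (G,) at beta (G,)."""
        eta = Xs * beta  # (n, G) broadcast
        # clip to keep exp finite; divergent columns are flagged by the caller
        W = np.exp(np.clip(eta, -500, 500))
        XW = Xs * W
        X2W = Xs * XW
        # suffix (risk-set) sums at each event group's start row
        S0r = np.cumsum(W[::-1], axis=0)[::-1][self.risk_start]
        S1r = np.cumsum(XW[::-1], axis=0)[::-1][self.risk_start]
        S2r = np.cumsum(X2W[::-1], axis=0)[::-1][self.risk_start]
        # tied-event sums
        Wev, XWev, X2Wev = W[self.event_rows], XW[self.event_rows], X2W[self.event_rows]
        S0d = np.add.reduceat(Wev, self.event_group_bounds, axis=0)
        S1d = np.add.reduceat(XWev, self.event_group_bounds, axis=0)
        S2d = np.add.reduceat(X2Wev, self.event_group_bounds, axis=0)
        f = self.frac[:, None]
        phi = S0r[self.rep] - f * S0d[self.rep]
        num1 = S1r[self.rep] - f * S1d[self.rep]
        num2 = S2r[self.rep] - f * S2d[self.rep]
        phi = np.maximum(phi, 1e-300)
        r1 = num1 / phi
        loglik = (Xs[self.event_rows] * beta).sum(axis=0) - np.log(phi).sum(axis=0)
        score = Xs[self.event_rows].sum(axis=0) - r1.sum(axis=0)
        info = (num2 / phi - r1 * r1).sum(axis=0)
        return loglik, score, info

    def loglik(self, Xs, beta):
        """Partial log-likelihood only (cheaper than the full triple)."""
        W = np.exp(np.clip(Xs * beta, -500, 500))
        S0r = np.cumsum(W[::-1], axis=0)[::-1][self.risk_start]
        S0d = np.add.reduceat(W[self.event_rows], self.event_group_bounds, axis=0)
        phi = np.maximum(S0r[self.rep] - self.frac[:, None] * S0d[self.rep], 1e-300)
        return (Xs[self.event_rows] * beta).sum(axis=0) - np.log(phi).sum(axis=0)


def fit_univariate_cox_many(
    X,
    time,
    event,
    *,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
):
    """Fit one univariate Cox model per column of ``X`` on a shared cohort.

    All columns share the single (time, event) risk-set layout, so the Newton
    iterations are carried out as dense matrix operations across genes.

    Parameters
    ----------
    X : (n_samples, n_covariates) array
    time, event : (n_samples,) arrays
    ties : "efron" (default) or "breslow"
    tol : convergence tolerance on \\|delta beta\\|
    max_iter : Newton iteration cap; step-halving guards each update

    Returns
    -------
    dict of arrays with keys ``beta``, ``se``, ``p_value``, ``converged``,
    ``loglik``, ``flag`` (int8: 0 ok, 1 zero variance, 2 monotone/diverged,
    3 no convergence) plus scalar ``n_events``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event = _check_surv(time, event)
    if X.shape[0] != time.size:
        raise ValueError("X rows must match number of samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in survival data; Cox fit undefined")

    layout = _RiskSetLayout(time, event, ties=ties)
    Xs = X[layout.order]
    G = X.shape[1]

    sd = Xs.std(axis=0)
    degenerate = sd == 0.0

    beta = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    flag = np.zeros(G, dtype=np.int8)
    flag[degenerate] = 1
    converged[degenerate] = True  # nothing to iterate; reported non-informative

    # Newton iterations on a shrinking set of not-yet-converged columns
    act_idx = np.flatnonzero(~degenerate)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if act_idx.size == 0:
            break
        Xa = np.ascontiguousarray(Xs[:, act_idx])
        ba = beta[act_idx]
        ll_cur, U, I = layout._sums(Xa, ba)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(I > 1e-12, U / np.maximum(I, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        new_b = ba + step
        # step-halving where the partial log-likelihood does not improve
        for _ in range(8):
            ll_new = layout.loglik(Xa, new_b)
            bad = ll_new < ll_cur - 1e-12
            if not bad.any():
                break
            step = np.where(bad, step / 2.0, step)
            new_b = ba + step
        beta[act_idx] = new_b
        done = np.abs(step) < tol
        converged[act_idx[done]] = True
        diverged = ~done & (np.abs(new_b) > _MAX_ABS_BETA)
        flag[act_idx[diverged]] = 2
        act_idx = act_idx[~done & ~diverged]

    flag[act_idx] = 3  # hit max_iter without meeting tol
    ll_fin, _, I_fin = layout._sums(Xs, beta)
    with np.errstate(divide="ignore"):
        se = np.where(I_fin > 0, 1.0 / np.sqrt(np.maximum(I_fin, 1e-300)), np.inf)
    se[degenerate] = np.inf
    beta = np.where(degenerate, 0.0, beta)
    with np.errstate(invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    p = np.minimum(2.0 * norm.sf(np.abs(z)), 1.0)
    p[degenerate] = 1.0
    p[flag == 2] = np.nan  # monotone likelihood: Wald p meaningless
    return {
        "beta": beta,
        "se": se,
        "p_value": p,
        "converged": converged & (flag != 2),
        "loglik": ll_fin,
        "flag": flag,
        "n_events": n_events,
        "n_iter": n_iter,
    }


def fit_univariate_cox(
    covariate,
    time,
    event,
    *,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
    p_method: str = "wald",
) -> CoxFit:
    """Fit a single-covariate Cox proportional-hazards model.

    Maximises the partial likelihood (Efron tie correction by default) by
    Newton–Raphson with step-halving.  A zero-variance covariate yields the
    non-informative fit (beta 0, p 1) flagged ``"zero_variance"`` rather than
    an exception; monotone-likelihood divergence is flagged ``"monotone"``
    with ``converged=False``.  ``p_method`` is ``"wald"`` (default) or
    ``"lr"`` (likelihood-ratio test against beta = 0, chi-squared 1 df).
    """
    if p_method not in ("wald", "lr"):
        raise ValueError(f"unknown p_method {p_method!r}")
    x = np.asarray(covariate, dtype=float)[:, None]
    res = fit_univariate_cox_many(
        x,
        time,
        event,
        ties=ties,
        tol=tol,
        max_iter=max_iter,
    )
    fl = {0: "", 1: "zero_variance", 2: "monotone", 3: "no_converge"}[int(res["flag"][0])]
    p = float(res["p_value"][0])
    if p_method == "lr" and fl == "":
        time_a, event_a = _check_surv(time, event)
        layout = _RiskSetLayout(time_a, event_a, ties=ties)
        ll0 = float(layout.loglik(x[layout.order], np.zeros(1))[0])
        lr_stat = max(0.0, 2.0 * (float(res["loglik"][0]) - ll0))
        p = float(chi2.sf(lr_stat, df=1))
    if math.isnan(p):
        p = 1.0  # degenerate: report non-informative, flag carries the reason
    return CoxFit(
        beta=float(res["beta"][0]),
        se=float(res["se"][0]),
        p_value=p,
        converged=bool(res["converged"][0]),
        n_events=int(res["n_events"]),
        n_iter=int(res["n_iter"]),
        loglik=float(res["loglik"][0]),
        flag=fl,
    )


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function.

    Censored subjects remain in the risk set through their censoring time
    (ties between events and censorings at the same time keep the censored
    subjects at risk for that event time, the standard convention).
    """
    time, event = _check_surv(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    uniq = t[starts]
    counts = np.diff(np.r_[starts, n])
    group_id = np.repeat(np.arange(starts.size), counts)
    d = np.bincount(group_id, weights=e, minlength=starts.size)
    at_risk = n - starts  # subjects with time >= uniq[k]
    mask = d > 0
    et, dk, rk = uniq[mask], d[mask], at_risk[mask]
    surv = np.cumprod(1.0 - dk / rk)
    return KMCurve(
        event_times=et,
        survival=surv,
        at_risk=rk.astype(np.int64),
        n_events=dk.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(groups, time, event) -> LogRankResult:
    """Two-group Mantel–Cox log-rank test.

    At each distinct event time the observed group-1 events are compared with
    their hypergeometric expectation given the margins; the chi-squared
    statistic (1 df) is (O-E)^2 / V with the hypergeometric variance V.
    With no events the statistic is 0 and p = 1.
    """
    time, event = _check_surv(time, event)
    g = np.asarray(groups)
    if g.shape != time.shape:
        raise ValueError("groups must match number of samples")
    gvals = np.unique(g)
    if gvals.size != 2:
        raise ValueError(f"exactly two non-empty groups required, got {gvals.size}")
    g1 = (g == gvals[1]).astype(np.int64)

    order = np.argsort(time, kind="stable")
    t, e, z = time[order], event[order], g1[order]
    n = t.size
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    counts = np.diff(np.r_[starts, n])
    gid = np.repeat(np.arange(starts.size), counts)
    d = np.bincount(gid, weights=e, minlength=starts.size)  # events at time
    d1 = np.bincount(gid, weights=e * z, minlength=starts.size)
    n_at = (n - starts).astype(float)  # at risk
    # group-1 at risk: suffix sums of z at group starts
    n1_at = np.cumsum(z[::-1])[::-1][starts].astype(float)

    mask = d > 0
    dm, d1m, nm, n1m = d[mask], d1[mask], n_at[mask], n1_at[mask]
    E = dm * n1m / nm
    with np.errstate(divide="ignore", invalid="ignore"):
        V = dm * (n1m / nm) * (1.0 - n1m / nm) * (nm - dm) / np.maximum(nm - 1.0, 1.0)
    V = np.where(nm > 1, V, 0.0)
    O1 = d1m.sum()
    E1 = E.sum()
    Vsum = V.sum()
    obs = np.array([dm.sum() - O1, O1])
    exp = np.array([dm.sum() - E1, E1])
    if Vsum <= 0:
        return LogRankResult(0.0, 1.0, obs, exp)
    stat = (O1 - E1) ** 2 / Vsum
    return LogRankResult(float(stat), float(chi2.sf(stat, df=1)), obs, exp)


# ---------------------------------------------------------------------------
# hazard ratio
# ---------------------------------------------------------------------------

def hazard_ratio(groups, time, event, *, ties: str = "efron") -> HazardRatioResult:
    """Hazard ratio (group 1 vs group 0) as exp(beta) of an indicator Cox fit.

    The 95% CI is exp(beta +- 1.96 se).  Monotone likelihood (e.g. all events
    in one group) is reported as an infinite/zero HR with ``flag="monotone"``.
    """
    g = np.asarray(groups)
    gvals = np.unique(g)
    if gvals.size != 2:
        raise ValueError("exactly two non-empty groups required")
    ind = (g == gvals[1]).astype(float)
    fit = fit_univariate_cox(ind, time, event, ties=ties)
    if fit.flag == "monotone":
        hr = math.inf if fit.beta > 0 else 0.0
        return HazardRatioResult(hr, 0.0, math.inf, float("nan"), fit.beta, fit.se, "monotone")
    hr = math.exp(fit.beta)
    half = 1.959963984540054 * fit.se
    lo = math.exp(fit.beta - half) if math.isfinite(half) else 0.0
    hi = math.exp(fit.beta + half) if math.isfinite(half) else math.inf
    return HazardRatioResult(hr, lo, hi, fit.p_value, fit.beta, fit.se, fit.flag)


# ---------------------------------------------------------------------------
# Mann–Whitney–Wilcoxon
# ---------------------------------------------------------------------------

def _exact_ranksum_tail(pooled_2ranks, counts, n_a, total_2ranksum_a):
    """Exact null distribution of the group-A rank sum with ties, by DP.

    ``pooled_2ranks`` are the distinct midranks (doubled so they are ints),
    ``counts`` how many pooled observations share each midrank.  Returns the
    probabilities P(R_A <= r) and P(R_A >= r) for the observed doubled rank
    sum ``total_2ranksum_a`` with |A| = n_a, by dynamic programming over how
    many of each tied block fall in A.
    """
    # dp[k] = dict mapping doubled-ranksum -> number of ways, for k chosen
    max_sum = int(sum(r * c for r, c in zip(pooled_2ranks, counts)))
    dp = np.zeros((n_a + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r, c in zip(pooled_2ranks, counts):
        new = np.zeros_like(dp)
        for j in range(min(c, n_a) + 1):
            ways = math.comb(c, j)
            shift = int(r * j)
            kmax = n_a - j
            if shift > max_sum:
                continue
            new[j : j + kmax + 1, shift:] += ways * dp[: kmax + 1, : max_sum + 1 - shift]
        dp = new
    dist = dp[n_a]
    total = dist.sum()
    s = int(round(total_2ranksum_a))
    p_le = dist[: s + 1].sum() / total
    p_ge = dist[s:].sum() / total
    return p_le, p_ge


def mann_whitney(sample_a, sample_b, alternative: str = "two-sided"):
    """Mann–Whitney–Wilcoxon rank-sum test for two unpaired samples.

    Returns ``(U, p_value)`` where U counts pairs (a, b) with a > b (ties
    count 1/2).  When both samples have at most 12 observations the p-value
    is computed by exact enumeration of the permutation distribution of the
    rank sum (tie-aware); otherwise the tie-corrected normal approximation
    with continuity correction is used.

    ``alternative`` is ``"two-sided"`` (default), ``"greater"`` (A tends to
    exceed B) or ``"less"``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    # midranks
    i = 0
    r = np.empty(pooled.size)
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        r[i : j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    ranks[order] = r
    R_a = ranks[:n_a].sum()
    U = R_a - n_a * (n_a + 1) / 2.0  # = #{a > b} + 0.5 #{a == b}

    if n_a <= 12 and n_b <= 12:
        vals, counts = np.unique(pooled, return_counts=True)
        # doubled midranks are integers even with ties
        cum = np.cumsum(counts)
        start = cum - counts
        mid2 = (start + cum - 1) + 2  # 2*midrank = (start+1) + (end+1) - 1 ... simplified
        p_le, p_ge = _exact_ranksum_tail(mid2.tolist(), counts.tolist(), n_a, 2 * R_a)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(U), float(p)

    # tie-corrected normal approximation with continuity correction
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return float(U), 1.0
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (U - mu - 0.5) / sd
        p = norm.sf(z)
    elif alternative == "less":
        z = (U - mu + 0.5) / sd
        p = norm.cdf(z)
    else:
        z = (abs(U - mu) - 0.5) / sd
        p = 2.0 * norm.sf(max(z, 0.0))
    return float(U), float(min(p, 1.0))
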