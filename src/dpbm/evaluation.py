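"""Survival-analysis evaluation of predicted risk groups.

``evaluate_groups`` summarises a high/low risk partition of a cohort with
the log-rank test, the two-group hazard ratio (with 95% CI) and the two
Kaplan–Meier curves.  ``balanced_resample_eval`` guards against class
imbalance: it repeatedly draws equally sized subsamples from the two
predicted groups (without replacement within each group), re-evaluates, and
reports the means of the per-repeat hazard ratios and log-rank p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gene_selection import _as_time_event
from .survival_stats import (
    HazardRatioResult,
    KMCurve,
    LogRankResult,
    hazard_ratio,
    km_estimate,
    logrank_test,
)

__all__ = ["GroupEvaluation", "BalancedResamplingResult", "evaluate_groups", "balanced_resample_eval"]


@dataclass(frozen=True)
class GroupEvaluation:
    """Joint survival summary of a high-vs-low risk split."""

    n_high: int
    n_low: int
    logrank: LogRankResult | None
    hr: HazardRatioResult | None
    km_high: KMCurve | None
    km_low: KMCurve | None

    def to_dict(self) -> dict:
        out = {"n_high": self.n_high, "n_low": self.n_low}
        if self.logrank is not None:
            out["logrank_statistic"] = self.logrank.statistic
            out["logrank_p"] = self.logrank.p_value
        if self.hr is not None:
            out["hazard_ratio"] = self.hr.hr
            out["hr_ci_low"] = self.hr.ci_low
            out["hr_ci_high"] = self.hr.ci_high
        return out


@dataclass(frozen=True)
class BalancedResamplingResult:
    """Means over balanced (equal group size) resampling repeats."""

    n_repeats: int
    group_size: int
    hazard_ratios: np.ndarray
    p_values: np.ndarray

    @property
    def mean_hr(self) -> float:
        return float(np.mean(self.hazard_ratios))

    @property
    def geometric_mean_hr(self) -> float:
        return float(np.exp(np.mean(np.log(self.hazard_ratios))))

    @property
    def mean_p(self) -> float:
        return float(np.mean(self.p_values))


def _high_mask(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    return labels == "high"


def evaluate_groups(labels, survival) -> GroupEvaluation:
    """Log-rank, hazard ratio and KM curves for a high/low risk labelling.

    ``labels`` is boolean (True = high) or the strings "high"/"low".  With an
    empty group the tests are skipped (a warning is raised) and only counts
    and the non-empty group's KM curve are reported.
    """
    time, event = _as_time_event(survival)
    high = _high_mask(labels)
    if high.shape != time.shape:
        raise ValueError("labels and survival must cover the same samples")
    n_high, n_low = int(high.sum()), int((~high).sum())
    km_h = km_estimate(time[high], event[high]) if n_high else None
    km_l = km_estimate(time[~high], event[~high]) if n_low else None
    if n_high == 0 or n_low == 0:
        warnings.warn("one risk group is empty; log-rank/HR skipped", stacklevel=2)
        return GroupEvaluation(n_high, n_low, None, None, km_h, km_l)
    lr = logrank_test(high, time, event)
    hr = hazard_ratio(high, time, event)  # high vs low
    return GroupEvaluation(n_high, n_low, lr, hr, km_h, km_l)


def balanced_resample_eval(
    labels,
    survival,
    *,
    n_repeats: int = 1000,
    seed: int | None = None,
) -> BalancedResamplingResult:
    """Re-evaluate the risk split on repeated balanced subsamples.

    Each repeat draws m = min(n_high, n_low) samples without replacement from
    each predicted group and evaluates the hazard ratio and log-rank p on the
    union.  Repeats with a degenerate fit (monotone likelihood) contribute an
    HR of NaN and are excluded from the means.
    """
    time, event = _as_time_event(survival)
    high = _high_mask(labels)
    idx_h = np.flatnonzero(high)
    idx_l = np.flatnonzero(~high)
    m = min(idx_h.size, idx_l.size)
    if m < 2:
        raise ValueError("both risk groups need at least 2 samples")
    rng = np.random.default_rng(seed)
    hrs = np.empty(n_repeats)
    ps = np.empty(n_repeats)
    for r in range(n_repeats):
        sh = rng.choice(idx_h, size=m, replace=False)
        sl = rng.choice(idx_l, size=m, replace=False)
        idx = np.concatenate([sh, sl])
        g = np.r_[np.ones(m, dtype=bool), np.zeros(m, dtype=bool)]
        lr = logrank_test(g, time[idx], event[idx])
        hr = hazard_ratio(g, time[idx], event[idx])
        hrs[r] = hr.hr if hr.flag != "monotone" else np.nan
        ps[r] = lr.p_value
    ok = np.isfinite(hrs)
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} of {n_repeats} balanced repeats had degenerate fits",
            stacklevel=2,
        )
    return BalancedResamplingResult(
        n_repeats=n_repeats,
        group_size=m,
        hazard_ratios=hrs[ok],
        p_values=ps,
    )
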