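"""Bootstrap stability selection of metastasis-associated candidate genes.

The selection procedure: repeatedly subsample a fixed fraction of the
training cohort (without replacement by default), fit a univariate Cox
proportional-hazards model per gene on each subsample, and call a gene a
*candidate* when its Cox p-value falls below the per-run significance level
in strictly more than a stability fraction of all runs (defaults: 400 runs,
3/4 subsampling, p < 0.05, stability > 0.80).  Each gene's final coefficient
and p-value are the plain averages over all runs.

One subsample is drawn per run and shared by every gene, so results are a
pure function of (data, config, seed).  A subsample containing zero events
carries no Cox information and is redrawn (the redraw count is recorded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import SurvivalData
from .survival_stats import fit_univariate_cox_many

__all__ = [
    "SelectionConfig",
    "BootstrapCoxSelector",
    "select_candidates",
    "candidate_sign",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Bootstrap-selection tuning knobs (defaults reproduce the procedure above)."""

    n_runs: int = 400
    subsample_fraction: float = 0.75
    per_run_alpha: float = 0.05
    stability_threshold: float = 0.80
    replace: bool = False  # True = classical with-replacement bootstrap
    ties: str = "efron"
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must be in (0, 1)")
        if not 0 < self.per_run_alpha < 1:
            raise ValueError("per_run_alpha must be in (0, 1)")
        if not 0 < self.stability_threshold <= 1:
            raise ValueError("stability_threshold must be in (0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def _as_time_event(y):
    """Accept SurvivalData, a structured array with event/time fields, or (time, event)."""
    if isinstance(y, SurvivalData):
        return y.time, y.event
    arr = np.asarray(y)
    if arr.dtype.names:
        names = {n.lower(): n for n in arr.dtype.names}
        ev = arr[names.get("event", list(names.values())[0])]
        tm = arr[names.get("time", list(names.values())[-1])]
        return np.asarray(tm, dtype=float), np.asarray(ev).astype(np.int64)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1].astype(np.int64)
    raise TypeError(
        "y must be SurvivalData, a structured (event, time) array, or an (n, 2) "
        "array of [time, event]"
    )


class BootstrapCoxSelector(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer performing the bootstrap Cox selection.

    Parameters mirror :class:`SelectionConfig`.  ``X`` is samples × genes
    (a DataFrame keeps gene names; a bare array gets positional names),
    ``y`` carries the censored survival outcome.

    Attributes
    ----------
    results_ : DataFrame indexed by gene with columns ``mean_coefficient``,
        ``mean_p_value``, ``stability``, ``selected``.
    selected_genes_ : list of genes with stability strictly above the threshold.
    n_redraws_ : number of event-free subsamples that had to be redrawn.
    """

    def __init__(
        self,
        n_runs: int = 400,
        subsample_fraction: float = 0.75,
        per_run_alpha: float = 0.05,
        stability_threshold: float = 0.80,
        replace: bool = False,
        ties: str = "efron",
        random_state: int | None = None,
    ):
        self.n_runs = n_runs
        self.subsample_fraction = subsample_fraction
        self.per_run_alpha = per_run_alpha
        self.stability_threshold = stability_threshold
        self.replace = replace
        self.ties = ties
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def _config(self) -> SelectionConfig:
        return SelectionConfig(
            n_runs=self.n_runs,
            subsample_fraction=self.subsample_fraction,
            per_run_alpha=self.per_run_alpha,
            stability_threshold=self.stability_threshold,
            replace=self.replace,
            ties=self.ties,
            seed=self.random_state,
        )

    def fit(self, X, y):
        cfg = self._config()
        if isinstance(X, pd.DataFrame):
            genes = [str(g) for g in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            genes = [f"g{i}" for i in range(values.shape[1])]
        time, event = _as_time_event(y)
        n = values.shape[0]
        if time.shape[0] != n:
            raise ValueError("X and y disagree on the number of samples")
        if n < 20:
            raise ValueError("bootstrap selection needs at least ~20 samples")
        if event.sum() == 0:
            raise ValueError("bootstrap selection needs at least one event")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")

        m = int(np.floor(cfg.subsample_fraction * n + 0.5))
        m = min(max(m, 2), n)
        rng = np.random.default_rng(cfg.seed)

        G = values.shape[1]
        sig_counts = np.zeros(G)
        beta_sum = np.zeros(G)
        p_sum = np.zeros(G)
        n_redraws = 0
        for _ in range(cfg.n_runs):
            for _attempt in range(1000):
                idx = rng.choice(n, size=m, replace=cfg.replace)
                if event[idx].sum() > 0:
                    break
                n_redraws += 1
            else:
                raise RuntimeError("could not draw a subsample containing an event")
            res = fit_univariate_cox_many(
                values[idx], time[idx], event[idx], ties=cfg.ties
            )
            p = res["p_value"]
            ok = res["converged"]
            # a failed fit counts as non-significant for that run
            sig = ok & (np.nan_to_num(p, nan=1.0) < cfg.per_run_alpha)
            sig_counts += sig
            beta_sum += res["beta"]
            p_sum += np.nan_to_num(p, nan=1.0)
        if n_redraws:
            logger.info("redrew %d event-free subsamples", n_redraws)

        stability = sig_counts / cfg.n_runs
        results = pd.DataFrame(
            {
                "mean_coefficient": beta_sum / cfg.n_runs,
                "mean_p_value": p_sum / cfg.n_runs,
                "stability": stability,
                "selected": stability > cfg.stability_threshold,
            },
            index=pd.Index(genes, name="gene_id"),
        )
        self.results_ = results
        self.selected_genes_ = results.index[results["selected"]].tolist()
        self.n_redraws_ = n_redraws
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.n_features_in_ = G
        return self

    def get_support(self, indices: bool = False):
        mask = self.results_["selected"].to_numpy()
        return np.flatnonzero(mask) if indices else mask

    def transform(self, X):
        """Restrict ``X`` (samples × genes) to the selected genes."""
        if isinstance(X, pd.DataFrame):
            return X[self.selected_genes_]
        return np.asarray(X)[:, self.get_support(indices=True)]


def select_candidates(
    expr: pd.DataFrame, survival: SurvivalData, config: SelectionConfig | None = None
) -> pd.DataFrame:
    """Functional wrapper: expression is genes × samples (pipeline orientation).

    Returns the per-gene results table (see :class:`BootstrapCoxSelector`).
    """
    config = config or SelectionConfig()
    if list(expr.columns) != list(survival.sample_ids):
        raise ValueError("expression and survival must be aligned (same sample order)")
    sel = BootstrapCoxSelector(
        n_runs=config.n_runs,
        subsample_fraction=config.subsample_fraction,
        per_run_alpha=config.per_run_alpha,
        stability_threshold=config.stability_threshold,
        replace=config.replace,
        ties=config.ties,
        random_state=config.seed,
    )
    sel.fit(expr.T, survival)
    return sel.results_


def candidate_sign(results: pd.DataFrame, gene: str) -> int:
    """Sign (+1/-1) of a selected gene's averaged Cox coefficient.

    An exactly zero mean coefficient carries no direction and raises, which
    callers treat as "exclude this gene".
    """
    if gene not in results.index:
        raise KeyError(f"gene {gene!r} not in selection results")
    coef = float(results.loc[gene, "mean_coefficient"])
    if coef > 0:
        return 1
    if coef < 0:
        return -1
    raise ValueError(f"gene {gene!r} has a zero mean coefficient; sign unassignable")
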