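"""The dysregulated-pathway ensemble risk model.

One *sub-model* per dysregulated pathway: its features are the pathway's
dysregulated genes, split by the sign of their averaged Cox coefficient, and
its score is the unweighted signed sum (grade-index style)

    RiskScore = sum_{i in positive genes} x_i  -  sum_{j in negative genes} x_j

so higher scores mean higher metastasis risk.  Each sub-model's decision
threshold is picked by 10-fold cross-validation: per fold, the candidate
cut-off is the n-th smallest training-fold score where n is the number of
event-free training-fold patients, and the fold whose held-out log-rank
p-value is smallest contributes the final threshold.  A patient whose score
strictly exceeds the threshold is voted high-risk by that sub-model, and the
ensemble labels a patient high-risk iff strictly more than half of the
sub-models vote high-risk.

:class:`DPBMClassifier` packages the full fit (bootstrap gene selection →
pathway enrichment → per-pathway thresholds) behind the scikit-learn
estimator API; the module-level functions expose each stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .enrichment import find_dysregulated_pathways
from .gene_selection import BootstrapCoxSelector, _as_time_event, candidate_sign
from .survival_stats import logrank_test

__all__ = [
    "SubModel",
    "ThresholdSelection",
    "EnsembleModel",
    "risk_score",
    "select_threshold_cv",
    "build_ensemble",
    "predict_risk",
    "DPBMClassifier",
]

HIGH, LOW = "high", "low"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubModel:
    """A single pathway's signed-sum risk scorer with decision threshold."""

    pathway_name: str
    positive_genes: tuple
    negative_genes: tuple
    threshold: float

    def __post_init__(self):
        pos, neg = set(self.positive_genes), set(self.negative_genes)
        if pos & neg:
            raise ValueError("a gene cannot be both positive and negative")
        if not pos | neg:
            raise ValueError("sub-model needs at least one gene")


@dataclass(frozen=True)
class ThresholdSelection:
    """Cross-validated threshold choice: one candidate per fold, best held-out p wins."""

    candidate_thresholds: tuple
    fold_p_values: tuple
    chosen_threshold: float
    fold_assignments: tuple  # fold index per sample


@dataclass(frozen=True)
class EnsembleModel:
    """The majority-vote ensemble of per-pathway sub-models."""

    sub_models: tuple

    def __post_init__(self):
        if len(self.sub_models) == 0:
            raise ValueError("ensemble needs at least one sub-model")

    @property
    def genes(self) -> set:
        out: set = set()
        for sm in self.sub_models:
            out |= set(sm.positive_genes) | set(sm.negative_genes)
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "sub_models": [
                {
                    "pathway_name": sm.pathway_name,
                    "positive_genes": sorted(sm.positive_genes),
                    "negative_genes": sorted(sm.negative_genes),
                    "threshold": sm.threshold,
                }
                for sm in self.sub_models
            ]
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "EnsembleModel":
        if isinstance(source, (str, bytes)) and "{" in str(source):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        subs = tuple(
            SubModel(
                pathway_name=d["pathway_name"],
                positive_genes=tuple(d["positive_genes"]),
                negative_genes=tuple(d["negative_genes"]),
                threshold=float(d["threshold"]),
            )
            for d in payload["sub_models"]
        )
        return cls(subs)


# ---------------------------------------------------------------------------
# risk score
# ---------------------------------------------------------------------------

def risk_score(expression, sub_model: SubModel):
    """Signed-sum risk score of one sample (Series) or many (samples × genes).

    Raises ``KeyError`` listing any sub-model gene absent from the input.
    """
    genes = list(sub_model.positive_genes) + list(sub_model.negative_genes)
    signs = np.r_[
        np.ones(len(sub_model.positive_genes)),
        -np.ones(len(sub_model.negative_genes)),
    ]
    if isinstance(expression, pd.Series):
        missing = [g for g in genes if g not in expression.index]
        if missing:
            raise KeyError(f"expression missing sub-model genes: {missing}")
        return float(expression[genes].to_numpy() @ signs)
    if isinstance(expression, pd.DataFrame):
        missing = [g for g in genes if g not in expression.columns]
        if missing:
            raise KeyError(f"expression missing sub-model genes: {missing}")
        return expression[genes].to_numpy() @ signs
    raise TypeError("expression must be a pandas Series (one sample) or DataFrame")


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def select_threshold_cv(
    scores,
    survival,
    *,
    k: int = 10,
    seed: int | None = None,
    stratify: bool = False,
    evaluate: str = "heldout",
) -> ThresholdSelection:
    """Pick a sub-model's cut-off by k-fold cross-validation.

    Per fold: on the k-1 training folds, let n be the number of event-free
    patients there and take the n-th smallest training-fold score as the
    candidate threshold; label the held-out fold (score > threshold = high)
    and record the held-out log-rank p (1 when a predicted group is empty).
    The fold with the smallest held-out p supplies the final threshold; ties
    break toward the smaller threshold.

    ``stratify=True`` balances event counts across folds.  ``evaluate``
    controls which samples score a candidate threshold: ``"heldout"``
    (default, avoids optimistic bias) or ``"train"`` (the whole training
    set, i.e. all samples passed in).
    """
    if evaluate not in ("heldout", "train"):
        raise ValueError(f"unknown evaluate mode {evaluate!r}")
    scores = np.asarray(scores, dtype=float)
    time, event = _as_time_event(survival)
    n = scores.size
    if time.size != n:
        raise ValueError("scores and survival must cover the same samples")
    if n < k:
        raise ValueError(f"need at least k={k} samples for {k}-fold CV")
    if event.sum() == 0:
        raise ValueError("threshold selection needs at least one event")

    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=np.int64)
    if stratify:
        for cls in (0, 1):
            idx = rng.permutation(np.flatnonzero(event == cls))
            for f, chunk in enumerate(np.array_split(idx, k)):
                fold_of[chunk] = f
    else:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k)):
            fold_of[chunk] = f

    cands, ps = [], []
    for f in range(k):
        test_mask = fold_of == f
        train_mask = ~test_mask
        tr_scores = np.sort(scores[train_mask])
        n_free = int((event[train_mask] == 0).sum())
        if n_free == 0:
            thr = -np.inf  # no event-free patients: everyone scores above the cut
        else:
            thr = float(tr_scores[n_free - 1])  # n-th smallest, 1-based
        cands.append(thr)
        eval_mask = test_mask if evaluate == "heldout" else np.ones(n, dtype=bool)
        held_high = scores[eval_mask] > thr
        if held_high.all() or (~held_high).all():
            ps.append(1.0)
        else:
            res = logrank_test(held_high, time[eval_mask], event[eval_mask])
            ps.append(res.p_value)
    ps_arr = np.asarray(ps)
    cands_arr = np.asarray(cands)
    best_p = ps_arr.min()
    chosen = float(cands_arr[ps_arr == best_p].min())
    return ThresholdSelection(
        candidate_thresholds=tuple(cands),
        fold_p_values=tuple(ps),
        chosen_threshold=chosen,
        fold_assignments=tuple(int(f) for f in fold_of),
    )


# ---------------------------------------------------------------------------
# ensemble construction and prediction
# ---------------------------------------------------------------------------

def build_ensemble(
    expr: pd.DataFrame,
    survival,
    enrichment_results: list,
    selection_results: pd.DataFrame,
    *,
    k: int = 10,
    seed: int | None = None,
) -> EnsembleModel:
    """Build one sub-model per dysregulated pathway and assemble the ensemble.

    ``expr`` is samples × genes (training cohort).  Pathway genes absent from
    the expression matrix are dropped at build time; genes whose averaged
    coefficient is exactly zero are excluded; a pathway left without signed
    genes is dropped with a warning.  Per-pathway CV seeds are derived from
    ``seed`` so sub-models are individually reproducible.
    """
    subs = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(enrichment_results))
    for child, res in zip(children, enrichment_results):
        pos, neg = [], []
        for g in sorted(res.dysregulated_genes):
            if g not in expr.columns:
                continue
            try:
                s = candidate_sign(selection_results, g)
            except (KeyError, ValueError):
                continue
            (pos if s > 0 else neg).append(g)
        if not pos and not neg:
            warnings.warn(
                f"pathway {res.pathway_name!r} has no signed genes in the "
                "expression matrix; dropped",
                stacklevel=2,
            )
            continue
        proto = SubModel(res.pathway_name, tuple(pos), tuple(neg), threshold=0.0)
        scores = risk_score(expr, proto)
        sel = select_threshold_cv(
            scores, survival, k=k, seed=int(child.generate_state(1)[0] % (2**31))
        )
        subs.append(
            SubModel(res.pathway_name, tuple(pos), tuple(neg), sel.chosen_threshold)
        )
    return EnsembleModel(tuple(subs))


def predict_risk(expr: pd.DataFrame, model: EnsembleModel) -> pd.DataFrame:
    """Per-sample sub-model scores/votes and the majority-vote label.

    Returns a DataFrame indexed like ``expr`` (samples × genes in) with one
    ``score:<pathway>`` and ``vote:<pathway>`` column pair per sub-model plus
    ``n_high_votes`` and ``final_label`` (high iff votes > half the models).
    """
    out = pd.DataFrame(index=expr.index)
    n_high = np.zeros(len(expr), dtype=np.int64)
    for sm in model.sub_models:
        s = risk_score(expr, sm)
        v = s > sm.threshold
        out[f"score:{sm.pathway_name}"] = s
        out[f"vote:{sm.pathway_name}"] = np.where(v, HIGH, LOW)
        n_high += v.astype(np.int64)
    out["n_high_votes"] = n_high
    out["final_label"] = np.where(n_high > len(model.sub_models) / 2.0, HIGH, LOW)
    return out


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------

class DPBMClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end pathway-ensemble risk classifier (scikit-learn API).

    Parameters
    ----------
    pathways : dict mapping pathway name -> set of gene ids (e.g. from a GMT
        file).  Analogous to a fixed vocabulary: it is a hyperparameter, not
        training data.
    n_runs, subsample_fraction, per_run_alpha, stability_threshold, replace :
        bootstrap gene-selection settings (see :class:`SelectionConfig`).
    enrich_alpha, min_pathway_size : dysregulated-pathway call settings.
    universe : "pathway_measured" (default) restricts the enrichment universe
        to measured genes that appear in at least one pathway; "measured"
        uses all measured genes.
    cv_folds : folds for per-pathway threshold selection.
    random_state : master seed; selection and per-pathway CV seeds derive
        from it.

    Attributes (after ``fit``)
    --------------------------
    selection_ : per-gene bootstrap results table.
    candidate_genes_ : genes passing the stability filter.
    enrichment_ : list of :class:`EnrichmentResult` for dysregulated pathways.
    ensemble_ : the fitted :class:`EnsembleModel`.
    classes_ : ``array(["high", "low"])``.
    """

    def __init__(
        self,
        pathways: dict | None = None,
        *,
        n_runs: int = 400,
        subsample_fraction: float = 0.75,
        per_run_alpha: float = 0.05,
        stability_threshold: float = 0.80,
        replace: bool = False,
        enrich_alpha: float = 0.05,
        min_pathway_size: int = 5,
        universe: str = "pathway_measured",
        cv_folds: int = 10,
        random_state: int | None = None,
    ):
        self.pathways = pathways
        self.n_runs = n_runs
        self.subsample_fraction = subsample_fraction
        self.per_run_alpha = per_run_alpha
        self.stability_threshold = stability_threshold
        self.replace = replace
        self.enrich_alpha = enrich_alpha
        self.min_pathway_size = min_pathway_size
        self.universe = universe
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _universe(self, measured) -> set:
        measured = set(measured)
        if self.universe == "measured":
            return measured
        if self.universe == "pathway_measured":
            in_pathways = set().union(*self.pathways.values()) if self.pathways else set()
            return measured & {str(g) for g in in_pathways}
        raise ValueError(f"unknown universe mode {self.universe!r}")

    def fit(self, X, y):
        if not self.pathways:
            raise ValueError("a non-empty pathway collection is required")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples × genes DataFrame with gene names")
        ss = np.random.SeedSequence(self.random_state)
        sel_seed, cv_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

        selector = BootstrapCoxSelector(
            n_runs=self.n_runs,
            subsample_fraction=self.subsample_fraction,
            per_run_alpha=self.per_run_alpha,
            stability_threshold=self.stability_threshold,
            replace=self.replace,
            random_state=sel_seed,
        )
        selector.fit(X, y)
        self.selection_ = selector.results_
        self.candidate_genes_ = selector.selected_genes_

        universe = self._universe(X.columns.astype(str))
        self.enrichment_ = find_dysregulated_pathways(
            self.candidate_genes_,
            self.pathways,
            universe,
            alpha=self.enrich_alpha,
            min_size=self.min_pathway_size,
        )
        if not self.enrichment_:
            raise ValueError(
                "no dysregulated pathway at alpha="
                f"{self.enrich_alpha}; cannot build an ensemble"
            )
        self.ensemble_ = build_ensemble(
            X,
            y,
            self.enrichment_,
            self.selection_,
            k=self.cv_folds,
            seed=cv_seed,
        )
        self.classes_ = np.array([HIGH, LOW])
        self.feature_names_in_ = X.columns.to_numpy(dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        detail = predict_risk(X, self.ensemble_)
        return detail["final_label"].to_numpy()

    def predict_detail(self, X) -> pd.DataFrame:
        """Full per-sample score/vote table (see :func:`predict_risk`)."""
        return predict_risk(X, self.ensemble_)

    def decision_function(self, X) -> np.ndarray:
        """High-vote margin: n_high_votes - n_sub_models / 2 (positive = high)."""
        detail = predict_risk(X, self.ensemble_)
        return detail["n_high_votes"].to_numpy() - len(self.ensemble_.sub_models) / 2.0
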