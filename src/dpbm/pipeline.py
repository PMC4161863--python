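"""End-to-end pipeline: split → select → enrich → train → predict → evaluate → topology.

``run_pipeline`` drives the whole analysis from a single
:class:`PipelineConfig` and writes every stage's output plus a provenance
manifest into a run directory.  One master seed fans out deterministically
to per-stage seeds (via ``numpy.random.SeedSequence`` spawn keys), so the
run is a pure function of (inputs, config, seed) and any stage can be
reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .dpbm_model import DPBMClassifier, predict_risk
from .evaluation import balanced_resample_eval, evaluate_groups
from .network_topology import compare_groups, compute_topology

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)

_STAGES = ("split", "select", "cv", "evaluate")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs; serialized alongside its outputs."""

    expression: str
    clinical: str
    pathways: str
    network: str | None = None
    out_dir: str = "dpbm_run"
    train_fraction: float = 2 / 3
    n_runs: int = 400
    subsample_fraction: float = 0.75
    per_run_alpha: float = 0.05
    stability_threshold: float = 0.80
    enrich_alpha: float = 0.05
    min_pathway_size: int = 5
    universe: str = "pathway_measured"
    cv_folds: int = 10
    balanced_repeats: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(master_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _eval_payload(labels, survival, *, repeats, seed) -> dict:
    ev = evaluate_groups(labels, survival)
    out = ev.to_dict()
    if ev.n_high >= 2 and ev.n_low >= 2 and repeats > 0:
        bal = balanced_resample_eval(labels, survival, n_repeats=repeats, seed=seed)
        out["balanced_mean_hr"] = bal.mean_hr
        out["balanced_mean_p"] = bal.mean_p
        out["balanced_group_size"] = bal.group_size
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory.

    Outputs: ``split.json``, ``selection.tsv``, ``enrichment.tsv``,
    ``model.json``, ``predictions_train.tsv`` / ``predictions_test.tsv``,
    ``evaluation.json``, ``topology.tsv`` + ``topology.json`` (when a
    network is given), ``km_<cohort>_<group>.tsv`` curves and
    ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expr = io_formats.load_expression(config.expression)
    survival = io_formats.load_clinical(config.clinical)
    pathways = io_formats.load_gmt(config.pathways)
    expr, survival = io_formats.align(expr, survival)

    split = io_formats.split_cohort(
        expr.columns, config.train_fraction, stage_seed(config.seed, "split")
    )
    with open(out / "split.json", "w") as fh:
        json.dump(
            {"train": list(split.train_sample_ids), "test": list(split.test_sample_ids)},
            fh,
            indent=2,
        )

    expr_train = expr[list(split.train_sample_ids)]
    surv_train = survival.subset(split.train_sample_ids)
    expr_test = expr[list(split.test_sample_ids)]
    surv_test = survival.subset(split.test_sample_ids)

    clf = DPBMClassifier(
        pathways=pathways,
        n_runs=config.n_runs,
        subsample_fraction=config.subsample_fraction,
        per_run_alpha=config.per_run_alpha,
        stability_threshold=config.stability_threshold,
        enrich_alpha=config.enrich_alpha,
        min_pathway_size=config.min_pathway_size,
        universe=config.universe,
        cv_folds=config.cv_folds,
        random_state=stage_seed(config.seed, "select"),
    )
    logger.info("fitting ensemble on %d training samples", len(surv_train))
    clf.fit(expr_train.T, surv_train)

    clf.selection_.to_csv(out / "selection.tsv", sep="\t")
    enr = pd.DataFrame(
        [
            {
                "pathway": r.pathway_name,
                "p_value": r.p_value,
                "x": r.x,
                "K": r.K,
                "N": r.N,
                "M": r.M,
                "dysregulated_genes": ",".join(sorted(r.dysregulated_genes)),
            }
            for r in clf.enrichment_
        ]
    )
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    clf.ensemble_.to_json(out / "model.json")

    evaluation: dict = {}
    for name, e, s in (
        ("train", expr_train, surv_train),
        ("test", expr_test, surv_test),
    ):
        detail = predict_risk(e.T, clf.ensemble_)
        detail.to_csv(out / f"predictions_{name}.tsv", sep="\t", index_label="sample_id")
        labels = detail["final_label"].to_numpy()
        evaluation[name] = _eval_payload(
            labels,
            s,
            repeats=config.balanced_repeats,
            seed=stage_seed(config.seed, "evaluate"),
        )
        ev = evaluate_groups(labels, s)
        for gname, curve in (("high", ev.km_high), ("low", ev.km_low)):
            if curve is not None:
                curve.to_table().to_csv(out / f"km_{name}_{gname}.tsv", sep="\t", index=False)
    with open(out / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=2, sort_keys=True)

    if config.network:
        network = io_formats.load_edge_list(config.network)
        topo = compute_topology(network)
        topo.to_csv(out / "topology.tsv", sep="\t")
        dys = set().union(*(set(r.dysregulated_genes) for r in clf.enrichment_))
        comp = compare_groups(topo, dys, set(clf.candidate_genes_))
        with open(out / "topology.json", "w") as fh:
            json.dump(comp.to_dict(), fh, indent=2, sort_keys=True)

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "inputs": {
            k: _sha256(v)
            for k, v in {
                "expression": config.expression,
                "clinical": config.clinical,
                "pathways": config.pathways,
                **({"network": config.network} if config.network else {}),
            }.items()
        },
        "n_candidate_genes": len(clf.candidate_genes_),
        "n_dysregulated_pathways": len(clf.enrichment_),
    }
    try:
        from importlib.metadata import version

        manifest["version"] = version("dpbm")
    except Exception:  # pragma: no cover - not installed
        manifest["version"] = "unknown"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
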