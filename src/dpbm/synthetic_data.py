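"""Synthetic cohorts with planted structure for every pipeline stage.

The generator emulates the shape of a merged breast-cancer expression cohort
with right-censored organ-specific (bone) metastasis-free survival: a few
hundred samples, a few thousand genes, a small minority of *signal* genes
whose expression modulates the event hazard, a pathway collection in which a
few pathways are deliberately enriched in signal genes, and a sparse
interaction network in which signal genes can be made hubs.

Generative model
----------------
* expression: independent standard normal per gene (log-scale intensities
  after per-gene standardisation);
* event times: proportional hazards with cumulative hazard
  ``H(t | x) = baseline_hazard * exp(sum_g effect_g x_g) * t**shape``
  (shape 1, the default, gives exponential times — the simplest model
  consistent with the Cox analyses downstream);
* censoring: independent exponential, its rate calibrated so the expected
  censored fraction equals ``censoring_rate`` given the realised hazards;
* observed time = min(event, censoring), event indicator accordingly.

Every draw is a pure function of ``design.seed``; the returned *truth*
record (signal genes with signed effects, enriched pathway names) lets tests
score each stage's recovery.  Default sizes mirror the merged cohort the
method targets: 569 samples, ~30% observed events, 2000 genes, 50 pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import SurvivalData

__all__ = ["SimulationDesign", "simulate_cohort", "simulate_pathways", "simulate_network", "simulate_all"]


@dataclass(frozen=True)
class SimulationDesign:
    """All knobs of the synthetic study, with cohort-realistic defaults."""

    n_samples: int = 569
    n_genes: int = 2000
    n_signal_genes: int = 20
    effect_size: float = 0.8  # |log-hazard| per unit (sd) expression
    baseline_hazard: float = 0.01  # per month at x = 0
    weibull_shape: float = 1.0  # 1 = exponential event times
    censoring_rate: float = 0.703  # expected censored fraction (~30% events)
    correlation: float = 0.0  # equicorrelation within enriched pathway blocks
    n_pathways: int = 50
    pathway_size_range: tuple = (15, 40)
    n_enriched_pathways: int = 3
    enrichment_overlap: int = 12  # signal genes per enriched pathway
    network_mean_degree: float = 6.0
    hub_boost: float = 2.0  # extra attachment factor for signal genes
    seed: int | None = None

    def __post_init__(self):
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes must be <= n_genes")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        lo, hi = self.pathway_size_range
        if self.n_enriched_pathways > 0 and self.enrichment_overlap > hi:
            raise ValueError("enrichment_overlap exceeds the maximum pathway size")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=seed)


def _gene_names(n: int):
    width = len(str(n - 1))
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def _stage_rngs(seed):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(3)]


def _calibrate_censoring(hazards: np.ndarray, shape: float, target: float) -> float:
    """Rate c of an Exp(c) censoring time achieving the target censored fraction.

    For exponential events (shape 1) the censored probability given a
    per-sample hazard h is c/(c+h), so the mean over samples is solved
    exactly; for Weibull shapes the per-sample probability is integrated
    numerically on a log-spaced grid.
    """
    if target == 0.0:
        return 0.0
    if shape == 1.0:
        def frac(c):
            return float(np.mean(c / (c + hazards))) - target
    else:
        # P(C < T | h) = int_0^inf c e^{-ct} exp(-h t^shape) dt
        t = np.logspace(-6, 6, 4000)
        def frac(c):
            ct = np.exp(-c * t)[None, :] * np.exp(-np.outer(hazards, t**shape))
            vals = c * ct
            return float(np.mean(np.trapezoid(vals, t, axis=1))) - target
    lo, hi = 1e-12, 1e12
    if frac(lo) > 0 or frac(hi) < 0:
        raise ValueError("censoring calibration infeasible for this design")
    return brentq(frac, lo, hi, xtol=1e-12, rtol=1e-10)


def simulate_cohort(design: SimulationDesign, truth: dict | None = None):
    """Draw (expression genes × samples, SurvivalData, truth record).

    Passing an existing ``truth`` record reuses its signal genes and effects
    while drawing fresh expression, event and censoring values — i.e. an
    independent cohort from the *same* population, the right way to create a
    matched test set for a model trained on an earlier draw.
    """
    rng, _, _ = _stage_rngs(design.seed)
    n, G = design.n_samples, design.n_genes
    genes = _gene_names(G)
    samples = [f"S{str(i).zfill(len(str(n - 1)))}" for i in range(n)]

    X = rng.standard_normal((n, G))
    if truth is not None:
        name_to_idx = {g: i for i, g in enumerate(genes)}
        signal_idx = np.array([name_to_idx[g] for g in truth["signal_genes"]], dtype=np.int64)
        effects = np.array([truth["effects"][g] for g in truth["signal_genes"]])
        if signal_idx.size != design.n_signal_genes:
            raise ValueError("truth record does not match the design's signal gene count")
    else:
        signal_idx = rng.choice(G, size=design.n_signal_genes, replace=False)
        signs = np.where(np.arange(design.n_signal_genes) % 2 == 0, 1.0, -1.0)
        effects = signs * design.effect_size
    if design.correlation > 0 and design.n_signal_genes > 1:
        # equicorrelated signal block: share a latent factor
        rho = design.correlation
        z = rng.standard_normal(n)[:, None]
        X[:, signal_idx] = np.sqrt(rho) * z + np.sqrt(1 - rho) * X[:, signal_idx]

    lp = X[:, signal_idx] @ effects
    hazards = design.baseline_hazard * np.exp(lp)
    # T = (E / h)^(1/shape) with E ~ Exp(1) has cumulative hazard h * t^shape
    T = (rng.exponential(1.0, size=n) / hazards) ** (1.0 / design.weibull_shape)
    c = _calibrate_censoring(hazards, design.weibull_shape, design.censoring_rate)
    if c == 0.0:
        time, event = T, np.ones(n, dtype=np.int64)
    else:
        C = rng.exponential(1.0 / c, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(np.int64)

    expr = pd.DataFrame(X.T, index=pd.Index(genes, name="gene_id"), columns=samples)
    survival = SurvivalData(tuple(samples), time, event)
    truth = {
        "signal_genes": [genes[i] for i in signal_idx],
        "effects": {genes[i]: float(e) for i, e in zip(signal_idx, effects)},
        "censoring_rate_target": design.censoring_rate,
        "event_fraction": float(event.mean()),
    }
    return expr, survival, truth


def simulate_pathways(design: SimulationDesign, truth: dict):
    """Pathway collection with ``n_enriched_pathways`` planted gene sets.

    Enriched pathways contain ``enrichment_overlap`` signal genes plus
    uniform non-signal fillers; the remaining pathways are drawn uniformly
    from the whole gene universe, so a correctly calibrated enrichment test
    flags non-planted pathways at roughly its nominal rate.  The truth record
    gains the list of enriched pathway names.
    """
    _, rng, _ = _stage_rngs(design.seed)
    genes = _gene_names(design.n_genes)
    signal = list(truth["signal_genes"])
    if design.n_enriched_pathways > 0 and design.enrichment_overlap > len(signal):
        raise ValueError("enrichment_overlap exceeds the number of signal genes")
    non_signal = [g for g in genes if g not in set(signal)]
    lo, hi = design.pathway_size_range
    width = len(str(design.n_pathways - 1))
    pathways: dict = {}
    enriched_names = []
    for i in range(design.n_pathways):
        name = f"pathway_{str(i).zfill(width)}"
        size = int(rng.integers(lo, hi + 1))
        if i < design.n_enriched_pathways:
            size = max(size, design.enrichment_overlap)
            core = rng.choice(len(signal), size=design.enrichment_overlap, replace=False)
            fill = rng.choice(
                len(non_signal), size=size - design.enrichment_overlap, replace=False
            )
            members = {signal[j] for j in core} | {non_signal[j] for j in fill}
            enriched_names.append(name)
        else:
            members = {genes[j] for j in rng.choice(design.n_genes, size=size, replace=False)}
        pathways[name] = members
    truth = dict(truth)
    truth["enriched_pathways"] = enriched_names
    return pathways, truth


def simulate_network(design: SimulationDesign, truth: dict) -> nx.Graph:
    """Sparse random interaction network, optionally with signal-gene hubs.

    Background: Erdős–Rényi with edge probability matching the design's mean
    degree.  Each signal gene then receives ``round(hub_boost * mean_degree)``
    additional edges to uniformly chosen partners, planting the
    "important genes are central" pattern the topology comparison looks for.
    """
    _, _, rng = _stage_rngs(design.seed)
    genes = _gene_names(design.n_genes)
    p = min(design.network_mean_degree / max(design.n_genes - 1, 1), 1.0)
    seed_int = int(rng.integers(0, 2**31 - 1))
    G = nx.fast_gnp_random_graph(design.n_genes, p, seed=seed_int)
    G = nx.relabel_nodes(G, dict(enumerate(genes)))
    extra = int(round(design.hub_boost * design.network_mean_degree))
    if extra > 0:
        for g in truth["signal_genes"]:
            partners = rng.choice(design.n_genes, size=extra, replace=False)
            for j in partners:
                if genes[j] != g:
                    G.add_edge(g, genes[j])
    return G


def simulate_all(design: SimulationDesign):
    """Convenience: cohort + pathways + network + combined truth record."""
    expr, survival, truth = simulate_cohort(design)
    pathways, truth = simulate_pathways(design, truth)
    network = simulate_network(design, truth)
    return expr, survival, pathways, network, truth
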