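"""Topological comparison of gene groups in a protein interaction network.

Dysregulated genes are compared against (a) the remaining candidate genes
and (b) all remaining network genes on two centralities: degree and
normalized shortest-path betweenness (Brandes' algorithm via networkx).
Group differences are tested with the Mann–Whitney–Wilcoxon test; the
comparison is directional on request ("greater": dysregulated genes tend to
have larger values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .survival_stats import mann_whitney

__all__ = ["TopologyComparison", "compute_topology", "compare_groups"]

METRICS = ("degree", "betweenness")
PAIRINGS = ("dysregulated_vs_candidate", "dysregulated_vs_all")


@dataclass(frozen=True)
class TopologyComparison:
    """Mann–Whitney comparisons of centralities between gene groups."""

    groups: dict  # group name -> list of genes (in the network)
    medians: dict  # (group, metric) -> median value
    p_values: dict  # (pairing, metric) -> p-value (may be absent if skipped)
    alternative: str = "two-sided"
    n_excluded: dict = field(default_factory=dict)  # genes absent from the network

    def to_dict(self) -> dict:
        return {
            "alternative": self.alternative,
            "group_sizes": {k: len(v) for k, v in self.groups.items()},
            "n_excluded": dict(self.n_excluded),
            "medians": {f"{g}:{m}": v for (g, m), v in self.medians.items()},
            "p_values": {f"{c}:{m}": v for (c, m), v in self.p_values.items()},
        }


def compute_topology(network: nx.Graph, *, normalized: bool = True) -> pd.DataFrame:
    """Per-node degree and betweenness centrality.

    Betweenness uses the exact all-pairs Brandes accumulation, by default
    with global normalization (2/((n-1)(n-2)) for undirected graphs) so
    values lie in [0, 1] also for disconnected graphs.  Rank-based group
    comparisons are invariant to this monotone normalization.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    if any(u == v for u, v in network.edges()):
        raise ValueError("network must not contain self-loops")
    deg = dict(network.degree())
    btw = nx.betweenness_centrality(network, normalized=normalized)
    nodes = list(network.nodes())
    return pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
        },
        index=pd.Index([str(n) for n in nodes], name="gene_id"),
    )


def compare_groups(
    topology: pd.DataFrame,
    dysregulated,
    candidates,
    *,
    alternative: str = "two-sided",
) -> TopologyComparison:
    """Compare dysregulated genes' centralities with the two reference groups.

    Reference groups exclude the dysregulated genes: "candidate" is the
    candidate genes minus the dysregulated set, "all" is every other network
    gene.  Gene sets are first intersected with the network's nodes (the
    exclusion counts are recorded).  An empty group skips its comparisons
    with a warning instead of raising.
    """
    nodes = set(topology.index)
    dys_in = sorted({str(g) for g in dysregulated} & nodes)
    cand_in = sorted(({str(g) for g in candidates} - set(dys_in)) & nodes)
    all_in = sorted(nodes - set(dys_in))
    groups = {
        "dysregulated": dys_in,
        "candidate_minus_dysregulated": cand_in,
        "all_minus_dysregulated": all_in,
    }
    n_excluded = {
        "dysregulated": len(set(map(str, dysregulated))) - len(dys_in),
        "candidate": len({str(g) for g in candidates} - set(dys_in)) - len(cand_in),
    }

    medians = {}
    for gname, members in groups.items():
        for metric in METRICS:
            medians[(gname, metric)] = (
                float(np.median(topology.loc[members, metric])) if members else float("nan")
            )

    p_values = {}
    pairs = {
        "dysregulated_vs_candidate": cand_in,
        "dysregulated_vs_all": all_in,
    }
    for pairing, other in pairs.items():
        if not dys_in or not other:
            warnings.warn(f"{pairing}: a group is empty; comparison skipped", stacklevel=2)
            continue
        for metric in METRICS:
            _, p = mann_whitney(
                topology.loc[dys_in, metric].to_numpy(),
                topology.loc[other, metric].to_numpy(),
                alternative=alternative,
            )
            p_values[(pairing, metric)] = p
    return TopologyComparison(
        groups=groups,
        medians=medians,
        p_values=p_values,
        alternative=alternative,
        n_excluded=n_excluded,
    )
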