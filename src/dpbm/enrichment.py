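"""Hypergeometric enrichment of candidate genes in pathways.

A pathway is *dysregulated* when its overlap with the candidate gene set is
larger than chance under sampling without replacement: with ``x`` the overlap
size, ``K`` the number of candidate genes, ``N`` the number of (measured)
pathway genes and ``M`` the universe size, the p-value is the upper tail
P(X >= x) of a Hypergeometric(M, K, N) variable.  The candidate genes inside
a dysregulated pathway are its *dysregulated genes* and become the features
of that pathway's risk sub-model.

The tail is accumulated in log space (log-gamma binomial coefficients +
log-sum-exp), which stays accurate for the tiny p-values of strongly
enriched pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "find_dysregulated_pathways",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's enrichment call."""

    pathway_name: str
    x: int  # overlap (candidate genes in the pathway)
    K: int  # candidate genes in the universe
    N: int  # pathway genes in the universe
    M: int  # universe size
    p_value: float
    dysregulated_genes: frozenset = field(default_factory=frozenset)


def _log_binom(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeom_upper_tail(x, K: int, N: int, M: int):
    """Upper-tail hypergeometric probability P(X >= x).

    X is the overlap between a uniformly drawn N-subset (the pathway) and a
    fixed K-subset (the candidates) of an M-element universe.  ``x`` may be a
    scalar or array; bounds are validated (0 <= x <= min(K, N), K, N <= M).
    """
    K, N, M = int(K), int(N), int(M)
    if M < 0 or K < 0 or N < 0 or K > M or N > M:
        raise ValueError(f"invalid hypergeometric parameters K={K}, N={N}, M={M}")
    x_arr = np.atleast_1d(np.asarray(x, dtype=np.int64))
    if np.any(x_arr < 0) or np.any(x_arr > min(K, N)):
        raise ValueError("x must satisfy 0 <= x <= min(K, N)")
    lo = max(0, N + K - M)
    hi = min(N, K)
    support = np.arange(lo, hi + 1)
    log_pmf = (
        _log_binom(K, support)
        + _log_binom(M - K, N - support)
        - _log_binom(M, N)
    )
    # suffix log-sum-exp: log_tail[j] = log sum_{i >= lo+j} pmf
    log_tail = np.logaddexp.accumulate(log_pmf[::-1])[::-1]
    idx = np.clip(x_arr - lo, 0, hi - lo)
    out = np.where(x_arr <= lo, 0.0, log_tail[idx])
    out = np.exp(np.minimum(out, 0.0))
    return float(out[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else out


def find_dysregulated_pathways(
    candidates,
    pathways: dict,
    universe,
    *,
    alpha: float = 0.05,
    min_size: int = 5,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Return the pathways hypergeometrically enriched in the candidate genes.

    Pathway gene sets are intersected with the ``universe`` before sizing,
    pathways with fewer than ``min_size`` universe genes are skipped, and a
    pathway is reported when its raw upper-tail p-value is strictly below
    ``alpha`` (set ``fdr=True`` to apply Benjamini–Hochberg across the tested
    pathways instead of using raw p-values).  Results are sorted by p
    ascending, ties by name.
    """
    universe = {str(g) for g in universe}
    candidates = {str(g) for g in candidates} & universe
    M = len(universe)
    K = len(candidates)
    if K == 0:
        warnings.warn("empty candidate set: no pathway can be enriched", stacklevel=2)
        return []
    tested: list[EnrichmentResult] = []
    for name, genes in pathways.items():
        members = {str(g) for g in genes} & universe
        N = len(members)
        if N < min_size:
            continue
        overlap = members & candidates
        p = hypergeom_upper_tail(len(overlap), K, N, M)
        tested.append(
            EnrichmentResult(
                pathway_name=name,
                x=len(overlap),
                K=K,
                N=N,
                M=M,
                p_value=p,
                dysregulated_genes=frozenset(overlap),
            )
        )
    if fdr and tested:
        adj = benjamini_hochberg([r.p_value for r in tested])
        keep = [r for r, q in zip(tested, adj) if q < alpha]
    else:
        keep = [r for r in tested if r.p_value < alpha]
    return sorted(keep, key=lambda r: (r.p_value, r.pathway_name))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
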