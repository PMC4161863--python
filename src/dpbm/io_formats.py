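"""Readers/writers and alignment for the pipeline's external formats.

Formats handled
---------------
* expression matrix: TSV, genes in rows (first column = gene id), samples in
  columns (header row), log-scale continuous values;
* clinical table: TSV with columns ``sample_id``, ``time`` (follow-up, study
  units such as months) and ``event`` (1 = the organ-specific metastasis of
  interest occurred first, 0 = censored / free);
* pathway collections: GMT (name, description, member genes per line);
* protein–protein interaction networks: two-column edge-list TSV.

The in-memory containers are the field's usual ones: a pandas DataFrame for
expression (genes × samples), a small :class:`SurvivalData` record for the
clinical data, a ``dict`` mapping pathway name to a gene set, and a
``networkx.Graph`` for the PPI network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SurvivalData",
    "CohortSplit",
    "load_expression",
    "write_expression",
    "validate_expression",
    "load_clinical",
    "write_clinical",
    "load_gmt",
    "write_gmt",
    "load_edge_list",
    "write_edge_list",
    "align",
    "split_cohort",
]


# ---------------------------------------------------------------------------
# survival container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalData:
    """Per-sample right-censored follow-up for the event of interest."""

    sample_ids: tuple
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=np.int64)
        ids = tuple(str(s) for s in self.sample_ids)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in survival data")
        if time.shape != (len(ids),) or event.shape != (len(ids),):
            raise ValueError("time/event length must match sample_ids")
        if np.any(~np.isfinite(time)) or np.any(time < 0):
            raise ValueError("follow-up times must be finite and non-negative")
        if not np.all(np.isin(event, (0, 1))):
            raise ValueError("event indicator must be 0/1")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def __len__(self):
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids) -> "SurvivalData":
        """Reorder/subset to the given sample ids (all must be present)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from survival data: {missing[:5]}")
        idx = np.array([index[s] for s in sample_ids], dtype=np.int64)
        return SurvivalData(tuple(sample_ids), self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint train/test sample-id lists from a random cohort split."""

    train_sample_ids: tuple
    test_sample_ids: tuple

    def __post_init__(self):
        tr, te = set(self.train_sample_ids), set(self.test_sample_ids)
        if tr & te:
            raise ValueError("train/test sample sets overlap")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes × samples expression DataFrame.

    Requires unique gene and sample identifiers and finite values throughout.
    """
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression values must be numeric")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains missing or non-finite values")
    return expr


def load_expression(path, *, missing: str = "strict", transpose: bool = False) -> pd.DataFrame:
    """Load a TSV expression matrix (genes in rows, samples in columns).

    Parameters
    ----------
    missing : "strict" (default) rejects any missing value; "mean" imputes
        per-gene means (the inputs this pipeline targets are pre-normalised
        and complete, so imputation is opt-in).
    transpose : set when the file is samples-in-rows.
    """
    if missing not in ("strict", "mean"):
        raise ValueError(f"unknown missing-value policy {missing!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene rows in {path}: {dups[:5]}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from exc
    if df.isna().any().any():
        if missing == "strict":
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise ValueError(
                f"missing expression values (policy=strict) for genes {bad[:5]}"
            )
        row_means = df.mean(axis=1)
        df = df.apply(lambda col: col.fillna(row_means))
    return validate_expression(df)


def write_expression(expr: pd.DataFrame, path) -> None:
    validate_expression(expr)
    expr.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

def load_clinical(path) -> SurvivalData:
    """Load the clinical TSV (sample_id, time, event columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    return SurvivalData(
        tuple(df["sample_id"]),
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(),
    )


def write_clinical(survival: SurvivalData, path) -> None:
    survival.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pathways (GMT)
# ---------------------------------------------------------------------------

def load_gmt(path) -> dict:
    """Parse a GMT file into ``{pathway_name: set(gene_ids)}``.

    Each line is name, description, then member genes, tab-separated; the
    description is discarded and repeated genes collapse to a set.
    """
    pathways: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name = fields[0]
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways[name] = genes
    return pathways


def write_gmt(pathways: dict, path, *, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, description] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# PPI network (edge list)
# ---------------------------------------------------------------------------

def load_edge_list(path) -> nx.Graph:
    """Load a two-column TSV edge list as a simple undirected graph.

    Self-loops are dropped; duplicate edges collapse (simple graph).
    """
    G = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: edge line needs two columns")
            u, v = fields[0], fields[1]
            if u == v:
                continue
            G.add_edge(u, v)
    return G


def write_edge_list(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in G.edges()):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# alignment and splitting
# ---------------------------------------------------------------------------

def align(expr: pd.DataFrame, survival: SurvivalData):
    """Restrict expression and survival to their common samples, same order.

    The sample order of the expression matrix is kept for the samples present
    in both inputs.  Raises if no sample is shared.
    """
    validate_expression(expr)
    common = [s for s in expr.columns if s in set(survival.sample_ids)]
    if not common:
        raise ValueError("expression and survival data share no samples")
    return expr[common], survival.subset(common)


def split_cohort(samples, train_fraction: float, seed: int, *, strata=None) -> CohortSplit:
    """Randomly split samples into train/test.

    ``|train| = ceil(train_fraction * n)``, matching the conventional 2/3
    split of a 569-sample cohort into 380 train + 189 test.  Deterministic
    given ``seed``.  ``strata`` (optional mapping sample -> stratum, e.g.
    source study) applies the same fraction within every stratum; the
    default split is unstratified.
    """
    samples = [str(s) for s in samples]
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if strata is not None:
        groups: dict = {}
        for s in samples:
            groups.setdefault(strata[s], []).append(s)
        train, test = [], []
        for key in sorted(groups, key=str):
            members = groups[key]
            if len(members) == 1:  # a singleton stratum cannot be split
                train.extend(members)
                continue
            sub = split_cohort(members, train_fraction, int(rng.integers(2**31)))
            train.extend(sub.train_sample_ids)
            test.extend(sub.test_sample_ids)
        return CohortSplit(tuple(train), tuple(test))
    n_train = int(math.ceil(train_fraction * n - 1e-9))
    n_train = min(max(n_train, 1), n - 1)
    perm = rng.permutation(n)
    train = [samples[i] for i in sorted(perm[:n_train])]
    test = [samples[i] for i in sorted(perm[n_train:])]
    return CohortSplit(tuple(train), tuple(test))
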