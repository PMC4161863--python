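"""Packaged reference data.

The package ships the published eight-pathway bone-metastasis signature for
breast cancer: for each dysregulated KEGG pathway, its enrichment p-value
and its dysregulated genes with their averaged Cox coefficients, p-values
and bootstrap stabilities.  It serves as a worked real-data example of the
model's output format and as the gene/sign source for scoring new cohorts
with the published sub-models.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reference_signature",
    "reference_pathway_gene_sets",
    "reference_gene_signs",
]


def load_reference_signature() -> pd.DataFrame:
    """The reference signature as a tidy table (one row per pathway-gene pair).

    Columns: ``pathway``, ``enrichment_p``, ``gene_id`` (Entrez),
    ``gene_symbol``, ``cox_coefficient``, ``cox_p``, ``stability``.  Genes
    shared by several pathways appear once per pathway.
    """
    ref = resources.files("dpbm.data").joinpath("bone_metastasis_signature.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def reference_pathway_gene_sets() -> dict:
    """``{pathway: set(gene symbols)}`` of the reference signature."""
    df = load_reference_signature()
    return {p: set(g["gene_symbol"]) for p, g in df.groupby("pathway", sort=False)}


def reference_gene_signs() -> dict:
    """``{gene symbol: +1/-1}`` from the sign of the averaged Cox coefficient."""
    df = load_reference_signature()
    first = df.drop_duplicates("gene_symbol")
    return {
        row.gene_symbol: (1 if row.cox_coefficient > 0 else -1)
        for row in first.itertuples()
    }
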