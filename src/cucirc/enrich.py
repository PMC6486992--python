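"""Hypergeometric term enrichment among parent genes of DE circRNAs.

For each annotation term with at least one hit in the differential set, the
upper-tail hypergeometric probability P(X >= k) is computed for drawing k
term-carrying genes in a differential set of size n from a background of N
genes of which K carry the term, followed by Benjamini-Hochberg adjustment.
This is the classic per-term Fisher test; graph-aware decorrelation (as in
topGO's elim) is deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

__all__ = ["enrich_terms", "read_gene_terms", "write_gene_terms"]


def read_gene_terms(path) -> Dict[str, Set[str]]:
    """2-column TSV (gene_id, term_id[|term_name]) -> gene -> set of terms."""
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


def write_gene_terms(gene_to_terms: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene_to_terms):
            for term in sorted(gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\n")


def enrich_terms(
    de_genes: Iterable[str],
    background_genes: Iterable[str],
    gene_to_terms: Mapping[str, Iterable[str]],
    term_names: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Enrichment of annotation terms in ``de_genes`` against the background.

    Returns one row per term with k >= 1 differential genes, sorted by
    ascending p-value (ties by term_id), with columns k, K, n, N, p_value
    and BH-adjusted fdr.  The differential set must be a subset of the
    background; terms only count genes present in the background.
    """
    de = set(de_genes)
    background = set(background_genes)
    if not de <= background:
        raise ValueError(
            f"differential genes outside background: {sorted(de - background)[:5]}"
        )
    term_genes: Dict[str, Set[str]] = {}
    for gene, terms in gene_to_terms.items():
        if gene in background:
            for t in terms:
                term_genes.setdefault(t, set()).add(gene)

    N, n = len(background), len(de)
    rows: List[dict] = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        k = len(genes & de)
        if k == 0:
            continue
        K = len(genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"]
    )
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df
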