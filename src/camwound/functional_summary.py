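"""GO-category composition of gene lists and generic over-representation testing.

Category percentages describe a gene list's composition: for each term, the
percentage of list genes annotated to it, out of the list genes carrying any
annotation in the same namespace (a gene annotated to several terms counts
once per term, so percentages can sum past 100).  Over-representation against
a background uses the one-sided hypergeometric upper tail with BH adjustment
across tested terms; the input annotation is taken as already propagated
through the ontology graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    list_hits: int
    list_size: int
    background_hits: int
    background_size: int
    p_value: float
    adjusted_p: float = float("nan")


def _check_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_symbol", "term_id"}
    missing = required - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if "namespace" not in annotation.columns:
        annotation = annotation.assign(namespace="biological_process")
    return annotation.drop_duplicates(["gene_symbol", "term_id"])


def category_percentages(genes, annotation: pd.DataFrame, terms) -> pd.Series:
    """Percentage of (annotated) list genes carrying each term.

    The denominator for a term is the number of list genes with at least one
    annotation in the term's namespace.
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ValueError("empty gene list")
    annotation = _check_annotation(annotation)
    in_list = annotation[annotation["gene_symbol"].isin(genes)]
    term_ns = annotation.drop_duplicates("term_id").set_index("term_id")["namespace"]
    out = {}
    for term in terms:
        if term not in term_ns.index:
            out[term] = 0.0
            continue
        ns = term_ns.loc[term]
        denom = in_list.loc[in_list["namespace"] == ns, "gene_symbol"].nunique()
        hits = in_list.loc[in_list["term_id"] == term, "gene_symbol"].nunique()
        out[term] = 100.0 * hits / denom if denom else 0.0
    return pd.Series(out, name="percentage")


def enrichment_test(list_genes, background_genes, annotation: pd.DataFrame, term: str) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test for one term.

    p = P(X >= k) where X is the number of term-annotated genes in a random
    list of the same size drawn from the background without replacement.
    """
    list_set = set(list_genes)
    background = set(background_genes)
    if not list_set <= background:
        raise ValueError("gene list must be a subset of the background")
    annotation = _check_annotation(annotation)
    term_genes = set(annotation.loc[annotation["term_id"] == term, "gene_symbol"])
    M = len(background)
    n = len(list_set)
    K = len(term_genes & background)
    k = len(term_genes & list_set)
    p = float(hypergeom.sf(k - 1, M, K, n))
    return EnrichmentResult(term, k, n, K, M, min(p, 1.0))


def enrichment_table(list_genes, background_genes, annotation: pd.DataFrame, terms=None) -> pd.DataFrame:
    """Enrichment results for many terms with BH-adjusted p-values."""
    annotation = _check_annotation(annotation)
    if terms is None:
        terms = list(dict.fromkeys(annotation["term_id"]))
    results = [enrichment_test(list_genes, background_genes, annotation, t) for t in terms]
    adjusted = multipletests([r.p_value for r in results], method="fdr_bh")[1] if results else []
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "list_hits": [r.list_hits for r in results],
            "list_size": [r.list_size for r in results],
            "background_hits": [r.background_hits for r in results],
            "background_size": [r.background_size for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": list(adjusted),
        }
    )


def read_annotation(path) -> pd.DataFrame:
    """Read a gene/term/namespace annotation TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return _check_annotation(df)
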