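"""GO-category composition and over-representation of the wound gene lists.

Computes per-term percentages for the up-regulated list (out of annotated
list genes, per namespace) and a hypergeometric over-representation test
against all probes on the chip, with BH adjustment.
"""

from _common import RESULTS, SEED, ensure_bundle

from camwound.differential_expression import DEConfig, permutation_fdr, select_de_genes
from camwound.expression_matrix import read_design_table, read_expression_table
from camwound.functional_summary import category_percentages, enrichment_table, read_annotation


def main() -> None:
    config = ensure_bundle()
    bundle = config.parent
    matrix = read_expression_table(bundle / "expression.tsv")
    design = read_design_table(bundle / "design.tsv")
    annotation = read_annotation(bundle / "annotation.tsv")

    cfg = DEConfig(seed=SEED)
    up, down = select_de_genes(permutation_fdr(matrix, design, cfg), cfg)
    up_genes = [r.probe_id for r in up]
    terms = list(dict.fromkeys(annotation["term_id"]))

    pct = category_percentages(up_genes, annotation, terms)
    enrich = enrichment_table(up_genes, matrix.probe_ids, annotation, terms)
    out = RESULTS / "go_summary.tsv"
    with open(out, "w") as fh:
        fh.write("# stage: functional_summary (up-regulated list)\n")
        merged = enrich.assign(percentage=[pct[t] for t in enrich["term_id"]])
        merged.to_csv(fh, sep="\t", index=False, float_format="%.4g")

    print(f"wrote {out}")
    for row in merged.itertuples():
        print(f"  {row.term_id}: {row.percentage:.1f}% of annotated up-genes, "
              f"p={row.p_value:.3g}, adjusted p={row.adjusted_p:.3g}")


if __name__ == "__main__":
    main()
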