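"""Sample-level quality control: do wound and control samples separate?

Clusters the six arrays by average linkage on correlation distance and
writes the merge table.  With real planted wound effects the top split of
the dendrogram should reproduce the wound/control design, as the published
experiment's QC clustering did.
"""

from _common import RESULTS, ensure_bundle

from camwound.expression_matrix import cluster_samples, read_design_table, read_expression_table


def main() -> None:
    config = ensure_bundle()
    bundle = config.parent
    matrix = read_expression_table(bundle / "expression.tsv")
    design = read_design_table(bundle / "design.tsv")
    den = cluster_samples(matrix)

    out = RESULTS / "qc_dendrogram.tsv"
    with open(out, "w") as fh:
        fh.write("# stage: expression_qc (average linkage, 1 - Pearson r)\n")
        fh.write("node_a\tnode_b\theight\n")
        for a, b, h in den.merges:
            fh.write(f"{a}\t{b}\t{h:.6f}\n")

    parts = [sorted(den.labels[i] for i in c) for c in den.cut(2)]
    groups = {frozenset(design.wound_samples), frozenset(design.control_samples)}
    separated = {frozenset(p) for p in parts} == groups
    print(f"wrote {out}")
    print(f"top split: {parts[0]} | {parts[1]}")
    print("wound and control samples separate cleanly" if separated
          else "WARNING: top split does not match the design groups")


if __name__ == "__main__":
    main()
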