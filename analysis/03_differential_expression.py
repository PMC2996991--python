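"""Differential expression between wound and matched control samples.

Runs the SAM-style Wilcoxon screen with permutation FDR (exhaustive for the
3v3 design), selects genes at FDR < 5% and fold change > 2, and checks the
calls against the planted truth.
"""

from _common import RESULTS, SEED, ensure_bundle

from camwound.differential_expression import (
    DEConfig,
    permutation_fdr,
    select_de_genes,
    write_results_table,
)
from camwound.expression_matrix import read_design_table, read_expression_table
from camwound.synthetic_data import SimulationTruth


def main() -> None:
    config = ensure_bundle()
    bundle = config.parent
    matrix = read_expression_table(bundle / "expression.tsv")
    design = read_design_table(bundle / "design.tsv")
    truth = SimulationTruth.from_json(bundle / "truth.json")

    cfg = DEConfig(seed=SEED)
    results = permutation_fdr(matrix, design, cfg)
    up, down = select_de_genes(results, cfg)
    out = RESULTS / "de_results.tsv"
    write_results_table(results, out, ["stage: differential_expression (3v3, exhaustive permutations)"])

    planted = {g for g, f in truth.de_flags.items() if f}
    called = {r.probe_id for r in up} | {r.probe_id for r in down}
    sens = len(planted & called) / len(planted)
    fp = len(called - planted)
    print(f"wrote {out}")
    print(f"{len(up)} genes up-regulated and {len(down)} genes down-regulated "
          f"at FDR < {cfg.fdr_max:.0%}, FC > {cfg.fc_min:g}")
    print(f"sensitivity vs planted truth: {sens:.0%}; false calls: {fp}")
    print("strongest effects:")
    for r in up[:5]:
        print(f"  {r.probe_id}  signed FC {r.signed_fold_change:8.2f}  fdr {r.fdr:.3f}")


if __name__ == "__main__":
    main()
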