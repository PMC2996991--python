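"""qPCR validation of selected wound genes by ddCt.

Computes one fold change per egg for every target gene on the simulated
9-egg plate (normalized to the housekeeping gene HNRPH1), summarizes with
the geometric mean and compares against the planted array fold changes.
"""

from _common import RESULTS, ensure_bundle

from camwound.qpcr import gene_summary_table, read_ct_table, write_fold_change_table
from camwound.synthetic_data import SimulationTruth


def main() -> None:
    config = ensure_bundle()
    bundle = config.parent
    ct = read_ct_table(bundle / "qpcr_ct.tsv")
    table = gene_summary_table(ct)
    out = RESULTS / "qpcr_fold_changes.tsv"
    write_fold_change_table(table, out, ["stage: qpcr (ddCt vs HNRPH1, geometric-mean summary)"])

    truth = SimulationTruth.from_json(bundle / "truth.json")
    print(f"wrote {out}")
    print("gene        planted FC   qPCR FC (geom. mean of 9 eggs)")
    summaries = table[table["egg_id"] == "summary"]
    for row in summaries.itertuples():
        planted = truth.qpcr_fold_changes.get(row.gene, float("nan"))
        print(f"{row.gene}  {planted:10.2f}   {row.fold_change:10.2f}")


if __name__ == "__main__":
    main()
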