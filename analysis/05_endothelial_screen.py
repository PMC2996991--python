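"""The full screen: wound genes with an endothelial signature.

Runs the complete pipeline (differential expression, ortholog mapping,
endothelial EST-pool filter at q <= 0.01, literature Angioscore) and writes
the joined endothelial report: gene, q-value, EST counts, Endofactor,
direction, Angioscore and the wound/control fold change.
"""

from _common import ensure_bundle

from camwound.pipeline import PipelineConfig, run_pipeline
from camwound.synthetic_data import SimulationTruth


def main() -> None:
    config = ensure_bundle()
    out = run_pipeline(PipelineConfig.from_yaml(config))

    truth = SimulationTruth.from_json(config.parent / "truth.json")
    human_of = dict(truth.ortholog_pairs)
    de_humans = {human_of[g] for g, f in truth.de_flags.items() if f}
    planted = set(truth.endothelial_genes) & de_humans
    reported = {r.gene_symbol for r in out["report"]}

    print(f"wrote {out['report_path']}")
    print(f"{len(out['up'])} up / {len(out['down'])} down regulated; "
          f"{len(out['report'])} wound genes pass the endothelial filter (q <= 0.01)")
    print(f"planted endothelial wound genes recovered: {len(planted & reported)}/{len(planted)}")
    print("top of the report (gene, q, counts, Endofactor, Angioscore, FC):")
    for r in out["report"][:5]:
        ef = "inf" if r.endo_factor == float("inf") else f"{r.endo_factor:.3f}"
        print(f"  {r.gene_symbol}  q={r.q_value:.4f}  {r.endo_count}/{r.nonendo_count}  "
              f"{ef}  {r.direction}  angioscore={r.angioscore}  fc={r.fold_change}")


if __name__ == "__main__":
    main()
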