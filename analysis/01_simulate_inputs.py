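"""Generate the synthetic study inputs.

Writes a coherent bundle under results/synthetic_inputs/: a 3-egg matched
wound/control expression experiment with planted fold changes (3- to
80-fold, 10% of genes), bidirectional chicken/human alignment hit tables
with decoy paralogs, endothelial/non-endothelial EST pools with planted
enrichment on human orthologs of wound-induced genes, a gene-linked abstract
corpus, a 9-egg qPCR plate and a small GO annotation — plus truth.json with
every planted parameter and config.yaml for the pipeline.
"""

from _common import BUNDLE, SEED

from camwound.pipeline import simulate_input_bundle
from camwound.synthetic_data import SimulationTruth


def main() -> None:
    config = simulate_input_bundle(BUNDLE, seed=SEED, n_genes=400)
    truth = SimulationTruth.from_json(BUNDLE / "truth.json")
    n_de = sum(truth.de_flags.values())
    print(f"wrote input bundle to {BUNDLE}")
    print(f"  {len(truth.de_flags)} genes, {n_de} with planted wound effects")
    print(f"  {len(truth.ortholog_pairs)} planted ortholog pairs")
    print(f"  {len(truth.endothelial_genes)} planted endothelial-pool genes")
    print(f"  config: {config}")


if __name__ == "__main__":
    main()
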