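"""Chicken-to-human ortholog prediction by reciprocal best hit.

Reads the bidirectional alignment hit tables, applies the RBH rule and
compares the recovered one-to-one mapping with the planted ortholog graph
(which includes one-way decoy paralogs that a naive best-hit mapping would
absorb).
"""

from _common import RESULTS, ensure_bundle

from camwound.ortholog_rbh import read_blast_tabular, reciprocal_best_hits, write_pairs_table
from camwound.synthetic_data import SimulationTruth


def main() -> None:
    config = ensure_bundle()
    bundle = config.parent
    fwd = read_blast_tabular(bundle / "hits_chick_to_human.tsv")
    rev = read_blast_tabular(bundle / "hits_human_to_chick.tsv")
    pairs = reciprocal_best_hits(fwd, rev)
    out = RESULTS / "orthologs.tsv"
    write_pairs_table(pairs, out, ["stage: ortholog_rbh"])

    truth = SimulationTruth.from_json(bundle / "truth.json")
    got = {(p.species_a_id, p.species_b_id) for p in pairs}
    planted = set(truth.ortholog_pairs)
    decoys_in = sum(1 for a, _ in got if "decoy" in a)
    print(f"wrote {out}")
    print(f"{len(pairs)} ortholog pairs from {len(fwd)} forward / {len(rev)} reverse hits")
    print(f"planted pairs recovered: {len(got & planted)}/{len(planted)}; "
          f"decoy paralogs admitted: {decoys_in}")


if __name__ == "__main__":
    main()
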