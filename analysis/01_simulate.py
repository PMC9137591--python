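"""Generate the synthetic study dataset.

Simulates the emulated design — 5 LBW + 5 HBW broilers sampled in jejunum
chymus (JC), jejunum mucosa (JM) and caecum chymus (CC) — with planted
co-occurring genus blocks (JC and JM), a JC-to-JM driver genus, and planted
body-weight effects, then writes the count table, metadata, taxonomy, tree
and ground truth under results/analysis/.
"""

import sys
from pathlib import Path

from gutlinks.io import write_count_table, write_json, write_metadata, write_taxonomy, write_tree
from gutlinks.pipeline import _stage_seed
from gutlinks.simulate import default_design, simulate_counts, simulate_tree

OUT = Path("results/analysis")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    design = default_design(seed=SEED)
    table, meta, tax, truth = simulate_counts(design)
    newick = simulate_tree(design.n_genera, _stage_seed(SEED, "tree"), taxa=table.feature_ids)
    write_count_table(table, OUT / "counts.tsv")
    write_metadata(meta, OUT / "metadata.tsv")
    write_taxonomy(tax, OUT / "taxonomy.tsv")
    write_tree(newick, OUT / "tree.nwk")
    write_json(truth.to_json_dict(), OUT / "truth.json")
    print(f"simulated {table.n_features} genera x {table.n_samples} samples (seed {SEED})")
    print(f"planted blocks: {[ (b.place, len(b.genera)) for b in design.planted_blocks ]}")
    print(f"planted BW effects: {sorted(truth.true_bw_genera)}")


if __name__ == "__main__":
    main()
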