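"""Per-place Spearman screen of genus abundance against body weight.

Genera above 0.01% mean relative abundance and present in at least 8 of a
place's 10 samples are correlated with the birds' individual weights; the
hits are compared with the planted ground truth.
"""

import json
from pathlib import Path

from gutlinks import composition as comp, trait
from gutlinks.io import Config, read_count_table, read_metadata, read_taxonomy

OUT = Path("results/analysis")


def main():
    cfg = Config()
    rare = read_count_table(OUT / "rarefied_counts.tsv")
    meta = read_metadata(OUT / "metadata.tsv")
    meta = meta[meta["sample_id"].isin(rare.sample_ids)].reset_index(drop=True)
    tax = read_taxonomy(OUT / "taxonomy.tsv")
    rel = comp.to_relative(comp.aggregate_to_rank(rare, tax, "genus"))

    screen = trait.bw_correlation_screen(rel, meta, cfg)
    screen.to_csv(OUT / "bw_correlations.tsv", sep="\t", index=False)
    hits = trait.significant_correlations(screen, cfg.alpha)
    truth = json.loads((OUT / "truth.json").read_text())
    planted = {(p, g) for p, g, _ in truth["true_bw_genera"]}
    print(f"{len(hits)} significant correlations (raw p < {cfg.alpha}):")
    for r in hits.itertuples():
        mark = "*planted*" if (r.place, r.genus) in planted else ""
        print(f"  {r.place} {r.genus}: rho={r.rho:+.2f} p={r.p_value:.3g} {mark}")
    recovered = {(r.place, r.genus) for r in hits.itertuples()} & planted
    print(f"recovered {len(recovered)}/{len(planted)} planted BW-associated genera")


if __name__ == "__main__":
    main()
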