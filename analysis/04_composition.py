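"""Compositional screening: group-mean tables, B/F ratio, two-way ANOVA
with BH-FDR, and shared/unique feature accounting.
"""

from pathlib import Path

from gutlinks import composition as comp
from gutlinks.io import Config, read_count_table, read_metadata, read_taxonomy, write_json

OUT = Path("results/analysis")


def main():
    cfg = Config()
    rare = read_count_table(OUT / "rarefied_counts.tsv")
    meta = read_metadata(OUT / "metadata.tsv")
    meta = meta[meta["sample_id"].isin(rare.sample_ids)].reset_index(drop=True)
    tax = read_taxonomy(OUT / "taxonomy.tsv")

    for rank in ("phylum", "genus"):
        rel = comp.to_relative(comp.aggregate_to_rank(rare, tax, rank))
        gmt = comp.group_mean_table(rel, meta)
        gmt.to_frame().to_csv(OUT / f"group_means_{rank}.tsv", sep="\t",
                              index_label="taxon")
        screen = comp.anova_screen(rel, meta, cfg)
        screen.table.to_csv(OUT / f"anova_screen_{rank}.tsv", sep="\t",
                            index_label="taxon")
        n_sig = (screen.table.filter(like="class_") == "significant").any(axis=1).sum()
        print(f"{rank}: {n_sig}/{len(screen.table)} taxa FDR-significant on >=1 effect")

    rel_phylum = comp.to_relative(comp.aggregate_to_rank(rare, tax, "phylum"))
    ratio, groups = comp.bf_ratio(rel_phylum, meta)
    ratio.to_frame().to_csv(OUT / "bf_ratio_samples.tsv", sep="\t",
                            index_label="sample_id")
    print("B/F ratio group means:")
    print(groups.round(3))

    venn = comp.venn_unique_shared(rare, meta, by="place")
    write_json(
        {"groups": list(venn.groups), "aggregate": venn.aggregate,
         "unique": venn.unique, "core": venn.core,
         "regions": {"+".join(sorted(k)): v for k, v in venn.regions.items()}},
        OUT / "venn_places.json",
    )
    print(f"core features shared by all places: {venn.core}; unique: {venn.unique}")


if __name__ == "__main__":
    main()
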