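"""End-to-end orchestration: simulate or load inputs, then run filtering,
rarefaction, diversity, ordination, compositional screening, the body-weight
correlation screen, and the co-occurrence networks, writing every table
under one output directory together with a reproducibility manifest.

Outputs are plain text (TSV/JSON/Newick/GraphML). Reruns with the same
inputs and seed are byte-identical; the manifest records the config
snapshot, input digests and per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import composition, diversity, ordination, trait
from . import network as coocnet
from .io import (
    BW_GROUPS,
    Config,
    CountTable,
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    sha256_of,
    write_count_table,
    write_json,
    write_metadata,
    write_taxonomy,
    write_tree,
)
from .simulate import default_design, simulate_counts, simulate_tree

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seed(base_seed: int, stage: str) -> int:
    import hashlib

    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(
    config: Config | str | Path | None = None,
    out_dir: str | Path = "results/run",
    design=None,
    counts_path=None,
    taxonomy_path=None,
    metadata_path=None,
    tree_path=None,
) -> dict:
    """Run all stages and return the manifest (also written to
    ``manifest.json``).

    Either ``design`` (simulate mode; a :class:`SyntheticDesign` or ``True``
    for the default demonstration design) or the three input paths must be
    given.
    """
    if isinstance(config, (str, Path)):
        config = Config.from_yaml(config)
    config = config or Config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "gutlinks",
        "version": __version__,
        "config": {**dataclasses.asdict(config), "trend_band": list(config.trend_band)},
        "stages": [],
        "inputs": {},
        "outputs": [],
    }

    def record(stage, **extra):
        manifest["stages"].append({"stage": stage, **extra})

    def save_frame(frame: pd.DataFrame, name: str, index_label=None):
        path = out / name
        frame.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label)
        manifest["outputs"].append(name)

    # ---- inputs ----------------------------------------------------------
    try:
        if design is not None:
            if design is True:
                design = default_design(seed=config.seed)
            table, meta, tax, truth = simulate_counts(design)
            newick = simulate_tree(
                design.n_genera, _stage_seed(design.seed, "tree"),
                taxa=table.feature_ids,
            )
            write_count_table(table, out / "input_counts.tsv")
            write_metadata(meta, out / "input_metadata.tsv")
            write_taxonomy(tax, out / "input_taxonomy.tsv")
            write_tree(newick, out / "input_tree.nwk")
            write_json(truth.to_json_dict(), out / "truth.json")
            manifest["outputs"] += [
                "input_counts.tsv", "input_metadata.tsv", "input_taxonomy.tsv",
                "input_tree.nwk", "truth.json",
            ]
            tree = read_tree(out / "input_tree.nwk")
            record("simulate", seed=design.seed)
        else:
            if not (counts_path and taxonomy_path and metadata_path):
                raise ValueError(
                    "either a design (simulate mode) or counts/taxonomy/metadata "
                    "paths are required"
                )
            table = read_count_table(counts_path)
            tax = read_taxonomy(taxonomy_path)
            meta = read_metadata(metadata_path)
            tree = read_tree(tree_path) if tree_path else None
            for label, p in (
                ("counts", counts_path), ("taxonomy", taxonomy_path),
                ("metadata", metadata_path), ("tree", tree_path),
            ):
                if p:
                    manifest["inputs"][label] = sha256_of(p)
            record("load")
        missing = set(meta["sample_id"]) - set(table.sample_ids)
        if missing:
            raise ValueError(f"metadata samples absent from counts: {sorted(missing)}")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("inputs", exc) from exc

    # ---- filter + rarefy -------------------------------------------------
    try:
        table = diversity.filter_low_abundance(table, config.min_feature_reads)
        seed = _stage_seed(config.seed, "rarefy")
        rare = diversity.rarefy(table, config.rarefaction_depth, seed)
        meta = meta[meta["sample_id"].isin(rare.sample_ids)].reset_index(drop=True)
        write_count_table(rare, out / "rarefied_counts.tsv")
        manifest["outputs"].append("rarefied_counts.tsv")
        record("filter_rarefy", seed=seed, depth=config.rarefaction_depth,
               n_features=rare.n_features, n_samples=rare.n_samples)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("filter_rarefy", exc) from exc

    # ---- aggregate + relative -------------------------------------------
    try:
        genus = composition.aggregate_to_rank(rare, tax, "genus")
        phylum = composition.aggregate_to_rank(rare, tax, "phylum")
        rel_genus = composition.to_relative(genus)
        rel_phylum = composition.to_relative(phylum)
        record("aggregate")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("aggregate", exc) from exc

    # ---- alpha diversity -------------------------------------------------
    try:
        alpha = diversity.alpha_diversity(rare, tree=tree, log_base=config.shannon_log_base)
        save_frame(alpha, "alpha_diversity.tsv", index_label="sample_id")
        record("alpha_diversity")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("alpha_diversity", exc) from exc

    # ---- ordination ------------------------------------------------------
    try:
        seed = _stage_seed(config.seed, "ordination")
        bc = ordination.bray_curtis(rel_genus)
        save_frame(
            pd.DataFrame(bc.data, index=list(bc.ids), columns=list(bc.ids)),
            "bray_curtis.tsv", index_label="sample_id",
        )
        pc = ordination.pcoa(bc)
        save_frame(pc.coordinates, "pcoa_coordinates.tsv", index_label="sample_id")
        m = meta.set_index("sample_id").loc[list(bc.ids)]
        tests = {}
        for factor in ("place", "bw_group"):
            tests[f"permanova_{factor}"] = ordination.permanova(
                bc, m[factor], config.n_permutations, seed
            ).to_dict()
            tests[f"anosim_{factor}"] = ordination.anosim(
                bc, m[factor], config.n_permutations, seed
            ).to_dict()
        bw_design = (m["bw_group"] == "HBW").astype(float).to_numpy()
        cres = ordination.cca(rel_genus, bw_design, config.n_permutations, seed)
        tests["cca_bw"] = {
            **cres.test.to_dict(),
            "constrained_fraction": cres.constrained_fraction,
        }
        write_json(tests, out / "ordination_tests.json")
        manifest["outputs"].append("ordination_tests.json")
        record("ordination", seed=seed)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("ordination", exc) from exc

    # ---- composition -----------------------------------------------------
    try:
        for rank, rel in (("phylum", rel_phylum), ("genus", rel_genus)):
            gmt = composition.group_mean_table(rel, meta)
            save_frame(gmt.to_frame(), f"group_means_{rank}.tsv", index_label="taxon")
            screen = composition.anova_screen(rel, meta, config)
            save_frame(screen.table, f"anova_screen_{rank}.tsv", index_label="taxon")
        ratio, ratio_groups = composition.bf_ratio(rel_phylum, meta)
        save_frame(ratio.to_frame(), "bf_ratio_samples.tsv", index_label="sample_id")
        save_frame(
            ratio_groups.to_frame().reset_index().set_index("place"),
            "bf_ratio_groups.tsv",
        )
        venn = composition.venn_unique_shared(rare, meta, by="place")
        venn_json = {
            "groups": list(venn.groups),
            "aggregate": venn.aggregate,
            "unique": venn.unique,
            "core": venn.core,
            "regions": {"+".join(sorted(k)): v for k, v in venn.regions.items()},
        }
        write_json(venn_json, out / "venn_places.json")
        manifest["outputs"].append("venn_places.json")
        record("composition")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("composition", exc) from exc

    # ---- trait screen ----------------------------------------------------
    try:
        screen = trait.bw_correlation_screen(rel_genus, meta, config)
        screen.to_csv(out / "bw_correlations.tsv", sep="\t", index=False,
                      float_format="%.10g")
        manifest["outputs"].append("bw_correlations.tsv")
        record("trait_screen")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("trait_screen", exc) from exc

    # ---- co-occurrence networks -----------------------------------------
    try:
        seed = _stage_seed(config.seed, "networks")
        summaries = {}
        places = list(dict.fromkeys(meta["place"]))
        for place in places:
            for grp in BW_GROUPS:
                key = f"{place}_{grp}"
                try:
                    net = coocnet.build_group_network(rel_genus, meta, place, grp, config)
                except ValueError as why:
                    summaries[key] = {"skipped": str(why)}
                    continue
                coocnet.mc_degree_significance(rel_genus, net, config.cooc_mc_reps, seed)
                coocnet.component_significance(rel_genus, net, config.cooc_mc_reps, seed)
                edge_name = f"network_{key}_edges.tsv"
                net.edge_frame().to_csv(out / edge_name, sep="\t", index=False,
                                        float_format="%.10g")
                nodes = pd.DataFrame(
                    {
                        "degree": pd.Series(net.degrees),
                        "mc_p": pd.Series(net.mc_degree_p),
                    }
                )
                node_name = f"network_{key}_nodes.tsv"
                nodes.to_csv(out / node_name, sep="\t", index_label="genus",
                             float_format="%.10g")
                manifest["outputs"] += [edge_name, node_name]
                _write_graphml(net, out / f"network_{key}.graphml")
                manifest["outputs"].append(f"network_{key}.graphml")
                summaries[key] = {
                    "n_nodes": len(net.nodes),
                    "n_edges": len(net.edges),
                    "components": [
                        {"nodes": list(c.nodes), "n_edges": c.n_edges, "p": c.p_value}
                        for c in net.components
                    ],
                }
        if {"JC", "JM"} <= set(places):
            for grp in BW_GROUPS:
                key = f"JCxJM_{grp}"
                try:
                    cross = coocnet.cross_compartment_network(
                        rel_genus, rel_genus, meta, grp, config,
                        mc_reps=config.cooc_mc_reps, seed=seed,
                    )
                except ValueError as why:
                    summaries[key] = {"skipped": str(why)}
                    continue
                name = f"network_{key}_edges.tsv"
                cross.edge_frame().to_csv(out / name, sep="\t", index=False,
                                          float_format="%.10g")
                manifest["outputs"].append(name)
                summaries[key] = {
                    "n_nodes_jc": len(cross.nodes_a),
                    "n_nodes_jm": len(cross.nodes_b),
                    "n_edges": len(cross.edges),
                    "out_degree": cross.out_degree,
                    "mc_out_p": cross.mc_out_p,
                }
        write_json(summaries, out / "network_summaries.json")
        manifest["outputs"].append("network_summaries.json")
        record("networks", seed=seed, mc_reps=config.cooc_mc_reps)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("networks", exc) from exc

    write_json(manifest, out / "manifest.json")
    return manifest


def _write_graphml(net, path):
    import networkx as nx

    g = net.to_graph()
    for node in g.nodes:
        g.nodes[node]["degree"] = net.degrees[node]
        if net.mc_degree_p:
            g.nodes[node]["mc_p"] = float(net.mc_degree_p[node])
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Report


def make_report(out_dir: str | Path) -> str:
    """Render a markdown summary of a completed run (written to report.md)."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {out}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# Gut microbiota analysis report",
        "",
        f"Pipeline version {manifest['version']}; seed {manifest['config']['seed']}.",
        "",
    ]

    alpha = pd.read_csv(out / "alpha_diversity.tsv", sep="\t", index_col=0)
    lines += ["## Alpha diversity (per-sample mean by index)", ""]
    lines.append(alpha.describe().loc[["mean", "std"]].round(3).to_markdown())
    lines.append("")

    tests = json.loads((out / "ordination_tests.json").read_text())
    lines += ["## Community-level tests", ""]
    for name, t in tests.items():
        lines.append(
            f"- {name}: statistic = {t['statistic']:.3f}, p = {t['p_value']:.4g} "
            f"({t['n_permutations']} permutations)"
        )
    lines.append("")

    for rank in ("phylum", "genus"):
        screen = pd.read_csv(out / f"anova_screen_{rank}.tsv", sep="\t", index_col=0)
        sig = screen[screen.filter(like="class_").eq("significant").any(axis=1)]
        lines += [
            f"## Two-way ANOVA screen ({rank})",
            "",
            f"{len(sig)} of {len(screen)} taxa significant (BH-FDR < 0.05) on "
            "at least one effect.",
            "",
        ]

    corr = pd.read_csv(out / "bw_correlations.tsv", sep="\t")
    hits = trait.significant_correlations(corr)
    lines += ["## Body-weight correlations (raw p < 0.05)", ""]
    if hits.empty:
        lines.append("No significant genus-body-weight correlations.")
    else:
        for r in hits.itertuples():
            lines.append(
                f"- {r.place} {r.genus}: rho = {r.rho:.2f}, p = {r.p_value:.3g}"
            )
    lines.append("")

    nets = json.loads((out / "network_summaries.json").read_text())
    lines += ["## Co-occurrence networks", ""]
    for key, summary in nets.items():
        lines.append(f"### {key}")
        if "skipped" in summary:
            lines.append(f"Skipped: {summary['skipped']}")
        elif "out_degree" in summary:
            lines.append(
                f"{summary['n_nodes_jc']} JC genera x {summary['n_nodes_jm']} JM "
                f"genera, {summary['n_edges']} bipartite edges."
            )
            if summary["mc_out_p"]:
                top = sorted(summary["mc_out_p"].items(), key=lambda kv: kv[1])[:3]
                for g, p in top:
                    lines.append(
                        f"- {g}: out-degree {summary['out_degree'][g]}, MC p = {p:.4g}"
                    )
        else:
            lines.append(
                f"{summary['n_nodes']} nodes, {summary['n_edges']} edges."
            )
            if not summary["n_edges"]:
                lines.append("No edges.")
            for c in summary["components"]:
                lines.append(
                    f"- component {'+'.join(c['nodes'])}: {c['n_edges']} edges, "
                    f"MC p = {c['p']:.4g}"
                )
        lines.append("")

    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
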