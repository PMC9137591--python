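"""Evaluation experiments: worked examples on published table cells,
type-I-error calibration of the permutation tests, and recovery of planted
synthetic structure.

These are the quantitative checks behind the package's validation suite;
every number is recomputed from scratch at call time.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from . import composition as comp
from . import network as nw
from . import ordination as ordn
from . import reference
from .io import Config
from .simulate import PlantedBlock, SyntheticDesign, genus_names, simulate_counts


def derive_seed(base_seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{base_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Worked examples from the published group-mean tables


def margin_worked_examples() -> pd.DataFrame:
    """Recompute every printed margin from its printed cells.

    Returns one row per (table, taxon, margin) with the recomputed balanced
    mean and the printed value. In the balanced design each margin is the
    arithmetic mean of its cells, so agreement is expected to the printed
    rounding (+/- 0.01).
    """
    rows = []
    for label, loader in (("phylum", reference.phylum_table),
                          ("genus", reference.genus_table)):
        cells, printed_sp, printed_bw = loader()
        mean_sp, mean_bw = comp.margins_from_cells(cells)
        for taxon in cells.index:
            for grp in printed_bw.columns:
                rows.append({
                    "table": label, "taxon": taxon, "margin": f"Mean(BW) {grp}",
                    "recomputed": mean_bw.loc[taxon, grp],
                    "printed": printed_bw.loc[taxon, grp],
                })
            for place in printed_sp.columns:
                rows.append({
                    "table": label, "taxon": taxon, "margin": f"Mean(SP) {place}",
                    "recomputed": mean_sp.loc[taxon, place],
                    "printed": printed_sp.loc[taxon, place],
                })
    out = pd.DataFrame(rows)
    out["abs_error"] = (out["recomputed"] - out["printed"]).abs()
    return out


def dominant_jc_phyla_sum() -> float:
    """Sum of the printed JC place-margin means of the four dominant phyla."""
    _, printed_sp, _ = reference.phylum_table()
    return float(printed_sp.loc[list(reference.DOMINANT_JC_PHYLA), "JC"].sum())


# ---------------------------------------------------------------------------
# Type-I-error calibration


def _null_distance_matrix(rng, n=12, f=20):
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix

    X = rng.random((n, f)) + 0.01
    X /= X.sum(axis=1, keepdims=True)
    D = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(D, ids=[f"s{i}" for i in range(n)])


def permutation_test_type1(method: str, n_sims: int = 1000, n_perm: int = 199,
                           seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of PERMANOVA or ANOSIM under an exchangeable null.

    Each simulation draws 12 random compositions, computes Bray-Curtis
    distances and tests a 6/6 split that is independent of the data.
    """
    fn = {"permanova": ordn.permanova, "anosim": ordn.anosim}[method]
    rng = np.random.default_rng(seed)
    labels = ["a"] * 6 + ["b"] * 6
    rejections = 0
    for sim in range(n_sims):
        dm = _null_distance_matrix(rng)
        res = fn(dm, labels, n_perm=n_perm, seed=derive_seed(seed, f"{method}{sim}"))
        rejections += res.p_value <= alpha
    return rejections / n_sims


def mc_degree_type1(n_tables: int = 200, B: int = 199, seed: int = 0,
                    alpha: float = 0.05) -> tuple:
    """Per-genus false-positive rate of the Monte Carlo degree test.

    Null tables come from the synthetic generator with no planted structure
    (the study-like conditions); returns ``(rate, n_tests)``.
    """
    cfg = Config()
    hits = total = 0
    for sim in range(n_tables):
        design = SyntheticDesign(seed=derive_seed(seed, f"nulltab{sim}"),
                                 places=("JM",))
        table, meta, _, _ = simulate_counts(design)
        rel = comp.to_relative(table)
        try:
            net = nw.build_group_network(rel, meta, "JM", "LBW", Config())
        except ValueError:
            continue
        p = nw.mc_degree_significance(rel, net, B=B,
                                      seed=derive_seed(seed, f"nullmc{sim}"))
        vals = np.array(list(p.values()))
        hits += (vals < alpha).sum()
        total += len(vals)
    return hits / total, total


# ---------------------------------------------------------------------------
# Recovery of planted structure


def block_recovery_rate(n_sims: int = 100, B: int = 1000, seed: int = 0,
                        n_members: int = 7, loading: float = 2.0) -> float:
    """Fraction of simulations in which a planted co-occurring block is
    recovered as one significant component (component p <= 0.05)."""
    cfg = Config()
    block = tuple(genus_names(40)[10:10 + n_members])
    recovered = 0
    for sim in range(n_sims):
        design = SyntheticDesign(
            seed=derive_seed(seed, f"block{sim}"), places=("JM",),
            planted_blocks=(PlantedBlock("JM", block, loading),),
        )
        table, meta, _, _ = simulate_counts(design)
        rel = comp.to_relative(table)
        try:
            net = nw.build_group_network(rel, meta, "JM", "LBW", cfg)
        except ValueError:
            continue
        nw.component_significance(rel, net, B=B,
                                  seed=derive_seed(seed, f"blockmc{sim}"))
        recovered += any(
            set(block) <= set(c.nodes) and c.p_value <= 0.05
            for c in net.components
        )
    return recovered / n_sims


def cross_driver_recovery_rate(n_sims: int = 100, seed: int = 0,
                               n_partners: int = 6, loading: float = 2.0) -> float:
    """Fraction of simulations in which a planted JC driver genus recovers
    bipartite out-degree >= 5 against its JM partner genera."""
    cfg = Config()
    partners = tuple(genus_names(40)[21:21 + n_partners])
    recovered = 0
    for sim in range(n_sims):
        design = SyntheticDesign(
            seed=derive_seed(seed, f"cross{sim}"), places=("JC", "JM"),
            planted_blocks=(
                PlantedBlock("JC", ("g021",), loading, factor="jc2jm"),
                PlantedBlock("JM", partners, loading, factor="jc2jm"),
            ),
        )
        table, meta, _, _ = simulate_counts(design)
        rel = comp.to_relative(table)
        try:
            net = nw.cross_compartment_network(rel, rel, meta, "LBW", cfg)
        except ValueError:
            continue
        recovered += net.out_degree.get("g021", 0) >= 5
    return recovered / n_sims


# ---------------------------------------------------------------------------
# Determinism


def pipeline_rerun_identical(out_dir, seed: int = 0) -> bool:
    """Run the full pipeline twice under one seed; True iff every output
    file is byte-identical."""
    from pathlib import Path

    from .pipeline import run_pipeline

    cfg = Config(seed=seed, n_permutations=99, cooc_mc_reps=199,
                 rarefaction_depth=5000)
    out = Path(out_dir)
    m1 = run_pipeline(cfg, out / "a", design=True)
    run_pipeline(cfg, out / "b", design=True)
    names = m1["outputs"] + ["manifest.json"]
    return all((out / "a" / n).read_bytes() == (out / "b" / n).read_bytes()
               for n in names)
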