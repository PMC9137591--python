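"""Synthetic gut-microbiota data generator.

Emulates the study design the downstream statistics assume: two body-weight
groups (LBW/HBW, selected beyond one standard deviation from the flock
mean), three gut compartments (jejunum chymus JC, jejunum mucosa JM, caecum
chymus CC), and five birds per group, each bird sampled once per
compartment.

Generative model
----------------
Per compartment, each genus g has a log-normal baseline abundance
``mu[g] ~ N(0, baseline_sigma^2)``; planted genera instead get a fixed
baseline ``planted_baseline`` placing them in the moderately-abundant,
reliably detected range the co-occurrence and trait screens operate on.
For a bird b, the log abundance is

    l[g, b] = mu[g] + eps[g, b] + sum_blocks loading * f[block, b]
              + ln(2) * beta[g] * z[b]

where ``eps ~ N(0, noise_sigma^2)`` is independent bird-level noise,
``f[block, b] ~ N(0, 1)`` is a latent factor shared by all genera of a
planted block (and, when two blocks name the same factor, across
compartments — the lumen-to-mucosa driver), ``beta[g]`` is a planted
log2-fold change per standard deviation of body weight, and ``z[b]`` is the
bird's standardised body weight. Relative abundances are the softmax of
``l``; counts are Dirichlet-multinomial: ``p ~ Dirichlet(rel * dispersion)``
then ``counts ~ Multinomial(depth, p)`` with the depth drawn uniformly from
``depth_range``.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` children, so identical designs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BW_GROUPS, PLACES, RANKS, CountTable, validate_metadata

_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")


class SelectionImpossibleError(RuntimeError):
    """The requested tail selection cannot be satisfied."""


def genus_names(n: int) -> list:
    return [f"g{i + 1:03d}" for i in range(n)]


@dataclass(frozen=True)
class PlantedBlock:
    """A set of genera in one compartment sharing a latent factor.

    ``factor`` defaults to a per-block key; give two blocks (possibly in
    different compartments) the same factor to correlate them with each
    other — the construction behind the JC-driver-to-JM-partners scenario.
    """

    place: str
    genera: tuple
    loading: float
    factor: str | None = None

    def factor_key(self) -> str:
        return self.factor or f"{self.place}:{'+'.join(self.genera)}"


@dataclass(frozen=True)
class PlantedBwEffect:
    """A log2-fold change per body-weight SD for one genus in one place."""

    place: str
    genus: str
    log2fc_per_sd: float


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic dataset.

    Defaults reproduce the emulated flock: mean body weight 2696 g,
    SD 227 g, five birds per group, three compartments.
    """

    n_birds_per_group: int = 5
    places: tuple = PLACES
    n_genera: int = 40
    depth_range: tuple = (12_000, 20_000)
    bw_population_mean_g: float = 2696.0
    bw_population_sd_g: float = 227.0
    n_population: int = 160
    planted_blocks: tuple = ()
    planted_bw_effects: tuple = ()
    dispersion: float = 5000.0
    baseline_sigma: float = 3.5
    noise_sigma: float = 0.15
    planted_baseline: float = 4.5
    seed: int = 0

    def __post_init__(self):
        self.places = tuple(self.places)
        self.depth_range = tuple(int(d) for d in self.depth_range)
        self.planted_blocks = tuple(
            b if isinstance(b, PlantedBlock) else PlantedBlock(*b)
            for b in self.planted_blocks
        )
        self.planted_bw_effects = tuple(
            e if isinstance(e, PlantedBwEffect) else PlantedBwEffect(*e)
            for e in self.planted_bw_effects
        )
        if self.n_birds_per_group < 3:
            raise ValueError("n_birds_per_group must be >= 3")
        if not self.places or len(set(self.places)) != len(self.places):
            raise ValueError("places must be non-empty and unique")
        if self.n_genera < 2:
            raise ValueError("n_genera must be >= 2")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range must be positive and ordered")
        if self.bw_population_sd_g <= 0:
            raise SelectionImpossibleError(
                "bw_population_sd_g must be > 0: with a degenerate weight "
                "distribution no bird lies beyond mean +/- SD"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        names = set(genus_names(self.n_genera))
        per_place: dict = {}
        for blk in self.planted_blocks:
            blk = dataclasses.replace(blk, genera=tuple(blk.genera))
            if blk.place not in self.places:
                raise ValueError(f"planted block in unknown place {blk.place!r}")
            if blk.loading < 0:
                raise ValueError("block loading must be >= 0")
            unknown = set(blk.genera) - names
            if unknown:
                raise ValueError(f"planted block names unknown genera {sorted(unknown)}")
            seen = per_place.setdefault(blk.place, set())
            overlap = seen & set(blk.genera)
            if overlap:
                raise ValueError(
                    f"planted blocks overlap in {blk.place}: {sorted(overlap)}"
                )
            seen |= set(blk.genera)
        for eff in self.planted_bw_effects:
            if eff.place not in self.places:
                raise ValueError(f"planted BW effect in unknown place {eff.place!r}")
            if eff.genus not in names:
                raise ValueError(f"planted BW effect on unknown genus {eff.genus!r}")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset, for power/FDR evaluation."""

    bird_weights: dict
    true_edges: dict  # place -> set of frozenset({genus_a, genus_b})
    true_cross_edges: set  # frozenset({(place_a, genus_a), (place_b, genus_b)})
    true_bw_genera: set  # (place, genus, sign)

    def to_json_dict(self) -> dict:
        return {
            "bird_weights": self.bird_weights,
            "true_edges": {
                place: sorted(sorted(pair) for pair in pairs)
                for place, pairs in self.true_edges.items()
            },
            "true_cross_edges": sorted(
                sorted(list(p) for p in pair) for pair in self.true_cross_edges
            ),
            "true_bw_genera": sorted(list(t) for t in self.true_bw_genera),
        }


# ---------------------------------------------------------------------------
# Body weights


def simulate_body_weights(
    n_population: int,
    mean: float,
    sd: float,
    n_low: int,
    n_high: int,
    seed,
    max_retries: int = 100,
):
    """Draw a flock and select birds from beyond one SD of the mean.

    Returns ``(low_weights, high_weights)``: ``n_low`` weights strictly below
    ``mean - sd`` and ``n_high`` strictly above ``mean + sd``, sampled at
    random from the respective tails. The flock is redrawn (bounded retries)
    if a tail is too small.
    """
    if sd <= 0:
        raise SelectionImpossibleError(
            "sd must be > 0: no bird can lie beyond mean +/- SD of a "
            "degenerate weight distribution"
        )
    if n_low + n_high > n_population:
        raise SelectionImpossibleError("more birds requested than in the flock")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        flock = rng.normal(mean, sd, size=n_population)
        low_tail = flock[flock < mean - sd]
        high_tail = flock[flock > mean + sd]
        if len(low_tail) >= n_low and len(high_tail) >= n_high:
            low = rng.choice(low_tail, size=n_low, replace=False)
            high = rng.choice(high_tail, size=n_high, replace=False)
            return np.sort(low), np.sort(high)
    raise SelectionImpossibleError(
        f"could not find {n_low} low / {n_high} high birds beyond one SD in "
        f"a flock of {n_population} after {max_retries} redraws"
    )


# ---------------------------------------------------------------------------
# Count tables


def _child_rng(master: np.random.SeedSequence, *key) -> np.random.Generator:
    # deterministic named child streams: stable (non-salted) hash of the key
    import hashlib

    digest = hashlib.sha256("/".join(str(k) for k in key).encode()).digest()
    h = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master.entropy, spawn_key=(h,))
    )


def simulate_counts(design: SyntheticDesign):
    """Simulate one dataset under ``design``.

    Returns ``(CountTable, metadata DataFrame, taxonomy DataFrame,
    SyntheticTruth)``. One sample per bird x compartment; sample ids are
    ``<bird>_<place>``.
    """
    master = np.random.SeedSequence(design.seed)
    n = design.n_birds_per_group
    genera = genus_names(design.n_genera)

    low, high = simulate_body_weights(
        design.n_population,
        design.bw_population_mean_g,
        design.bw_population_sd_g,
        n_low=n,
        n_high=n,
        seed=_child_rng(master, "weights"),
    )
    birds = [f"L{i + 1}" for i in range(n)] + [f"H{i + 1}" for i in range(n)]
    groups = ["LBW"] * n + ["HBW"] * n
    weights = dict(zip(birds, np.concatenate([low, high])))
    z = {
        b: (w - design.bw_population_mean_g) / design.bw_population_sd_g
        for b, w in weights.items()
    }

    planted_genera: dict = {place: set() for place in design.places}
    for blk in design.planted_blocks:
        planted_genera[blk.place] |= set(blk.genera)
    for eff in design.planted_bw_effects:
        planted_genera[eff.place].add(eff.genus)

    factors = sorted({blk.factor_key() for blk in design.planted_blocks})
    factor_rng = _child_rng(master, "factors")
    latent = {
        fac: dict(zip(birds, factor_rng.normal(size=len(birds)))) for fac in factors
    }

    beta = {place: np.zeros(design.n_genera) for place in design.places}
    gidx = {g: i for i, g in enumerate(genera)}
    for eff in design.planted_bw_effects:
        beta[eff.place][gidx[eff.genus]] += eff.log2fc_per_sd

    sample_ids, meta_rows = [], []
    columns = []
    for place in design.places:
        base_rng = _child_rng(master, "baseline", place)
        mu = base_rng.normal(0.0, design.baseline_sigma, size=design.n_genera)
        planted_idx = [gidx[g] for g in sorted(planted_genera[place])]
        mu[planted_idx] = design.planted_baseline
        place_blocks = [b for b in design.planted_blocks if b.place == place]
        for bird, group in zip(birds, groups):
            rng = _child_rng(master, "sample", place, bird)
            logab = mu + rng.normal(0.0, design.noise_sigma, size=design.n_genera)
            for blk in place_blocks:
                f = latent[blk.factor_key()][bird]
                for g in blk.genera:
                    logab[gidx[g]] += blk.loading * f
            logab = logab + np.log(2.0) * beta[place] * z[bird]
            rel = np.exp(logab - logab.max())
            rel /= rel.sum()
            p = rng.dirichlet(np.maximum(rel * design.dispersion, 1e-12))
            depth = int(rng.integers(design.depth_range[0], design.depth_range[1] + 1))
            counts = rng.multinomial(depth, p)
            sid = f"{bird}_{place}"
            sample_ids.append(sid)
            columns.append(counts)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "bird_id": bird,
                    "place": place,
                    "bw_group": group,
                    "body_weight_g": weights[bird],
                }
            )

    table = CountTable(np.column_stack(columns), genera, sample_ids)
    meta = validate_metadata(pd.DataFrame(meta_rows), source="synthetic metadata")

    tax_rng = _child_rng(master, "taxonomy")
    phyla = tax_rng.choice(_PHYLA, size=design.n_genera)
    tax = pd.DataFrame(
        {
            "kingdom": "Bacteria",
            "phylum": phyla,
            "class": [f"{p}_class" for p in phyla],
            "order": [f"{p}_order" for p in phyla],
            "family": [f"{p}_family" for p in phyla],
            "genus": genera,
            "species": "Unclassified",
        },
        index=genera,
    )[list(RANKS)]

    true_edges = {place: set() for place in design.places}
    for blk in design.planted_blocks:
        if blk.loading > 0:
            for i, a in enumerate(blk.genera):
                for b in blk.genera[i + 1 :]:
                    true_edges[blk.place].add(frozenset((a, b)))
    true_cross = set()
    by_factor: dict = {}
    for blk in design.planted_blocks:
        if blk.loading > 0:
            by_factor.setdefault(blk.factor_key(), []).append(blk)
    for blocks in by_factor.values():
        for i, ba in enumerate(blocks):
            for bb in blocks[i + 1 :]:
                if ba.place != bb.place:
                    for ga in ba.genera:
                        for gb in bb.genera:
                            true_cross.add(
                                frozenset(((ba.place, ga), (bb.place, gb)))
                            )
    true_bw = {
        (e.place, e.genus, 1 if e.log2fc_per_sd > 0 else -1)
        for e in design.planted_bw_effects
        if e.log2fc_per_sd != 0
    }
    truth = SyntheticTruth(weights, true_edges, true_cross, true_bw)
    return table, meta, tax, truth


# ---------------------------------------------------------------------------
# Trees


def simulate_tree(n_taxa: int, seed, taxa=None, star: bool = False) -> str:
    """Random rooted binary tree over ``taxa`` (default ``g001..``) as Newick.

    With ``star=True``, a star-like tree with unit branch lengths instead
    (total branch length equals the number of leaves).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    taxa = list(taxa) if taxa is not None else genus_names(n_taxa)
    if len(taxa) != n_taxa:
        raise ValueError("len(taxa) must equal n_taxa")
    if star:
        return "(" + ",".join(f"{t}:1.0" for t in taxa) + ");"
    rng = np.random.default_rng(seed)
    nodes = [f"{t}:{rng.exponential(0.1) + 0.01:.6f}" for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = rng.exponential(0.1) + 0.01
        merged = f"({nodes[i]},{nodes[j]}):{b:.6f}"
        nodes = [n_ for k, n_ in enumerate(nodes) if k not in (i, j)] + [merged]
    # strip the root's branch length
    root = nodes[0]
    root = root[: root.rfind(":")]
    return root + ";"


# ---------------------------------------------------------------------------
# Default study-like design


def default_design(seed: int = 0) -> SyntheticDesign:
    """The demonstration design used by the pipeline's simulate mode.

    Plants one six-genus co-occurring block in the JC, one seven-genus block
    in the JM, a JC driver genus sharing a factor with six JM partner genera
    (the lumen-to-mucosa scenario), and body-weight effects in each
    compartment, all at effect sizes large enough for the screens to have
    power at n = 5 birds per group.
    """
    g = genus_names(40)
    return SyntheticDesign(
        planted_blocks=(
            PlantedBlock("JC", tuple(g[0:6]), 2.0),
            PlantedBlock("JM", tuple(g[10:17]), 2.0),
            PlantedBlock("JC", ("g021",), 2.0, factor="jc2jm"),
            PlantedBlock("JM", tuple(g[21:27]), 2.0, factor="jc2jm"),
        ),
        planted_bw_effects=(
            PlantedBwEffect("JC", "g031", 1.0),
            PlantedBwEffect("JM", "g032", 1.0),
            PlantedBwEffect("JM", "g033", -1.0),
            PlantedBwEffect("CC", "g034", -1.0),
            PlantedBwEffect("CC", "g035", -1.0),
        ),
        seed=seed,
    )
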