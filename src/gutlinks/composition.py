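"""Taxonomic aggregation, relative abundance, group-mean tables, the
Bacteroidetes/Firmicutes ratio, two-way ANOVA screening with BH-FDR, and
unique/shared feature accounting.

The screening follows the study design: a balanced two-factor layout with
sampling place (JC/JM/CC) and body-weight group (LBW/HBW) as fixed main
factors, per-taxon two-way ANOVA with Tukey HSD post hoc comparisons,
Benjamini-Hochberg FDR across taxa separately per effect, and a "trend"
class for FDR p in the 0.05-0.10 band. ANOVA runs on untransformed relative
abundances by default (an arcsine-square-root option exists); with equal
cell sizes the balanced decomposition used here coincides with Type-I/II
sums of squares.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import RANKS, UNCLASSIFIED, Config, CountTable, taxonomy_for

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Aggregation and relative abundance


def aggregate_to_rank(table: CountTable, tax: pd.DataFrame, rank: str) -> CountTable:
    """Sum features sharing a label at ``rank``; unmapped features pool
    under ``Unclassified``."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    labels = taxonomy_for(tax, table.feature_ids)[rank].tolist()
    frame = table.to_frame()
    frame.index = labels
    agg = frame.groupby(level=0, sort=False).sum()
    # keep first-appearance order but put Unclassified last for readability
    order = [t for t in agg.index if t != UNCLASSIFIED]
    if UNCLASSIFIED in agg.index:
        order.append(UNCLASSIFIED)
    return CountTable.from_frame(agg.loc[order])


def to_relative(table) -> pd.DataFrame:
    """Percent relative abundance per sample (columns sum to 100)."""
    frame = table.to_frame() if isinstance(table, CountTable) else pd.DataFrame(table)
    sums = frame.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive total")
    return frame / sums * 100.0


# ---------------------------------------------------------------------------
# Group-mean tables (the published table layout)


@dataclass
class GroupMeanTable:
    """Cell means and balanced margins of a taxon x (place, bw_group) layout.

    ``cells``: taxa x MultiIndex(place, bw_group) mean percent abundances;
    ``mean_sp``: margin over bw groups per place; ``mean_bw``: margin over
    places per bw group. In the balanced design both margins are arithmetic
    means of their cells.
    """

    cells: pd.DataFrame
    mean_sp: pd.DataFrame
    mean_bw: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        flat = self.cells.copy()
        flat.columns = [f"{p}:{g}" for p, g in flat.columns]
        for p in self.mean_sp.columns:
            flat[f"Mean(SP):{p}"] = self.mean_sp[p]
        for g in self.mean_bw.columns:
            flat[f"Mean(BW):{g}"] = self.mean_bw[g]
        return flat


def group_mean_table(rel: pd.DataFrame, meta: pd.DataFrame) -> GroupMeanTable:
    """Mean percent abundance per (place, bw_group) cell plus balanced margins."""
    places = list(dict.fromkeys(meta["place"]))
    groups = list(dict.fromkeys(meta["bw_group"]))
    cols = {}
    for place in places:
        for grp in groups:
            samples = meta.loc[
                (meta["place"] == place) & (meta["bw_group"] == grp), "sample_id"
            ]
            if samples.empty:
                raise ValueError(f"empty design cell ({place}, {grp})")
            cols[(place, grp)] = rel[list(samples)].mean(axis=1)
    cells = pd.DataFrame(cols)
    cells.columns = pd.MultiIndex.from_tuples(cells.columns, names=["place", "bw_group"])
    mean_sp = cells.T.groupby(level="place", sort=False).mean().T
    mean_bw = cells.T.groupby(level="bw_group", sort=False).mean().T
    return GroupMeanTable(cells, mean_sp, mean_bw)


def margins_from_cells(cells: pd.DataFrame) -> tuple:
    """Recompute balanced margins from a cells frame (same layout as above)."""
    mean_sp = cells.T.groupby(level="place", sort=False).mean().T
    mean_bw = cells.T.groupby(level="bw_group", sort=False).mean().T
    return mean_sp, mean_bw


def bf_ratio(rel_phylum: pd.DataFrame, meta: pd.DataFrame | None = None):
    """Bacteroidetes/Firmicutes ratio per sample (and group means).

    Samples with zero Firmicutes are undefined and excluded with a warning;
    absent Bacteroidetes gives ratio 0. Group values are means of the
    per-sample ratios, not ratios of group means.
    """
    bact = (
        rel_phylum.loc["Bacteroidetes"]
        if "Bacteroidetes" in rel_phylum.index
        else pd.Series(0.0, index=rel_phylum.columns)
    )
    if "Firmicutes" not in rel_phylum.index:
        raise ValueError("Firmicutes row absent; B/F ratio undefined everywhere")
    firm = rel_phylum.loc["Firmicutes"]
    defined = firm > 0
    if not defined.all():
        log.warning(
            "bf_ratio: %d sample(s) with zero Firmicutes excluded",
            int((~defined).sum()),
        )
    ratio = (bact[defined] / firm[defined]).rename("bf_ratio")
    if meta is None:
        return ratio
    m = meta.set_index("sample_id").loc[ratio.index]
    group_means = ratio.groupby([m["place"], m["bw_group"]]).mean()
    return ratio, group_means


# ---------------------------------------------------------------------------
# Two-way ANOVA machinery (balanced design, vectorised across taxa)


def twoway_anova_balanced(Y: np.ndarray, codes_a: np.ndarray, codes_b: np.ndarray):
    """Balanced two-way fixed-effects ANOVA for many response rows at once.

    ``Y`` is (n_taxa x n_samples); ``codes_a``/``codes_b`` integer factor
    codes per sample. Returns a dict of arrays: F and p for factor A, factor
    B and the interaction, plus the error mean square and its df. Rows with
    zero residual variance get NaN statistics.
    """
    a = codes_a.max() + 1
    b = codes_b.max() + 1
    n_samples = Y.shape[1]
    cell = codes_a * b + codes_b
    counts = np.bincount(cell, minlength=a * b)
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per design cell")
    if np.ptp(counts) != 0:
        raise ValueError("design must be balanced")
    n = counts[0]

    grand = Y.mean(axis=1, keepdims=True)

    def level_means(codes, k):
        M = np.zeros((Y.shape[0], k))
        for lev in range(k):
            M[:, lev] = Y[:, codes == lev].mean(axis=1)
        return M

    mA = level_means(codes_a, a)
    mB = level_means(codes_b, b)
    mC = level_means(cell, a * b)

    ss_a = b * n * ((mA - grand) ** 2).sum(axis=1)
    ss_b = a * n * ((mB - grand) ** 2).sum(axis=1)
    ss_cells = n * ((mC - grand) ** 2).sum(axis=1)
    ss_ab = ss_cells - ss_a - ss_b
    resid = Y - mC[:, cell]
    ss_e = (resid**2).sum(axis=1)

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = n_samples - a * b
    mse = ss_e / df_e

    with np.errstate(divide="ignore", invalid="ignore"):
        f_a = (ss_a / df_a) / mse
        f_b = (ss_b / df_b) / mse
        f_ab = (ss_ab / df_ab) / mse
    bad = mse <= 0
    for f in (f_a, f_b, f_ab):
        f[bad] = np.nan
    return {
        "F_a": f_a,
        "p_a": stats.f.sf(f_a, df_a, df_e),
        "F_b": f_b,
        "p_b": stats.f.sf(f_b, df_b, df_e),
        "F_ab": f_ab,
        "p_ab": stats.f.sf(f_ab, df_ab, df_e),
        "mse": mse,
        "df_e": df_e,
    }


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through unadjusted."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def tukey_hsd(means, n_per_level, mse: float, df_error: int) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons from level means and an error MS.

    ``means`` is a mapping level -> mean based on ``n_per_level``
    observations each; the p-value is the studentized-range tail
    ``Q.sf(q, k, df_error)`` with ``q = |m_i - m_j| / sqrt(MSE / n)``.
    """
    levels = list(means)
    k = len(levels)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[levels[i]] - means[levels[j]]
        se = np.sqrt(mse / n_per_level)
        q = np.abs(diff) / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(q, k, df_error)) if np.isfinite(q) else 0.0
        rows.append(
            {
                "level_a": levels[i],
                "level_b": levels[j],
                "meandiff": diff,
                "q": q,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def compact_letters(levels, nonsig_pairs) -> dict:
    """Compact letter display: levels sharing a letter are not separable.

    ``nonsig_pairs`` is an iterable of unordered level pairs that were NOT
    significantly different. Letters are the maximal cliques of the
    non-significance graph, ordered by first member.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(levels)
    g.add_edges_from(nonsig_pairs)
    cliques = sorted(
        (sorted(c, key=list(levels).index) for c in nx.find_cliques(g)),
        key=lambda c: list(levels).index(c[0]),
    )
    letters = {lev: "" for lev in levels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for lev in clique:
            letters[lev] += letter
    return letters


@dataclass
class AnovaScreenResult:
    """Per-taxon screening output.

    ``table`` columns: raw p per effect (``p_sp``, ``p_bw``, ``p_int``),
    BH-FDR adjusted (``q_*``), significance class per effect, within-place
    one-way body-weight p-values (``p_bw_in_<place>``), and Tukey letters
    for the place factor (``letters_sp``).
    """

    table: pd.DataFrame
    alpha: float
    trend_band: tuple


def _classify(q: float, alpha: float, band) -> str:
    if np.isnan(q):
        return "na"
    if q < alpha:
        return "significant"
    if band[0] <= q <= band[1]:
        return "trend"
    return "ns"


def anova_screen(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    config: Config | None = None,
    arcsine: bool = False,
    compute_letters: bool = True,
) -> AnovaScreenResult:
    """Two-factor compositional screen over all taxa.

    Per taxon: two-way ANOVA (place x bw_group), BH-FDR across taxa per
    effect, Tukey HSD letters on places (pooled error from the two-way
    model), and one-way body-weight ANOVA within each place. Constant taxa
    are reported with missing p-values and excluded from the FDR families.
    """
    config = config or Config()
    meta = meta.set_index("sample_id").loc[list(rel.columns)].reset_index()
    places = list(dict.fromkeys(meta["place"]))
    groups = list(dict.fromkeys(meta["bw_group"]))
    codes_a = np.array([places.index(p) for p in meta["place"]])
    codes_b = np.array([groups.index(g) for g in meta["bw_group"]])
    Y = rel.to_numpy(dtype=float)
    if arcsine:
        Y = np.arcsin(np.sqrt(np.clip(Y / 100.0, 0, 1)))

    res = twoway_anova_balanced(Y, codes_a, codes_b)
    out = pd.DataFrame(
        {
            "F_sp": res["F_a"],
            "p_sp": res["p_a"],
            "F_bw": res["F_b"],
            "p_bw": res["p_b"],
            "F_int": res["F_ab"],
            "p_int": res["p_ab"],
        },
        index=rel.index,
    )
    for eff in ("sp", "bw", "int"):
        out[f"q_{eff}"] = bh_fdr(out[f"p_{eff}"])
        out[f"class_{eff}"] = [
            _classify(q, config.alpha, config.trend_band) for q in out[f"q_{eff}"]
        ]
    n_na = int(out["p_sp"].isna().sum())
    if n_na:
        log.info("anova_screen: %d constant taxa excluded from the FDR families", n_na)

    # one-way BW ANOVA within each place
    for place in places:
        mask = meta["place"] == place
        cols = meta.loc[mask, "sample_id"]
        gcodes = meta.loc[mask, "bw_group"].to_numpy()
        sub = rel[list(cols)].to_numpy(dtype=float)
        if arcsine:
            sub = np.arcsin(np.sqrt(np.clip(sub / 100.0, 0, 1)))
        pvals = np.full(sub.shape[0], np.nan)
        for i in range(sub.shape[0]):
            samples = [sub[i, gcodes == g] for g in groups]
            if all(np.ptp(s) == 0 for s in samples) and np.ptp(sub[i]) == 0:
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                pvals[i] = stats.f_oneway(*samples).pvalue
        out[f"p_bw_in_{place}"] = pvals

    if compute_letters:
        n_per_place = int((codes_a == 0).sum())
        letters = []
        for i, taxon in enumerate(rel.index):
            if np.isnan(res["p_a"][i]):
                letters.append("")
                continue
            means = {p: Y[i, codes_a == k].mean() for k, p in enumerate(places)}
            pairs = tukey_hsd(means, n_per_place, res["mse"][i], res["df_e"])
            nonsig = [
                (r.level_a, r.level_b)
                for r in pairs.itertuples()
                if r.p >= config.alpha
            ]
            ordered = sorted(places, key=lambda p: -means[p])
            letters.append(
                "/".join(f"{p}:{compact_letters(ordered, nonsig)[p]}" for p in places)
            )
        out["letters_sp"] = letters

    return AnovaScreenResult(out, config.alpha, config.trend_band)


# ---------------------------------------------------------------------------
# Unique / shared feature accounting


@dataclass
class VennSummary:
    """Region counts of the presence/absence Venn over groups.

    ``regions`` maps a frozenset of group labels to the number of features
    present in exactly those groups (absent elsewhere); ``aggregate`` is the
    per-group total presence count; ``unique`` the per-group exclusive
    count; ``core`` the number present in every group.
    """

    groups: tuple
    regions: dict
    aggregate: dict
    unique: dict
    core: int


def venn_unique_shared(table: CountTable, meta: pd.DataFrame, by: str = "place") -> VennSummary:
    """Set algebra on feature presence (count >= 1 in any sample of a group)."""
    if by not in meta.columns:
        raise ValueError(f"unknown grouping column {by!r}")
    labels = list(dict.fromkeys(meta[by]))
    if not labels:
        raise ValueError("grouping is empty")
    present = {}
    for lab in labels:
        cols = [table.sample_ids.index(s) for s in meta.loc[meta[by] == lab, "sample_id"]]
        mask = table.counts[:, cols].sum(axis=1) > 0
        present[lab] = {f for f, m in zip(table.feature_ids, mask) if m}
    regions = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(present[l] for l in combo))
            outside = set.union(
                *(present[l] for l in labels if l not in combo), set()
            )
            regions[frozenset(combo)] = len(inside - outside)
    aggregate = {l: len(present[l]) for l in labels}
    unique = {l: regions[frozenset((l,))] for l in labels}
    core = len(set.intersection(*present.values()))
    return VennSummary(tuple(labels), regions, aggregate, unique, core)
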