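"""Feature filtering, rarefaction and alpha-diversity indices.

Indices follow the conventions of the upstream ecology toolkits: observed
richness, bias-corrected Chao1, Shannon entropy (base 2 by default — the
scale on which a ~360-OTU caecal sample scores ~6), Simpson's index
``1 - sum(p^2)``, and Faith's phylogenetic diversity (total branch length of
the minimal rooted subtree spanning the observed leaves).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import CountTable

log = logging.getLogger(__name__)


class RarefactionError(ValueError):
    """No sample reaches the requested rarefaction depth."""


def filter_low_abundance(table: CountTable, min_total: int) -> CountTable:
    """Drop features whose total count across all samples is < ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.feature_sums() >= min_total
    return CountTable(
        table.counts[keep],
        [f for f, k in zip(table.feature_ids, keep) if k],
        table.sample_ids,
    )


def rarefy(table: CountTable, depth: int, seed) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (logged).
    Raises :class:`RarefactionError` if no sample survives.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    kept_cols, kept_ids = [], []
    for j, sid in enumerate(table.sample_ids):
        if sums[j] < depth:
            log.warning(
                "rarefy: dropping sample %s (total %d < depth %d)", sid, sums[j], depth
            )
            continue
        kept_cols.append(rng.multivariate_hypergeometric(table.counts[:, j], depth))
        kept_ids.append(sid)
    if not kept_ids:
        raise RarefactionError(f"all samples have fewer than {depth} reads")
    return CountTable(np.column_stack(kept_cols), table.feature_ids, kept_ids)


# ---------------------------------------------------------------------------
# Alpha diversity


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1: ``S_obs + F1(F1-1) / (2(F2+1))``."""
    counts = np.asarray(counts)
    s_obs = int(np.count_nonzero(counts))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts: np.ndarray, base: float = 2.0) -> float:
    counts = np.asarray(counts, dtype=float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def simpson(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    return float(1.0 - (p**2).sum())


def faith_pd(counts: np.ndarray, feature_ids, tree) -> float:
    """Faith's PD: total branch length of the minimal rooted subtree
    spanning the observed leaves (the root is included, so a single observed
    leaf contributes its full root-to-tip path).

    ``tree`` is an skbio TreeNode (rooted; multifurcations allowed).
    """
    counts = np.asarray(counts)
    observed = {f for f, c in zip(feature_ids, counts) if c > 0}
    tips = {t.name for t in tree.tips()}
    missing = observed - tips
    if missing:
        raise ValueError(f"tree is missing observed features: {sorted(missing)}")
    total = 0.0
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} if node.children else {node.name}
        if leaves & observed:
            total += node.length or 0.0
    return float(total)


def alpha_diversity(table: CountTable, tree=None, log_base: float = 2.0) -> pd.DataFrame:
    """Per-sample alpha-diversity table.

    Columns: ``observed_features, chao1, shannon, simpson`` and, when a
    rooted tree covering the features is given, ``faith_pd``. Empty samples
    get missing values with a warning.
    """
    if table.n_features == 0 or table.n_samples == 0:
        raise ValueError("empty count table")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        if col.sum() == 0:
            log.warning("alpha_diversity: sample %s is empty; indices undefined", sid)
            row = {
                "observed_features": 0,
                "chao1": np.nan,
                "shannon": np.nan,
                "simpson": np.nan,
            }
            if tree is not None:
                row["faith_pd"] = np.nan
            rows.append(row)
            continue
        row = {
            "observed_features": int(np.count_nonzero(col)),
            "chao1": chao1(col),
            "shannon": shannon(col, base=log_base),
            "simpson": simpson(col),
        }
        if tree is not None:
            row["faith_pd"] = faith_pd(col, table.feature_ids, tree)
        rows.append(row)
    return pd.DataFrame(rows, index=table.sample_ids)


def rarefaction_curve(
    table: CountTable, depths, reps: int = 10, seed=0
) -> pd.DataFrame:
    """Mean observed-feature count per sample at each subsampling depth.

    Depths exceeding a sample's total are reported as missing for that
    sample. Returns a (sample x depth) DataFrame of means over ``reps``
    independent subsamples.
    """
    depths = list(depths)
    if sorted(depths) != depths:
        raise ValueError("depths must be ascending")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    out = np.full((table.n_samples, len(depths)), np.nan)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        for k, depth in enumerate(depths):
            if depth > sums[j]:
                continue
            obs = [
                np.count_nonzero(rng.multivariate_hypergeometric(col, depth))
                for _ in range(reps)
            ]
            out[j, k] = float(np.mean(obs))
    return pd.DataFrame(out, index=table.sample_ids, columns=depths)
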