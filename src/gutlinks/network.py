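"""Co-occurrence networks of genera within and across gut compartments.

The procedure mirrors the study's: within each sampling-place x body-weight
group (five birds), genera non-zero in at least four of the five samples are
kept; Spearman's rho is computed for every genus pair; pairs with |rho| at
or beyond a descriptive threshold (default 0.9) become edges. At n = 5 only
|rho| = 1 reaches two-sided exact significance, so individual edges are not
tested — instead the *number of connections* of each genus, and the edge
count of each connected component, are tested by Monte Carlo: null tables
permute every genus's abundance vector independently across the group's
samples (marginals preserved, all cross-genus association destroyed), the
network is rebuilt per replicate, and ``p = (#{null >= observed} + 1) /
(B + 1)``.

The lumen-to-mucosa variant correlates every jejunum-chymus genus with every
jejunum-mucosa genus across the same five birds (bipartite network) and
tests each chymus genus's out-degree with the same null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from .io import Config

_MAX_EXACT_N = 10


# ---------------------------------------------------------------------------
# Exact small-n Spearman


@dataclass
class SpearmanResult:
    rho: float
    one_sided_p: float
    two_sided_p: float
    n: int
    method: str  # "exact", "asymptotic" or "undefined"


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    return float((rxc * ryc).sum() / denom)


def exact_spearman(x, y, method: str = "auto", max_exact_n: int = 8) -> SpearmanResult:
    """Spearman's rho with an exact permutation p at small n.

    Rho uses average ranks. For ``n <= max_exact_n`` (exact regime,
    enumeration of all n! orderings of one vector — ties are permuted with
    their values, so the null conditions on the observed tie pattern) the p
    is exact; longer vectors fall back to the t approximation. ``method``
    may force ``"exact"`` (allowed up to n = 10) or ``"asymptotic"``.
    A constant vector leaves rho undefined (NaN, method ``"undefined"``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(np.nan, np.nan, np.nan, n, "undefined")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _rank_rho(rx, ry)

    if method == "auto":
        method = "exact" if n <= max_exact_n else "asymptotic"
    if method == "exact" and n > _MAX_EXACT_N:
        raise ValueError(f"exact enumeration supported only for n <= {_MAX_EXACT_N}")

    if method == "asymptotic":
        t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        from scipy.stats import t as tdist

        one = float(tdist.sf(abs(t), n - 2))
        return SpearmanResult(rho, one, min(1.0, 2 * one), n, "asymptotic")

    rxc = rx - rx.mean()
    norm = np.sqrt((rxc**2).sum() * ((ry - ry.mean()) ** 2).sum())
    tol = 1e-12
    ge = le = abs_ge = 0
    total = 0
    perms = itertools.permutations(ry)
    chunk_size = 40320 * 5
    while True:
        chunk = np.array(list(itertools.islice(perms, chunk_size)))
        if chunk.size == 0:
            break
        rhos = (chunk - ry.mean()) @ rxc / norm
        ge += int(np.sum(rhos >= rho - tol))
        le += int(np.sum(rhos <= rho + tol))
        abs_ge += int(np.sum(np.abs(rhos) >= abs(rho) - tol))
        total += len(rhos)
    one = (ge if rho >= 0 else le) / total
    return SpearmanResult(rho, one, min(1.0, abs_ge / total), n, "exact")


# ---------------------------------------------------------------------------
# Rank machinery shared by the network builders


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.vstack([rankdata(row) for row in X])


def _normalized_ranks(R: np.ndarray) -> np.ndarray:
    """Center and L2-normalise rank rows; constant rows become zero."""
    Z = R - R.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(norms > 0, Z / norms, 0.0)
    return Z


def _adjacency(C: np.ndarray, threshold: float, allow_negative: bool) -> np.ndarray:
    adj = C >= threshold - 1e-12
    if allow_negative:
        adj |= C <= -(threshold - 1e-12)
    if adj.ndim == 2:
        np.fill_diagonal(adj, False)
    else:
        idx = np.arange(adj.shape[1])
        adj[:, idx, idx] = False
    return adj


def _null_adjacencies(R: np.ndarray, threshold: float, allow_negative: bool, B: int, rng):
    """Stack of B null adjacency matrices from per-row rank permutations."""
    G, n = R.shape
    keys = rng.random((B, G, n))
    perm = np.argsort(keys, axis=2)
    P = np.take_along_axis(np.broadcast_to(R, (B, G, n)), perm, axis=2)
    mean = R.mean(axis=1)[None, :, None]
    norms = np.linalg.norm(R - R.mean(axis=1, keepdims=True), axis=1)
    Z = P - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(norms[None, :, None] > 0, Z / norms[None, :, None], 0.0)
    C = Z @ Z.transpose(0, 2, 1)
    return _adjacency(C, threshold, allow_negative)


def _component_edge_counts(adj: np.ndarray):
    """(labels, edges-per-component) for one boolean adjacency matrix."""
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    ii, _ = np.nonzero(np.triu(adj, 1))
    counts = np.bincount(labels[ii], minlength=n_comp).astype(float)
    return labels, counts


# ---------------------------------------------------------------------------
# Within-group networks


@dataclass
class Edge:
    a: str
    b: str
    rho: float
    exact_p: float
    sign: int


@dataclass
class Component:
    nodes: tuple
    n_edges: int
    p_value: float | None = None


@dataclass
class GroupNetwork:
    place: str
    bw_group: str
    nodes: list
    edges: list
    degrees: dict
    threshold: float
    allow_negative: bool
    sample_ids: list
    mc_degree_p: dict | None = None
    components: list = field(default_factory=list)
    mc_reps: int | None = None
    seed: int | None = None

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.a, e.b, rho=e.rho, exact_p=e.exact_p, sign=e.sign)
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.a, e.b, e.rho, e.exact_p, e.sign) for e in self.edges],
            columns=["genus_a", "genus_b", "rho", "exact_p", "sign"],
        )


def prevalence_filter_group(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    place: str,
    bw_group: str,
    min_present: int,
) -> list:
    """Genera non-zero in at least ``min_present`` of the group's samples."""
    samples = meta.loc[
        (meta["place"] == place) & (meta["bw_group"] == bw_group), "sample_id"
    ]
    if len(samples) < min_present:
        raise ValueError(
            f"group ({place}, {bw_group}) has {len(samples)} samples, fewer than "
            f"min_present={min_present}"
        )
    sub = rel[list(samples)]
    keep = (sub.to_numpy() > 0).sum(axis=1) >= min_present
    return [g for g, k in zip(rel.index, keep) if k]


def _group_samples(meta: pd.DataFrame, place: str, bw_group: str) -> list:
    sub = meta[(meta["place"] == place) & (meta["bw_group"] == bw_group)]
    return list(sub.sort_values("bird_id")["sample_id"])


def build_group_network(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    place: str,
    bw_group: str,
    config: Config | None = None,
    allow_negative: bool = True,
) -> GroupNetwork:
    """Build one group's co-occurrence network (no significance yet)."""
    config = config or Config()
    genera = prevalence_filter_group(
        rel, meta, place, bw_group, config.cooc_prevalence_min
    )
    if len(genera) < 2:
        raise ValueError(
            f"fewer than 2 genera pass the prevalence filter in ({place}, {bw_group})"
        )
    samples = _group_samples(meta, place, bw_group)
    X = rel.loc[genera, samples].to_numpy(dtype=float)
    R = _rank_rows(X)
    Z = _normalized_ranks(R)
    C = Z @ Z.T
    adj = _adjacency(C, config.cooc_edge_rho_min, allow_negative)
    edges = []
    for i, j in zip(*np.nonzero(np.triu(adj, 1))):
        res = exact_spearman(X[i], X[j])
        edges.append(
            Edge(genera[i], genera[j], float(C[i, j]), res.two_sided_p,
                 1 if C[i, j] > 0 else -1)
        )
    degrees = {g: 0 for g in genera}
    for e in edges:
        degrees[e.a] += 1
        degrees[e.b] += 1
    net = GroupNetwork(
        place=place,
        bw_group=bw_group,
        nodes=genera,
        edges=edges,
        degrees=degrees,
        threshold=config.cooc_edge_rho_min,
        allow_negative=allow_negative,
        sample_ids=samples,
    )
    labels, counts = _component_edge_counts(adj)
    for comp in range(counts.shape[0] if len(edges) else 0):
        members = tuple(genera[i] for i in np.nonzero(labels == comp)[0])
        if len(members) >= 2 and counts[comp] > 0:
            net.components.append(Component(members, int(counts[comp])))
    return net


def _group_rank_matrix(rel: pd.DataFrame, network: GroupNetwork) -> np.ndarray:
    X = rel.loc[network.nodes, network.sample_ids].to_numpy(dtype=float)
    return _rank_rows(X)


def mc_degree_significance(
    rel: pd.DataFrame, network: GroupNetwork, B: int = 1000, seed=0
) -> dict:
    """Monte Carlo p for each genus's connection count.

    Null tables permute every genus's vector independently; the network is
    rebuilt per replicate with the same threshold; ``p_g = (#{null degree of
    g >= observed} + 1) / (B + 1)``. Updates ``network.mc_degree_p``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    R = _group_rank_matrix(rel, network)
    obs = np.array([network.degrees[g] for g in network.nodes])
    adj = _null_adjacencies(R, network.threshold, network.allow_negative, B, rng)
    null_deg = adj.sum(axis=2)  # B x G
    exceed = (null_deg >= obs[None, :]).sum(axis=0)
    p = (exceed + 1) / (B + 1)
    network.mc_degree_p = dict(zip(network.nodes, p.astype(float)))
    network.mc_reps = B
    network.seed = seed
    return network.mc_degree_p


def component_significance(
    rel: pd.DataFrame, network: GroupNetwork, B: int = 1000, seed=0
) -> list:
    """Monte Carlo p per connected component.

    Statistic: edge count within the component. Null distribution: the
    *maximum* component edge count of each fully permuted replicate network,
    so one comparison covers the whole network's strongest community.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    R = _group_rank_matrix(rel, network)
    adj = _null_adjacencies(R, network.threshold, network.allow_negative, B, rng)
    null_max = np.zeros(B)
    for b in range(B):
        _, counts = _component_edge_counts(adj[b])
        null_max[b] = counts.max() if counts.size else 0.0
    for comp in network.components:
        comp.p_value = float((np.sum(null_max >= comp.n_edges) + 1) / (B + 1))
    network.mc_reps = B
    network.seed = seed
    return network.components


# ---------------------------------------------------------------------------
# Cross-compartment (lumen <-> mucosa) bipartite networks


@dataclass
class CrossEdge:
    genus_a: str  # source compartment (e.g. JC)
    genus_b: str  # target compartment (e.g. JM)
    rho: float
    exact_p: float
    sign: int


@dataclass
class CrossNetwork:
    bw_group: str
    place_a: str
    place_b: str
    nodes_a: list
    nodes_b: list
    edges: list
    out_degree: dict
    threshold: float
    allow_negative: bool
    birds: list
    mc_out_p: dict | None = None
    mc_reps: int | None = None
    seed: int | None = None

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.place_a, e.genus_a, self.place_b, e.genus_b, e.rho, e.exact_p, e.sign)
                for e in self.edges
            ],
            columns=["place_a", "genus_a", "place_b", "genus_b", "rho", "exact_p", "sign"],
        )


def cross_compartment_network(
    rel_a: pd.DataFrame,
    rel_b: pd.DataFrame,
    meta: pd.DataFrame,
    bw_group: str,
    config: Config | None = None,
    place_a: str = "JC",
    place_b: str = "JM",
    allow_negative: bool = True,
    mc_reps: int | None = None,
    seed=0,
) -> CrossNetwork:
    """Bipartite correlation network between two compartments' genera.

    Samples are matched by ``bird_id`` (the same five birds sampled in both
    compartments); a mismatch raises. Each ``place_a`` genus's out-degree is
    tested by Monte Carlo when ``mc_reps`` is given (only the ``place_a``
    vectors are permuted; the ``place_b`` side is held fixed).
    """
    config = config or Config()
    sub_a = meta[(meta["place"] == place_a) & (meta["bw_group"] == bw_group)]
    sub_b = meta[(meta["place"] == place_b) & (meta["bw_group"] == bw_group)]
    birds_a = sorted(sub_a["bird_id"])
    birds_b = sorted(sub_b["bird_id"])
    if birds_a != birds_b:
        raise ValueError(
            f"bird mismatch between {place_a} and {place_b} in {bw_group}: "
            f"{birds_a} vs {birds_b}"
        )
    samples_a = list(sub_a.set_index("bird_id").loc[birds_a, "sample_id"])
    samples_b = list(sub_b.set_index("bird_id").loc[birds_b, "sample_id"])

    genera_a = prevalence_filter_group(
        rel_a, meta, place_a, bw_group, config.cooc_prevalence_min
    )
    genera_b = prevalence_filter_group(
        rel_b, meta, place_b, bw_group, config.cooc_prevalence_min
    )
    XA = rel_a.loc[genera_a, samples_a].to_numpy(dtype=float)
    XB = rel_b.loc[genera_b, samples_b].to_numpy(dtype=float)
    ZA = _normalized_ranks(_rank_rows(XA))
    ZB = _normalized_ranks(_rank_rows(XB))
    C = ZA @ ZB.T
    thr = config.cooc_edge_rho_min
    adj = C >= thr - 1e-12
    if allow_negative:
        adj |= C <= -(thr - 1e-12)
    edges = []
    for i, j in zip(*np.nonzero(adj)):
        res = exact_spearman(XA[i], XB[j])
        edges.append(
            CrossEdge(genera_a[i], genera_b[j], float(C[i, j]), res.two_sided_p,
                      1 if C[i, j] > 0 else -1)
        )
    out_degree = dict(zip(genera_a, adj.sum(axis=1).astype(int)))
    net = CrossNetwork(
        bw_group=bw_group,
        place_a=place_a,
        place_b=place_b,
        nodes_a=genera_a,
        nodes_b=genera_b,
        edges=edges,
        out_degree=out_degree,
        threshold=thr,
        allow_negative=allow_negative,
        birds=birds_a,
    )
    if mc_reps is not None:
        mc_cross_out_degree_significance(rel_a, net, XA=XA, ZB=ZB, B=mc_reps, seed=seed)
    return net


def mc_cross_out_degree_significance(
    rel_a: pd.DataFrame, net: CrossNetwork, XA=None, ZB=None, B: int = 1000, seed=0
) -> dict:
    """Monte Carlo p for each source genus's bipartite out-degree."""
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    if XA is None or ZB is None:
        raise ValueError("internal arrays required; call via cross_compartment_network")
    RA = _rank_rows(XA)
    G, n = RA.shape
    keys = rng.random((B, G, n))
    perm = np.argsort(keys, axis=2)
    P = np.take_along_axis(np.broadcast_to(RA, (B, G, n)), perm, axis=2)
    norms = np.linalg.norm(RA - RA.mean(axis=1, keepdims=True), axis=1)
    Z = P - RA.mean(axis=1)[None, :, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(norms[None, :, None] > 0, Z / norms[None, :, None], 0.0)
    C = Z @ ZB.T[None, :, :]
    thr = net.threshold
    adj = C >= thr - 1e-12
    if net.allow_negative:
        adj |= C <= -(thr - 1e-12)
    null_deg = adj.sum(axis=2)  # B x G_a
    obs = np.array([net.out_degree[g] for g in net.nodes_a])
    p = ((null_deg >= obs[None, :]).sum(axis=0) + 1) / (B + 1)
    net.mc_out_p = dict(zip(net.nodes_a, p.astype(float)))
    net.mc_reps = B
    net.seed = seed
    return net.mc_out_p
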