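"""Beta-diversity distances, principal-coordinate analysis, and permutation
tests for community differences.

Distances are computed on per-sample relative abundances. Bray-Curtis is the
classical semimetric ``sum|x-y| / sum(x+y)``; the chi-square distance is the
correspondence-analysis distance between row profiles, which up-weights rare
taxa. Group tests (PERMANOVA pseudo-F, ANOSIM R, constrained correspondence
analysis) use label permutations with ``p = (#{null >= observed} + 1) /
(n_perm + 1)``, so p is never zero and reruns under one seed are identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

log = logging.getLogger(__name__)


@dataclass
class OrdinationTestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Distances


def bray_curtis(rel: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    ``rel`` is a features x samples abundance frame (relative or raw, as
    long as non-negative). A pair of all-zero samples gets distance 0 with
    a warning (the dissimilarity is undefined there).
    """
    X = rel.to_numpy(dtype=float).T  # samples x features
    if np.any(X < 0):
        raise ValueError("bray_curtis requires non-negative abundances")
    with np.errstate(invalid="ignore"):
        condensed = pdist(X, metric="braycurtis")
    if np.any(np.isnan(condensed)):
        log.warning("bray_curtis: all-zero sample pair(s); distance set to 0")
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(squareform(condensed), ids=list(rel.columns))


def chi_square_distance(rel: pd.DataFrame) -> DistanceMatrix:
    """Correspondence-analysis chi-square distance between sample profiles.

    ``d(i,j) = sqrt( sum_k (1/c_k) (p_ik/r_i - p_jk/r_j)^2 )`` computed on
    sample profiles (each sample normalised to sum 1, so samples carry equal
    mass and the distance is invariant to rescaling any one sample); all-zero
    features (zero column mass) are dropped with a warning.
    """
    X = rel.to_numpy(dtype=float).T  # samples x features
    if np.any(X < 0):
        raise ValueError("chi_square_distance requires non-negative abundances")
    keep = X.sum(axis=0) > 0
    if not keep.all():
        log.warning(
            "chi_square_distance: dropping %d feature(s) with zero total",
            int((~keep).sum()),
        )
        X = X[:, keep]
    if np.any(X.sum(axis=1) == 0):
        raise ValueError("chi_square_distance requires positive sample sums")
    X = X / X.sum(axis=1, keepdims=True)
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    profiles = P / r[:, None]
    scaled = profiles / np.sqrt(c)[None, :]
    condensed = pdist(scaled, metric="euclidean")
    return DistanceMatrix(squareform(condensed), ids=list(rel.columns))


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical (Gower) principal-coordinate analysis.

    Centers ``-D^2 / 2`` double-centred, eigendecomposes, and returns
    coordinates on the positive-eigenvalue axes. Negative eigenvalues are
    reported verbatim (no Lingoes/Cailliez correction).
    """
    D = dm.data
    n = D.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PCo{i + 1}" for i in range(int(pos.sum()))],
    )
    return PcoaResult(frame, eigvals)


# ---------------------------------------------------------------------------
# Permutation tests on distance matrices


def _group_info(dm: DistanceMatrix, labels):
    labels = np.asarray([str(x) for x in labels])
    if len(labels) != len(dm.ids):
        raise ValueError("one label per sample required")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if np.any(sizes < 2):
        small = uniq[np.argmin(sizes)]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    return codes, sizes, len(uniq)


def _permuted_codes(codes: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """(n_perm + 1) x n code matrix; row 0 is the observed labelling."""
    n = len(codes)
    out = np.empty((n_perm + 1, n), dtype=codes.dtype)
    out[0] = codes
    for b in range(1, n_perm + 1):
        out[b] = codes[rng.permutation(n)]
    return out


def _within_group_pair_sums(M: np.ndarray, codes_matrix: np.ndarray, k: int):
    """For each permutation row, sum of M over unordered within-group pairs."""
    B = codes_matrix.shape[0]
    totals = np.zeros(B)
    for g in range(k):
        mask = (codes_matrix == g).astype(float)
        totals += np.einsum("bi,ij,bj->b", mask, M, mask) / 2.0
    return totals


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999, seed=0) -> OrdinationTestResult:
    """One-way PERMANOVA: pseudo-F from squared-distance partitioning."""
    codes, sizes, k = _group_info(dm, labels)
    n = len(codes)
    rng = np.random.default_rng(seed)
    D2 = dm.data**2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    cm = _permuted_codes(codes, n_perm, rng)
    # SS_within per permutation: per group, pair sums / group size
    ss_within = np.zeros(n_perm + 1)
    for g in range(k):
        mask = (cm == g).astype(float)
        ss_within += np.einsum("bi,ij,bj->b", mask, D2, mask) / (2.0 * sizes[g])
    ss_among = ss_total - ss_within
    f_stats = (ss_among / (k - 1)) / (ss_within / (n - k))
    p = (np.sum(f_stats[1:] >= f_stats[0]) + 1) / (n_perm + 1)
    return OrdinationTestResult("permanova", float(f_stats[0]), float(p), n_perm, seed)


def anosim(dm: DistanceMatrix, labels, n_perm: int = 999, seed=0) -> OrdinationTestResult:
    """ANOSIM: R = (mean between-rank - mean within-rank) / (M/2)."""
    codes, sizes, k = _group_info(dm, labels)
    n = len(codes)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    ranks = rankdata(dm.data[iu])
    R = np.zeros((n, n))
    R[iu] = ranks
    R = R + R.T
    m_pairs = n * (n - 1) // 2
    total_rank = ranks.sum()
    n_within = int(np.sum(sizes * (sizes - 1) // 2))
    cm = _permuted_codes(codes, n_perm, rng)
    within_sums = _within_group_pair_sums(R, cm, k)
    mean_within = within_sums / n_within
    mean_between = (total_rank - within_sums) / (m_pairs - n_within)
    r_stats = (mean_between - mean_within) / (m_pairs / 2.0)
    p = (np.sum(r_stats[1:] >= r_stats[0]) + 1) / (n_perm + 1)
    return OrdinationTestResult("anosim", float(r_stats[0]), float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# Constrained correspondence analysis


@dataclass
class CcaResult:
    site_scores: pd.DataFrame
    eigenvalues: np.ndarray  # constrained axes
    constrained_inertia: float
    total_inertia: float
    test: OrdinationTestResult

    @property
    def constrained_fraction(self) -> float:
        return self.constrained_inertia / self.total_inertia


def _chi_square_standardized(X: np.ndarray):
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Qbar = (P - E) / np.sqrt(E)
    return Qbar, r


def cca(rel: pd.DataFrame, constraint, n_perm: int = 999, seed=0) -> CcaResult:
    """Canonical correspondence analysis of samples constrained by a design.

    ``rel`` is features x samples (non-negative); ``constraint`` a samples x q
    design matrix (DataFrame or array). Row scores of the chi-square
    standardised table are constrained by weighted least squares on the
    design; significance of the constrained inertia is assessed by permuting
    design rows (pseudo-F, ``n_perm`` permutations).
    """
    X = rel.to_numpy(dtype=float).T  # samples x features
    if np.any(X < 0):
        raise ValueError("cca requires non-negative abundances")
    keep = X.sum(axis=0) > 0
    if not keep.all():
        log.warning("cca: dropping %d all-zero feature(s)", int((~keep).sum()))
        X = X[:, keep]
    C = np.asarray(constraint, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n, q = C.shape
    if n != X.shape[0]:
        raise ValueError("constraint rows must match samples")
    if np.any(np.ptp(C, axis=0) == 0):
        raise ValueError("constraint columns must not be constant")

    Qbar, r = _chi_square_standardized(X)
    total_inertia = float((Qbar**2).sum())
    sqrt_r = np.sqrt(r)

    def _fit(Cmat):
        # weighted centring, then projection in the sqrt(r)-weighted metric
        Cc = Cmat - (r @ Cmat)[None, :]  # weighted column means (sum r = 1)
        Xw = Cc * sqrt_r[:, None]
        Uq, s, _ = np.linalg.svd(Xw, full_matrices=False)
        rank = int(np.sum(s > max(1e-10, s[0] * 1e-10))) if len(s) else 0
        Uq = Uq[:, :rank]
        Yhat = Uq @ (Uq.T @ Qbar)
        return Yhat, rank

    Yhat, rank = _fit(C)
    if rank < q:
        raise ValueError("rank-deficient constraint matrix")
    constrained = float((Yhat**2).sum())
    resid = total_inertia - constrained
    dof_resid = n - 1 - rank
    f_obs = (constrained / rank) / (resid / dof_resid) if dof_resid > 0 else np.inf

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Yp, rk = _fit(C[rng.permutation(n)])
        ci = float((Yp**2).sum())
        fp = (ci / max(rk, 1)) / ((total_inertia - ci) / max(n - 1 - rk, 1))
        if fp >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = s[:rank] ** 2
    # site scores in the chi-square metric (weighted by row masses)
    scores = (U[:, :rank] * s[:rank]) / sqrt_r[:, None]
    frame = pd.DataFrame(
        scores, index=list(rel.columns), columns=[f"CCA{i + 1}" for i in range(rank)]
    )
    test = OrdinationTestResult("cca", float(f_obs), float(p), n_perm, seed)
    return CcaResult(frame, eig, constrained, total_inertia, test)
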