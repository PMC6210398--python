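"""Shared machinery for cluster-based permutation inference.

One engine serves sensor maps (neighbourhood graph), source volumes
(lattice 6-connectivity) and group one-sample maps (sign-flipping):
suprathreshold statistics are clustered by connectivity separately by
sign, cluster mass is the summed statistic, and the null is the maximum
absolute cluster mass over permuted datasets.  Monte-Carlo p-values use
the add-one convention p = (1 + #{null >= |mass|}) / (n_perm + 1).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


def slope_t_vec(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS slope t-statistics of y (n, ...) regressed on x (n,).

    Vectorized over trailing axes; df = n - 2.  Channels with zero
    residual variance return +-inf (degenerate fit).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("regressor x has zero variance")
    yc = y - y.mean(axis=0)
    sxy = np.tensordot(xc, yc, axes=(0, 0))
    beta = sxy / sxx
    syy = (yc**2).sum(axis=0)
    ss_res = np.maximum(syy - beta**2 * sxx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.sign(beta) * np.inf)
    t = np.where((se == 0) & (beta == 0), 0.0, t)
    return t


def label_clusters(t: np.ndarray, adjacency: sp.spmatrix, threshold: float
                   ) -> tuple[np.ndarray, list[float]]:
    """Connected suprathreshold clusters, separately by sign.

    Returns per-element cluster ids (0 = none, 1..K otherwise) and the
    signed mass (summed t) per cluster.
    """
    ids = np.zeros(len(t), dtype=int)
    masses: list[float] = []
    adjacency = sp.csr_matrix(adjacency)
    next_id = 1
    for sign in (1.0, -1.0):
        mask = (sign * t) > threshold
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        sub = adjacency[idx][:, idx]
        n_comp, lab = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[lab == c]
            ids[members] = next_id
            masses.append(float(t[members].sum()))
            next_id += 1
    return ids, masses


def max_cluster_mass(t: np.ndarray, adjacency: sp.spmatrix, threshold: float) -> float:
    _, masses = label_clusters(t, adjacency, threshold)
    return max((abs(m) for m in masses), default=0.0)


def permutation_null_labels(
    values: np.ndarray,
    x: np.ndarray,
    adjacency: sp.spmatrix,
    threshold: float,
    n_perm: int,
    rng: np.random.Generator,
    blocks: np.ndarray | None = None,
) -> np.ndarray:
    """Null max-cluster-mass distribution under label permutation.

    ``values`` is (n_obs, n_elements); labels are permuted freely or
    within blocks.
    """
    null = np.empty(n_perm)
    x = np.asarray(x, dtype=float)
    for p in range(n_perm):
        if blocks is None:
            xp = rng.permutation(x)
        else:
            xp = x.copy()
            for b in np.unique(blocks):
                sel = np.flatnonzero(blocks == b)
                xp[sel] = xp[rng.permutation(sel)]
        t = slope_t_vec(values, xp)
        null[p] = max_cluster_mass(t, adjacency, threshold)
    return null


def signflip_null(
    values: np.ndarray,
    adjacency: sp.spmatrix,
    threshold: float,
    n_perm: int,
    rng: np.random.Generator,
    exhaustive: bool = False,
) -> np.ndarray:
    """Null max-cluster-mass distribution under subject sign-flipping.

    ``values`` is (n_subjects, n_elements).  With ``exhaustive`` all
    2**n_subjects sign patterns are enumerated.
    """
    n_sub = values.shape[0]
    if exhaustive:
        patterns = ((np.arange(2**n_sub)[:, None] >> np.arange(n_sub)) & 1) * 2 - 1
    else:
        patterns = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    null = np.empty(len(patterns))
    for p, signs in enumerate(patterns):
        t = one_sample_t(values * signs[:, None])
        null[p] = max_cluster_mass(t, adjacency, threshold)
    return null


def one_sample_t(values: np.ndarray) -> np.ndarray:
    """One-sample t against zero over axis 0; zero-variance gives t = 0."""
    n = values.shape[0]
    m = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd > 0, t, np.where(m == 0, 0.0, np.sign(m) * np.inf))


def mc_pvalues(masses: list[float], null: np.ndarray) -> np.ndarray:
    n_perm = len(null)
    return np.array(
        [(1.0 + np.sum(null >= abs(m))) / (n_perm + 1.0) for m in masses]
    )
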