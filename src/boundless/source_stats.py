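"""Frequency-domain beamformer source estimation and volumetric inference.

At the sensor-level peak frequency, per-epoch multitapered Fourier
coefficients give a cross-spectral density (CSD) matrix.  A unit-gain
minimum-variance spatial filter (the scalar DICS special case) is built
per grid voxel from the regularized real part of the all-conditions CSD,
with the dipole orientation chosen to maximize output power.  Per-epoch
sensor coefficients projected through the filters and log-transformed
yield source power per epoch and voxel, which feeds the same ordinal
regression + cluster permutation engine as the sensor stage, with lattice
6-connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from ._cluster import (
    label_clusters,
    mc_pvalues,
    permutation_null_labels,
    slope_t_vec,
)
from .forward import SourceGrid, lattice_adjacency
from .io import EpochSet
from .spectral import taper_family


@dataclass
class CSDMatrix:
    """Cross-spectral density at one frequency, plus per-epoch coefficients.

    ``csd`` is channels x channels, Hermitian; ``coeffs`` holds the
    per-epoch, per-taper Fourier coefficients (n_epochs, n_tapers,
    n_channels) used later for single-epoch projection.
    """

    csd: np.ndarray
    coeffs: np.ndarray
    f0: float
    smoothing: float
    n_epochs: int

    def __post_init__(self) -> None:
        h = np.abs(self.csd - self.csd.conj().T).max()
        if h > 1e-10 * max(1.0, np.abs(self.csd).max()):
            raise ValueError("CSD must be Hermitian")


def compute_csd(epochs: EpochSet, f0: float, smoothing: float = 4.0) -> CSDMatrix:
    """Multitaper Fourier coefficients and CSD at frequency ``f0``.

    The taper family covers ``f0 +- smoothing`` Hz on the full epoch
    length; the CSD is the average over epochs and tapers of the outer
    product of the coefficient vectors (Hermitian by construction).
    """
    n_ep, n_ch, n_samp = epochs.data.shape
    if f0 >= epochs.sfreq / 2:
        raise ValueError("f0 must be below Nyquist")
    if n_ep < n_ch:
        warnings.warn("fewer epochs than channels: CSD is rank-deficient, "
                      "regularization required", stacklevel=2)
    t_len = n_samp / epochs.sfreq
    tapers = taper_family(t_len, epochs.sfreq, smoothing)     # (K, n_samp)
    t = np.arange(n_samp) / epochs.sfreq
    phasor = np.exp(-2j * np.pi * f0 * t)                     # (n_samp,)
    basis = tapers * phasor                                   # (K, n_samp)
    data = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    coeffs = np.einsum("ecs,ks->ekc", data, basis)            # (E, K, C)
    csd = np.einsum("ekc,ekd->cd", coeffs, coeffs.conj()) / (n_ep * len(tapers))
    csd = 0.5 * (csd + csd.conj().T)
    return CSDMatrix(csd, coeffs, f0, smoothing, n_ep)


@dataclass
class DICSFilters:
    """Per-voxel unit-gain spatial filters and source orientations."""

    weights: np.ndarray        # (n_voxels, n_channels)
    orientations: np.ndarray   # (n_voxels, 3)
    reg_lambda: float


def dics_filters(csd: CSDMatrix, leadfields: np.ndarray,
                 reg_lambda: float = 0.05) -> DICSFilters:
    """Unit-gain minimum-variance filters from the regularized CSD.

    The real part of the CSD is ridge-regularized with lambda =
    ``reg_lambda`` x mean(diagonal).  In a spherical conductor every
    source location has a silent (radial) direction, so the lead field is
    first reduced to its rank-2 non-silent subspace (SVD); within that
    subspace the orientation maximizing beamformer output power (the
    minimum eigenvector of the projected L^T C^-1 L) is selected, then
    w = C^-1 l / (l^T C^-1 l) for the oriented lead field l, so that
    w^T l = 1 exactly.  Fully silent voxels (e.g. the sphere centre) get
    zero filters.
    """
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be >= 0")
    C = np.real(csd.csd).copy()
    lam = reg_lambda * np.trace(C) / C.shape[0]
    C_reg = C + lam * np.eye(C.shape[0])
    try:
        Ci = np.linalg.inv(C_reg)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "CSD is singular; use reg_lambda > 0") from err
    cond = np.linalg.cond(C_reg)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"CSD nearly singular (cond {cond:.2g}); use reg_lambda > 0")
    n_vox = leadfields.shape[0]
    n_ch = leadfields.shape[2]
    weights = np.empty((n_vox, n_ch))
    orients = np.empty((n_vox, 3))
    for v in range(n_vox):
        L = leadfields[v].T                      # (C, 3)
        U, S, Vt = np.linalg.svd(L, full_matrices=False)
        if S[0] <= 0 or S[1] < 1e-8 * S[0]:      # silent voxel
            weights[v] = 0.0
            orients[v] = Vt[0] if S[0] > 0 else np.array([1.0, 0.0, 0.0])
            continue
        V2 = Vt[:2].T                            # (3, 2) non-silent subspace
        L2 = L @ V2                              # (C, 2)
        P2 = L2.T @ Ci @ L2
        _, evecs = np.linalg.eigh(P2)
        u = V2 @ evecs[:, 0]                     # min eigenvalue: max power
        l = L @ u
        denom = float(l @ Ci @ l)
        if denom <= 0:
            raise np.linalg.LinAlgError("degenerate lead field projection")
        w = (Ci @ l) / denom
        weights[v] = w
        orients[v] = u
    return DICSFilters(weights, orients, reg_lambda)


def project_epoch_power(filters: DICSFilters, csd: CSDMatrix) -> np.ndarray:
    """Per-epoch, per-voxel log source power.

    For each epoch the taper-averaged |w^T F|^2 is computed from the
    epoch's Fourier coefficients F and log-transformed.
    """
    if filters.weights.shape[1] != csd.coeffs.shape[2]:
        raise ValueError("filters and coefficients disagree on channel count")
    proj = np.einsum("vc,ekc->ekv", filters.weights, csd.coeffs)
    power = (np.abs(proj) ** 2).mean(axis=1)          # (E, V)
    tiny = np.finfo(float).tiny
    return np.log(np.maximum(power, tiny))


@dataclass
class StatVolume:
    """Per-voxel regression t-values on a source grid, with clusters."""

    grid: SourceGrid
    t: np.ndarray              # (n_inside,)
    cluster_id: np.ndarray
    cluster_mass: np.ndarray
    cluster_p: np.ndarray
    forming_threshold: float

    def significant_voxels(self, alpha: float = 0.05) -> np.ndarray:
        sig_ids = {i + 1 for i, p in enumerate(self.cluster_p) if p <= alpha}
        return np.flatnonzero(np.isin(self.cluster_id, list(sig_ids)))

    def peak_position(self) -> np.ndarray:
        """Position (m) of the most extreme |t| inside voxel."""
        return self.grid.inside_positions[int(np.argmax(np.abs(self.t)))]


def volume_regression_test(
    src_power: np.ndarray,
    x: np.ndarray,
    grid: SourceGrid,
    forming_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    blocks: np.ndarray | None = None,
) -> StatVolume:
    """Voxelwise ordinal regression with volumetric cluster permutation.

    Identical engine to the sensor-level cluster test, with 6-connectivity
    on the source lattice.
    """
    src_power = np.asarray(src_power, dtype=float)
    if src_power.shape[1] != grid.n_inside:
        raise ValueError("src_power must be (n_epochs, n_inside_voxels)")
    adjacency = lattice_adjacency(grid)
    x = np.asarray(x, dtype=float)
    df = len(x) - 2
    threshold = scipy.stats.t.ppf(1.0 - forming_alpha / 2.0, df)
    t = slope_t_vec(src_power, x)
    ids, masses = label_clusters(t, adjacency, threshold)
    rng = np.random.default_rng(seed)
    null = permutation_null_labels(src_power, x, adjacency, threshold, n_perm,
                                   rng, blocks)
    pvals = mc_pvalues(masses, null)
    return StatVolume(grid, t, ids, np.asarray(masses), pvals, threshold)
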