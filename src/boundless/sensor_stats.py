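"""Sensor-level inference for the graded three-state design.

Two-stage selection: first a spectrum-wide ordinal regression (power vs
condition code 1/2/3) averaged over sensors, corrected by
Benjamini-Hochberg FDR, defines the frequency of interest (FOI) as the
longest contiguous significant run; then a per-sensor regression averaged
over the FOI, assessed with a cluster-based permutation test on the
sensor neighbourhood graph, defines the sensors of interest (SOI).
Post hoc pairwise Welch tests (Bonferroni x3), percent signal change, an
order-of-presentation control regression and rest-baseline correction
complete the stage.

Responses default to log power: the graded design places the condition
effect multiplicatively on source power, so log power is linear in the
ordinal code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from ._cluster import (
    label_clusters,
    mc_pvalues,
    permutation_null_labels,
    slope_t_vec,
)
from .spectral import PowerSpectra, band_average


@dataclass
class RegressionSpectrum:
    """Per-frequency ordinal-regression results with an FDR mask and FOI."""

    freqs: np.ndarray
    t: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    foi: tuple[float, float] | None   # (f_lo, f_hi) of the longest significant run

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq": self.freqs, "t": self.t, "p": self.p,
                             "significant": self.fdr_mask})


@dataclass
class StatMap:
    """Per-channel regression t-values with cluster labels and p-values."""

    t: np.ndarray
    cluster_id: np.ndarray            # 0 = no cluster
    cluster_mass: np.ndarray          # signed summed t per cluster (1-based ids)
    cluster_p: np.ndarray
    forming_threshold: float
    channel_names: list[str] = field(default_factory=list)

    def significant_channels(self, alpha: float = 0.05) -> np.ndarray:
        """Indices of channels in any cluster with Monte-Carlo p <= alpha."""
        sig_ids = {i + 1 for i, p in enumerate(self.cluster_p) if p <= alpha}
        return np.flatnonzero(np.isin(self.cluster_id, list(sig_ids)))

    def cluster_report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": np.arange(1, len(self.cluster_mass) + 1),
            "mass": self.cluster_mass,
            "n_members": [int((self.cluster_id == i + 1).sum())
                          for i in range(len(self.cluster_mass))],
            "p": self.cluster_p,
        })


def slope_t(y: np.ndarray, x: np.ndarray) -> tuple[float, float, int]:
    """OLS slope t-statistic of y on the ordinal regressor x.

    Returns (t, two-sided p, df) with df = n - 2; equivalent to the
    correlation form t = r * sqrt((n - 2) / (1 - r^2)).  Zero residual
    variance yields t = +-inf with p = 0 (degenerate, perfect fit).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 1 or len(y) != len(x):
        raise ValueError("y and x must be equal-length vectors")
    n = len(x)
    if n < 3 or len(np.unique(x)) < 2:
        raise ValueError("need >= 3 observations spanning >= 2 x values")
    t = float(slope_t_vec(y[:, None], x)[0])
    df = n - 2
    if np.isinf(t):
        return t, 0.0, df
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return t, float(p), df


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject the k* smallest p-values where
    k* = max{k : p_(k) <= k q / m}.  Returns a boolean rejection mask."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k_star = int(np.flatnonzero(below).max())
        mask[order[: k_star + 1]] = True
    return mask


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    """(start, stop) inclusive indices of the longest run of True;
    ties resolved toward the lowest index."""
    best = None
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    return best


def _scan(values_ef: np.ndarray, x: np.ndarray, freqs: np.ndarray, q: float
          ) -> RegressionSpectrum:
    t = slope_t_vec(values_ef, x)
    df = len(x) - 2
    p = np.where(np.isinf(t), 0.0, 2.0 * scipy.stats.t.sf(np.abs(t), df))
    mask = fdr_bh(p, q)
    run = _longest_true_run(mask)
    foi = (float(freqs[run[0]]), float(freqs[run[1]])) if run else None
    return RegressionSpectrum(freqs, t, p, mask, foi)


def foi_scan(ps: PowerSpectra, q: float = 0.05, use_log: bool = True
             ) -> RegressionSpectrum:
    """Spectrum-wide regression on the sensor-averaged power, BH-corrected.

    Power is averaged over channels per epoch and frequency, regressed on
    the ordinal condition code, and the FDR mask at level ``q`` defines
    the FOI as the span of the longest contiguous significant run.
    """
    y = ps.power.mean(axis=1)                      # (E, F)
    if use_log:
        y = np.log(y)
    return _scan(y, ps.x, ps.freqs, q)


def order_surrogate(ps: PowerSpectra, mode: str = "within_interval") -> np.ndarray:
    """Surrogate 1..3 "condition" codes built from presentation order alone.

    ``within_interval`` (default) ranks epochs by time within each
    block-and-condition interval and splits them into temporal thirds —
    a drift probe orthogonal to the condition code.  ``within_block``
    ranks within the whole block; under the fixed SB1->SB2->SB3 order
    with equal epoch counts this reproduces the condition code itself.
    """
    order = ps.meta["order_index"].to_numpy()
    block = ps.meta["block"].to_numpy()
    if mode == "within_block":
        groups = [(b,) for b in np.unique(block)]
        key = block
    elif mode == "within_interval":
        cond = ps.meta["condition"].to_numpy()
        key = np.array([f"{b}|{c}" for b, c in zip(block, cond)])
        groups = [(g,) for g in np.unique(key)]
    else:
        raise ValueError(f"unknown order_control mode {mode!r}")
    x = np.zeros(len(order))
    for (g,) in groups:
        sel = key == g
        ranks = scipy.stats.rankdata(order[sel], method="ordinal")
        x[sel] = np.ceil(3 * ranks / sel.sum())
    return x


def order_control(ps: PowerSpectra, q: float = 0.05, use_log: bool = True,
                  mode: str = "within_interval") -> RegressionSpectrum:
    """FOI scan with conditions replaced by temporal-order surrogates.

    A control for effects driven purely by the order of presentation:
    a condition-driven effect that is constant in time within intervals
    shows no surrogate-order regression, while genuine temporal drift
    does.  See :func:`order_surrogate` for the surrogate coding.
    """
    x = order_surrogate(ps, mode)
    y = ps.power.mean(axis=1)
    if use_log:
        y = np.log(y)
    return _scan(y, x, ps.freqs, q)


def cluster_perm_test(
    values: np.ndarray,
    x: np.ndarray,
    adjacency: sp.spmatrix,
    forming_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    blocks: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> StatMap:
    """Cluster-based permutation test of per-channel regression t-values.

    Channels whose |t| exceeds the two-sided forming threshold are
    clustered by graph connectivity separately by sign; cluster mass is
    the summed t.  The null distribution is the maximum absolute cluster
    mass over ``n_perm`` permutations of the condition labels (within
    blocks when ``blocks`` is given, preserving the block structure of the
    fixed-order design).
    """
    import warnings

    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("values must be (n_epochs, n_channels>=2)")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse Monte-Carlo p",
                      stacklevel=2)
    x = np.asarray(x, dtype=float)
    df = len(x) - 2
    threshold = scipy.stats.t.ppf(1.0 - forming_alpha / 2.0, df)
    t = slope_t_vec(values, x)
    ids, masses = label_clusters(t, adjacency, threshold)
    rng = np.random.default_rng(seed)
    null = permutation_null_labels(values, x, adjacency, threshold, n_perm,
                                   rng, blocks)
    pvals = mc_pvalues(masses, null)
    return StatMap(t, ids, np.asarray(masses), pvals, threshold,
                   channel_names or [])


def posthoc_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Welch two-sample t-tests for the three pairwise contrasts.

    ``values`` is one scalar per epoch (after SOI x FOI collapse); p-values
    are Bonferroni-corrected by a factor of 3 (capped at 1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = {}
    for lab in ("SB1", "SB2", "SB3"):
        sel = np.isin(labels, [lab]) | (labels == {"SB1": 1, "SB2": 2, "SB3": 3}[lab])
        if not sel.any():
            raise ValueError(f"condition {lab} missing")
        groups[lab] = values[sel]
    rows = []
    for a, b in (("SB1", "SB2"), ("SB2", "SB3"), ("SB1", "SB3")):
        t, p = scipy.stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append({"contrast": f"{a} vs {b}", "t": float(t),
                     "p": float(p), "p_bonferroni": min(1.0, 3.0 * float(p))})
    return pd.DataFrame(rows)


def baseline_correct(ps: PowerSpectra, rest_ps: PowerSpectra) -> PowerSpectra:
    """Divide SB power by the same block's mean rest power (relative change)."""
    if not np.array_equal(ps.freqs, rest_ps.freqs):
        raise ValueError("SB and rest spectra must share the frequency grid")
    out = ps.power.copy()
    blocks = ps.meta["block"].to_numpy()
    rest_blocks = rest_ps.meta["block"].to_numpy()
    for b in np.unique(blocks):
        sel_rest = rest_blocks == b
        if not sel_rest.any():
            raise ValueError(f"no rest epochs for block {b}")
        baseline = rest_ps.power[sel_rest].mean(axis=0)   # (C, F)
        if np.any(baseline <= 0):
            raise ValueError("zero rest power bin; cannot baseline-correct")
        out[blocks == b] /= baseline
    return PowerSpectra(out, ps.freqs, ps.meta.copy(), ps.native_bin)


def percent_signal_change(
    ps: PowerSpectra, foi: tuple[float, float], cond_a: str, cond_b: str
) -> np.ndarray:
    """Per-channel percent signal change of FOI power: 100 (mean_b - mean_a)/mean_a."""
    band = band_average(ps, foi)                  # (E, C)
    cond = ps.meta["condition"].to_numpy()
    for c in (cond_a, cond_b):
        if not (cond == c).any():
            raise ValueError(f"condition {c} not present")
    mean_a = band[cond == cond_a].mean(axis=0)
    mean_b = band[cond == cond_b].mean(axis=0)
    if np.any(mean_a == 0):
        raise ValueError("zero mean power in the reference condition")
    return 100.0 * (mean_b - mean_a) / mean_a
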