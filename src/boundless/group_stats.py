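"""Group-level pooling of per-subject regression results.

Per subject, the sensor-averaged ordinal-regression slope t is computed
for each canonical band; the group test is a one-sample t of the pooled
per-subject values against zero (df = n_subjects - 1), Bonferroni-corrected
over bands.  Group source maps pool per-subject voxelwise regression
t-values with a sign-flipping cluster permutation (exhaustive over all
2**n patterns for small cohorts), optionally restricted to a reference
ROI mask and optionally contrasted against a reference subject's map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._cluster import (
    label_clusters,
    mc_pvalues,
    one_sample_t,
    signflip_null,
    slope_t_vec,
)
from .config import CANONICAL_BANDS
from .forward import SourceGrid, lattice_adjacency
from .source_stats import StatVolume
from .spectral import PowerSpectra


def subject_band_regression(
    ps: PowerSpectra,
    bands: dict[str, tuple[float, float]] | None = None,
    use_log: bool = True,
) -> pd.Series:
    """Sensor-averaged slope t per canonical band for one subject."""
    from .spectral import band_bin_indices

    bands = bands or CANONICAL_BANDS
    out = {}
    x = ps.x
    for name, (lo, hi) in bands.items():
        sel = band_bin_indices(ps, (lo, hi))
        if len(sel) == 0:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) outside the spectrum")
        y = ps.power[:, :, sel].mean(axis=(1, 2))
        if use_log:
            y = np.log(y)
        out[name] = float(slope_t_vec(y[:, None], x)[0])
    return pd.Series(out)


def group_band_test(
    subject_values: pd.DataFrame | np.ndarray,
    n_bands_correction: int = 6,
) -> pd.DataFrame:
    """One-sample t per band of the pooled per-subject values against zero.

    ``subject_values`` is subjects x bands.  df = n_subjects - 1; the
    Bonferroni column multiplies p by ``n_bands_correction`` (capped at 1).
    All-zero input for a band is degenerate: t = 0, p = 1, flagged.
    """
    df_in = pd.DataFrame(subject_values)
    n = len(df_in)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for band in df_in.columns:
        v = df_in[band].to_numpy(float)
        degenerate = v.std(ddof=1) == 0
        if degenerate:
            t, p = (0.0, 1.0)
        else:
            t, p = scipy.stats.ttest_1samp(v, 0.0)
        rows.append({
            "band": band, "t": float(t), "df": n - 1,
            "p_uncorrected": float(p),
            "p_bonferroni": min(1.0, float(p) * n_bands_correction),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


@dataclass
class GroupSourceResult:
    volume: StatVolume
    reference_contrast: StatVolume | None = None


def group_source_test(
    subject_maps: np.ndarray,
    grid: SourceGrid,
    roi_mask: np.ndarray | None = None,
    reference_map: np.ndarray | None = None,
    forming_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> GroupSourceResult:
    """Voxelwise one-sample cluster test of per-subject regression maps.

    ``subject_maps`` is (n_subjects, n_inside_voxels) of per-subject
    regression t-values (or coefficients) on a shared grid.  The null is
    built by sign-flipping subjects; for cohorts of up to 12 subjects the
    exhaustive 2**n enumeration is used by default.  ``roi_mask``
    (boolean over inside voxels) restricts testing to the mask;
    ``reference_map`` additionally tests subjects minus the reference
    voxel values.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[1] != grid.n_inside:
        raise ValueError("subject_maps must be (n_subjects, n_inside_voxels) "
                         "on the shared grid")
    n_sub = maps.shape[0]
    if exhaustive is None:
        exhaustive = n_sub <= 12
    adjacency = lattice_adjacency(grid)
    active = np.ones(grid.n_inside, bool) if roi_mask is None else np.asarray(roi_mask, bool)

    def run(values: np.ndarray) -> StatVolume:
        threshold = scipy.stats.t.ppf(1.0 - forming_alpha / 2.0, n_sub - 1)
        t_full = one_sample_t(values)
        t = np.where(active, t_full, 0.0)
        sub_adj = adjacency
        ids, masses = label_clusters(t, sub_adj, threshold)
        rng = np.random.default_rng(seed)
        masked = values * active
        null = signflip_null(masked, sub_adj, threshold, n_perm, rng,
                             exhaustive=exhaustive)
        pvals = mc_pvalues(masses, null)
        return StatVolume(grid, t, ids, np.asarray(masses), pvals, threshold)

    vol = run(maps)
    ref = None
    if reference_map is not None:
        ref = run(maps - np.asarray(reference_map, float)[None, :])
    return GroupSourceResult(vol, ref)


def make_synthetic_atlas(
    grid: SourceGrid,
    labels: list[str] | None = None,
    seed: int = 0,
) -> pd.Series:
    """A synthetic labelled parcellation of the inside voxels.

    Voxels are assigned to the nearest of a few seed points drawn inside
    the sphere — a stand-in atlas for overlap bookkeeping (region names
    are placeholders, not anatomy).
    """
    labels = labels or ["TPJ-like-R", "TPJ-like-L", "MPC-like",
                        "frontal-like", "occipital-like", "deep"]
    rng = np.random.default_rng(seed)
    seeds = rng.uniform(-1, 1, (len(labels), 3))
    seeds = seeds / np.linalg.norm(seeds, axis=1, keepdims=True) * \
        rng.uniform(0.3, 0.9, (len(labels), 1)) * grid.sphere_radius
    pos = grid.inside_positions - grid.sphere_center
    d = np.linalg.norm(pos[:, None] - seeds[None, :], axis=2)
    idx = d.argmin(axis=1)
    return pd.Series([labels[i] for i in idx], name="label")


def atlas_overlap(vol: StatVolume, atlas: pd.Series, alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Percent overlap of the significant voxel set with each atlas label.

    Per label: 100 x |significant AND label| / |significant|, sorted
    descending.  An empty significant set yields an empty table.
    """
    if len(atlas) != vol.grid.n_inside:
        raise ValueError("atlas must label every inside voxel of the grid")
    sig = vol.significant_voxels(alpha)
    if len(sig) == 0:
        return pd.DataFrame(columns=["label", "overlap_pct"])
    lab = np.asarray(atlas)
    rows = [
        {"label": name, "overlap_pct": 100.0 * np.sum(lab[sig] == name) / len(sig)}
        for name in pd.unique(lab)
    ]
    out = pd.DataFrame(rows).sort_values("overlap_pct", ascending=False)
    return out[out["overlap_pct"] > 0].reset_index(drop=True)
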