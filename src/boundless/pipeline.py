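"""End-to-end subject-level analysis chains.

Thin orchestration over the module functions: raw recording -> cleaned
epochs -> spectra -> sensor statistics -> beamformer source statistics.
These are the units the command-line interface, the validation
experiments, and cohort pooling run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocess, sensor_stats, source_stats, spectral
from ._cluster import slope_t_vec
from .config import AnalysisConfig
from .forward import build_grid, leadfields
from .io import EpochSet, RawRecording
from .spectral import PowerSpectra


def preprocess_recording(
    rec: RawRecording,
    cfg: AnalysisConfig,
    ica_templates: list[np.ndarray] | None = None,
    run_ica: bool = False,
) -> tuple[EpochSet, EpochSet]:
    """Line-noise removal, epoching, artifact rejection, optional ICA.

    Returns (SB epochs, rest epochs).  ICA is skipped by default in the
    simulation experiments when no artifact sources are active.
    """
    clean = preprocess.remove_line_noise(rec, cfg.line_freq)
    sb, rest = preprocess.segment_epochs(clean, cfg)
    sb, _ = preprocess.reject_artifact_epochs(sb, cfg.reject_z_thresh)
    if run_ica:
        templates = None
        if ica_templates is not None:
            templates = [preprocess.slice_to_epochs(t, sb) for t in ica_templates]
        sb, _ = preprocess.ica_clean(sb, templates, cfg.ica_corr_thresh,
                                     cfg.downsample_to, seed=cfg.rng_seed)
    good = sb.sensors.good_index()
    if len(good) < sb.sensors.n_channels:
        sb = _drop_bad(sb, good)
        rest = _drop_bad(rest, good)
    return sb, rest


def _drop_bad(epochs: EpochSet, good: np.ndarray) -> EpochSet:
    return EpochSet(epochs.data[:, good, :], epochs.sfreq, epochs.condition,
                    epochs.block, epochs.order_index,
                    epochs.sensors.subset(good), epochs.start_sample)


@dataclass
class SensorResult:
    spectra: PowerSpectra
    scan: sensor_stats.RegressionSpectrum
    stat_map: sensor_stats.StatMap | None
    peak_freq: float | None


def sensor_analysis(sb: EpochSet, cfg: AnalysisConfig) -> SensorResult:
    """FOI scan then SOI cluster test on the FOI-averaged sensor power."""
    ps = spectral.epoch_power(sb, cfg)
    scan = sensor_stats.foi_scan(ps, cfg.fdr_q, cfg.use_log_power)
    stat_map = None
    peak = None
    if scan.foi is not None:
        sel = (ps.freqs >= scan.foi[0]) & (ps.freqs <= scan.foi[1])
        peak = float(ps.freqs[sel][np.argmax(np.abs(scan.t[sel]))])
        y = ps.power[:, :, sel].mean(axis=2)
        if cfg.use_log_power:
            y = np.log(y)
        stat_map = sensor_stats.cluster_perm_test(
            y, ps.x, sb.sensors.neighbor_graph, cfg.cluster_forming_alpha,
            cfg.n_permutations, seed=cfg.rng_seed,
            blocks=ps.meta["block"].to_numpy(),
            channel_names=sb.sensors.channel_names,
        )
    return SensorResult(ps, scan, stat_map, peak)


@dataclass
class SourceResult:
    grid: object
    src_power: np.ndarray            # (E, V) log power
    volume: source_stats.StatVolume
    voxel_t: np.ndarray              # per-voxel regression t (= volume.t)


def source_analysis(
    sb: EpochSet,
    cfg: AnalysisConfig,
    f0: float,
    sphere_radius: float,
    grid=None,
    lf: np.ndarray | None = None,
    n_perm: int | None = None,
) -> SourceResult:
    """Beamformer chain at frequency ``f0`` with volumetric cluster test."""
    if grid is None:
        grid = build_grid(np.zeros(3), sphere_radius, cfg.source_spacing,
                          cfg.source_margin)
    if lf is None:
        lf = leadfields(grid, sb.sensors)
    csd = source_stats.compute_csd(sb, f0, cfg.source_smoothing)
    filters = source_stats.dics_filters(csd, lf, cfg.reg_lambda)
    src_power = source_stats.project_epoch_power(filters, csd)
    vol = source_stats.volume_regression_test(
        src_power, sb.x, grid, cfg.cluster_forming_alpha,
        n_perm or cfg.n_permutations, seed=cfg.rng_seed,
        blocks=sb.block,
    )
    return SourceResult(grid, src_power, vol, vol.t)


def subject_voxel_map(sb: EpochSet, cfg: AnalysisConfig, f0: float,
                      grid, lf: np.ndarray) -> np.ndarray:
    """Per-voxel regression t for one subject (no permutation), for pooling."""
    csd = source_stats.compute_csd(sb, f0, cfg.source_smoothing)
    filters = source_stats.dics_filters(csd, lf, cfg.reg_lambda)
    src_power = source_stats.project_epoch_power(filters, csd)
    return slope_t_vec(src_power, sb.x)
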