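"""Analysis configuration.

All numeric parameters of the pipeline live in one dataclass so that a
default run reproduces the full graded-state pipeline shape: 2-s epochs, 3-s
lead-in discard, 300 Hz decomposition rate, band-specific sliding-window
spectra (0.5 s / ±2 Hz for 2–40 Hz; 0.2 s / ±14 Hz for 40–90 Hz; 50-ms
slide), BH-FDR frequency scan, cluster permutation, 1-cm source grid with
±4 Hz smoothing, and the six canonical bands.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

#: canonical frequency bands, Hz (inclusive edges)
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1, 4),
    "theta": (5, 7),
    "alpha": (8, 13),
    "beta": (14, 30),
    "low_gamma": (31, 50),
    "high_gamma": (51, 90),
}


@dataclass
class AnalysisConfig:
    """Pipeline parameters with the reference defaults (see module docstring)."""

    # spectral analysis
    low_band: tuple[float, float] = (2.0, 40.0)
    low_window: float = 0.5         # s
    low_smoothing: float = 2.0      # half-bandwidth, Hz
    high_band: tuple[float, float] = (40.0, 90.0)
    high_window: float = 0.2        # s
    high_smoothing: float = 14.0    # half-bandwidth, Hz
    slide_step: float = 0.05        # s
    # epoching / preprocessing
    epoch_len: float = 2.0          # s
    discard_lead_in: float = 3.0    # s
    downsample_to: float = 300.0    # Hz (ICA decomposition rate)
    line_freq: float = 50.0         # Hz
    reject_z_thresh: float = 5.0    # robust z for artifact-epoch rejection
    ica_corr_thresh: float = 0.5    # |r| for artifact-component flagging
    # statistics
    fdr_q: float = 0.05
    cluster_alpha: float = 0.05
    cluster_forming_alpha: float = 0.05
    n_permutations: int = 1000
    use_log_power: bool = True
    n_bands_correction: int = 6
    # source analysis
    source_spacing: float = 0.01    # m
    source_margin: float = 0.005    # m, keep voxels off the conductor boundary
    source_smoothing: float = 4.0   # half-bandwidth, Hz
    reg_lambda: float = 0.05        # fraction of mean CSD diagonal
    # misc
    canonical_bands: dict = field(default_factory=lambda: dict(CANONICAL_BANDS))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.low_band = tuple(float(v) for v in self.low_band)
        self.high_band = tuple(float(v) for v in self.high_band)
        for name in ("low_band", "high_band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be 0 < lo < hi, got {(lo, hi)}")
        for name in ("low_window", "high_window", "slide_step", "epoch_len",
                     "downsample_to", "line_freq", "source_spacing",
                     "source_smoothing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("discard_lead_in", "source_margin", "reg_lambda",
                     "low_smoothing", "high_smoothing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fdr_q", "cluster_alpha", "cluster_forming_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        bands = {k: (float(a), float(b)) for k, (a, b) in self.canonical_bands.items()}
        edges = sorted(bands.values())
        for (a0, b0), (a1, b1) in zip(edges, edges[1:]):
            if a1 <= b0:
                raise ValueError("canonical_bands must be disjoint and ordered")
        self.canonical_bands = bands


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key-value file.

    Unspecified keys take the defaults; unknown keys raise.  The fully
    resolved configuration is logged at INFO level.
    """
    overrides: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        overrides = loaded
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = AnalysisConfig(**overrides)
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg
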