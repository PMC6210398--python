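"""Tapered sliding-window spectral power.

Per epoch and channel, overlapping fixed-length windows (sliding every
50 ms by default) are demeaned, tapered and Fourier transformed; the
per-window power estimates are averaged into one value per epoch, channel
and frequency.  Two band-specific settings cover the low and high ranges:
0.5-s windows with ±2 Hz smoothing for 2–40 Hz and 0.2-s windows with
±14 Hz smoothing for 40–90 Hz.  When the requested smoothing exceeds the
window's native resolution the taper family is a DPSS (multitaper) set
sized to the smoothing bandwidth; otherwise a single Hanning taper is
used.  Output frequencies form a 1-Hz integer grid, each mapped without
interpolation to the window's nearest natural bin.

Power is normalized as variance per bin: summing the estimate over a
window's natural bins recovers the (windowed) signal variance, so a pure
sinusoid of amplitude A carries total power A**2 / 2 in its smoothing
band.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import scipy.signal

from .config import AnalysisConfig
from .io import EpochSet


@dataclass
class PowerSpectra:
    """Per-epoch, per-channel power estimates on an integer frequency grid."""

    power: np.ndarray       # (n_epochs, n_channels, n_freqs), T^2
    freqs: np.ndarray       # Hz
    meta: pd.DataFrame      # condition / block / order_index per epoch
    native_bin: np.ndarray | None = None  # Hz of the natural bin behind each freq

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        from .io import ORDINAL_CODE

        return np.array([ORDINAL_CODE[c] for c in self.meta["condition"]])

    def select_epochs(self, keep) -> "PowerSpectra":
        keep = np.asarray(keep)
        return PowerSpectra(self.power[keep], self.freqs,
                            self.meta.iloc[keep].reset_index(drop=True),
                            self.native_bin)


def taper_family(window_len: float, sfreq: float, smoothing: float) -> np.ndarray:
    """Tapers for a window: DPSS sized to the smoothing half-bandwidth,
    or a single Hanning taper when the smoothing does not exceed the
    window's native resolution (1 / window_len).  Unit-energy rows."""
    nw_samples = int(round(window_len * sfreq))
    time_bandwidth = window_len * smoothing  # NW
    if time_bandwidth > 1.0:
        k = max(1, int(np.floor(2 * time_bandwidth)) - 1)
        tapers = scipy.signal.windows.dpss(nw_samples, time_bandwidth, Kmax=k)
    else:
        h = np.hanning(nw_samples)
        tapers = (h / np.linalg.norm(h))[None, :]
    return tapers


def epoch_power(epochs: EpochSet, cfg: AnalysisConfig | None = None) -> PowerSpectra:
    """Band-specific sliding-window power at 1 Hz resolution.

    Frequencies up to the low-band edge use the long-window setting, the
    rest the short-window setting; both must stay below Nyquist.
    """
    cfg = cfg or AnalysisConfig()
    nyq = epochs.sfreq / 2.0
    lo_f = np.arange(np.ceil(cfg.low_band[0]), np.floor(cfg.low_band[1]) + 1)
    hi_f = np.arange(np.floor(cfg.low_band[1]) + 1,
                     np.floor(min(cfg.high_band[1], nyq - 1)) + 1)
    p_lo, nb_lo = _sliding_power(epochs, cfg.low_window, cfg.slide_step,
                                 cfg.low_smoothing, lo_f)
    if len(hi_f):
        p_hi, nb_hi = _sliding_power(epochs, cfg.high_window, cfg.slide_step,
                                     cfg.high_smoothing, hi_f)
        power = np.concatenate([p_lo, p_hi], axis=2)
        freqs = np.concatenate([lo_f, hi_f])
        native = np.concatenate([nb_lo, nb_hi])
    else:
        power, freqs, native = p_lo, lo_f, nb_lo
    meta = pd.DataFrame({
        "condition": epochs.condition,
        "block": epochs.block,
        "order_index": epochs.order_index,
    })
    return PowerSpectra(power, freqs, meta, native)


def _sliding_power(epochs: EpochSet, window_len: float, step: float,
                   smoothing: float, freqs_out: np.ndarray):
    n_ep, n_ch, n_samp = epochs.data.shape
    nw = int(round(window_len * epochs.sfreq))
    if nw > n_samp:
        raise ValueError("window longer than epoch")
    hop = max(1, int(round(step * epochs.sfreq)))
    tapers = taper_family(window_len, epochs.sfreq, smoothing)   # (K, nw)

    native = np.fft.rfftfreq(nw, 1.0 / epochs.sfreq)
    if freqs_out.max() > epochs.sfreq / 2:
        raise ValueError("requested frequency above Nyquist")
    bins = np.array([int(np.argmin(np.abs(native - f))) for f in freqs_out])
    uniq, inv = np.unique(bins, return_inverse=True)

    # tapered Fourier basis restricted to the needed bins: (K, B, nw)
    n = np.arange(nw)
    phasor = np.exp(-2j * np.pi * uniq[:, None] * n[None, :] / nw)
    basis = tapers[:, None, :] * phasor[None, :, :]
    k_taps, n_bins = basis.shape[0], basis.shape[1]
    flat = basis.reshape(k_taps * n_bins, nw)

    sw = np.lib.stride_tricks.sliding_window_view(
        epochs.data, nw, axis=2)[:, :, ::hop, :]                 # (E,C,W,nw) view
    # project windows on the basis; per-window demeaning folded in via
    # the basis column sums (subtracting the mean shifts each projection
    # by mean * sum(basis))
    spec = sw @ flat.real.T + 1j * (sw @ flat.imag.T)            # (E,C,W,K*B)
    mean_w = sw.mean(axis=-1)
    spec -= mean_w[..., None] * flat.sum(axis=1)[None, None, None, :]
    power = (2.0 / nw) * np.abs(spec) ** 2
    power = power.reshape(*power.shape[:3], k_taps, n_bins)
    acc = power.mean(axis=(2, 3))                                # avg windows+tapers
    return acc[:, :, inv], native[bins]


def n_windows(epoch_len: float, window_len: float, step: float) -> int:
    """Number of sliding windows fitting an epoch (continuous-time count)."""
    return int(np.floor((epoch_len - window_len) / step + 1e-9)) + 1


def band_bin_indices(ps: PowerSpectra, band: tuple[float, float]) -> np.ndarray:
    """Column indices whose spectral estimate belongs to the band.

    The 1-Hz output grid maps without interpolation onto each window's
    natural bins, so neighbouring output frequencies can share one natural
    bin.  Band membership is therefore decided by the natural-bin
    frequency actually estimated, and each natural bin is used once —
    otherwise a bin at a band edge would be double-counted or assigned to
    the wrong band.
    """
    lo, hi = band
    if ps.native_bin is None:
        sel = np.flatnonzero((ps.freqs >= lo) & (ps.freqs <= hi))
        return sel
    idx = []
    seen = set()
    for j, nb in enumerate(ps.native_bin):
        if lo <= nb <= hi and nb not in seen:
            seen.add(nb)
            idx.append(j)
    return np.asarray(idx, dtype=int)


def band_average(ps: PowerSpectra, band: tuple[float, float]) -> np.ndarray:
    """Arithmetic mean power over the inclusive frequency band (E, C)."""
    sel = band_bin_indices(ps, band)
    if len(sel) == 0:
        raise ValueError(f"band {band} contains no frequency bins")
    return ps.power[:, :, sel].mean(axis=2)


def save_spectra(path, ps: PowerSpectra) -> None:
    """HDF5 export of a :class:`PowerSpectra`."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("power", data=ps.power)
        fh.create_dataset("freqs", data=ps.freqs)
        for col in ps.meta.columns:
            v = ps.meta[col].to_numpy()
            if v.dtype.kind in "OU":
                v = v.astype("S")
            fh.create_dataset(f"meta/{col}", data=v)


def load_spectra(path) -> PowerSpectra:
    with h5py.File(path, "r") as fh:
        power = fh["power"][()]
        freqs = fh["freqs"][()]
        meta = {}
        for col in fh["meta"]:
            v = fh[f"meta/{col}"][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            meta[col] = v
    return PowerSpectra(power, freqs, pd.DataFrame(meta))
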