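"""Cleaning and preprocessing: line-noise removal, epoching, artifact-epoch
rejection, ICA component removal, downsampling.

The pipeline order is line-noise removal -> segmentation into nonoverlapping
2-s epochs (discarding a lead-in at the start of every schedule interval)
-> automated artifact-epoch rejection (robust-z jump and high-frequency
metrics) -> ICA with template-correlation component flagging.  ICA is
estimated on data downsampled to 300 Hz for speed, and the resulting
unmixing is applied to the data at its original sampling rate.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal

from .config import AnalysisConfig
from .io import CONDITION_LABELS, REST_LABEL, EpochSet, RawRecording

logger = logging.getLogger(__name__)


def remove_line_noise(rec: RawRecording, line_freq: float | None = None,
                      n_harmonics: int = 1) -> RawRecording:
    """Regress out sinusoids at the line frequency (and harmonics).

    Per channel, a least-squares sine/cosine fit at each harmonic of
    ``line_freq`` is subtracted.  The fit uses an integer number of line
    cycles so the regressors stay orthogonal to the rest of the spectrum:
    broadband content is left intact and a constant-amplitude line
    component is removed essentially exactly.
    """
    if line_freq is None:
        line_freq = 50.0
    if line_freq >= rec.sfreq / 2:
        raise ValueError("line_freq must be below Nyquist")
    t = rec.times
    # largest whole number of line cycles within the record
    n_cycles = np.floor(rec.n_samples / rec.sfreq * line_freq)
    n_fit = min(rec.n_samples, int(round(n_cycles / line_freq * rec.sfreq)))
    cols = []
    for h in range(1, n_harmonics + 1):
        f = h * line_freq
        if f >= rec.sfreq / 2:
            break
        cols += [np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X[:n_fit], rec.data[:, :n_fit].T, rcond=None)
    cleaned = rec.data - (X @ beta).T
    return RawRecording(cleaned, rec.sfreq, rec.sensors, rec.schedule)


def segment_epochs(rec: RawRecording, cfg: AnalysisConfig) -> tuple[EpochSet, EpochSet]:
    """Cut nonoverlapping fixed-length epochs from every schedule interval.

    The first ``cfg.discard_lead_in`` seconds of each interval are dropped
    (state-stabilization time), then ``floor((duration - lead_in) /
    epoch_len)`` epochs are cut.  Graded (SB) and REST epochs are returned
    as two separate sets.  Blocks are numbered by occurrences of SB1.
    """
    nsamp = int(round(cfg.epoch_len * rec.sfreq))
    sb, rest = [], []
    block = -1
    for _, row in rec.schedule.iterrows():
        if row["duration"] < cfg.discard_lead_in + cfg.epoch_len - 1e-9:
            raise ValueError(
                f"interval of {row['duration']} s too short for "
                f"{cfg.discard_lead_in} s lead-in + {cfg.epoch_len} s epoch"
            )
        if row["label"] == CONDITION_LABELS[0]:
            block += 1
        cur_block = max(block, 0)
        start = int(round((row["onset"] + cfg.discard_lead_in) * rec.sfreq))
        n_ep = int(np.floor((row["duration"] - cfg.discard_lead_in) / cfg.epoch_len))
        for k in range(n_ep):
            i0 = start + k * nsamp
            if i0 + nsamp > rec.n_samples:
                break
            entry = {
                "data": rec.data[:, i0:i0 + nsamp],
                "label": row["label"],
                "block": cur_block,
                "start": i0,
            }
            (rest if row["label"] == REST_LABEL else sb).append(entry)
    for entries in (sb, rest):
        counters: dict[int, int] = {}
        for e in entries:
            counters[e["block"]] = counters.get(e["block"], 0) + 1
            e["order"] = counters[e["block"]]

    def build(entries):
        if not entries:
            return EpochSet(np.zeros((0, rec.sensors.n_channels, nsamp)), rec.sfreq,
                            np.array([], dtype=str), np.array([], int),
                            np.array([], int), rec.sensors, np.array([], int))
        return EpochSet(
            np.stack([e["data"] for e in entries]),
            rec.sfreq,
            np.array([e["label"] for e in entries]),
            np.array([e["block"] for e in entries]),
            np.array([e["order"] for e in entries]),
            rec.sensors,
            np.array([e["start"] for e in entries]),
        )

    return build(sb), build(rest)


def _robust_z(v: np.ndarray) -> np.ndarray:
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    scale = 1.4826 * mad if mad > 0 else (v.std() or 1.0)
    return (v - med) / scale


def reject_artifact_epochs(
    epochs: EpochSet, z_thresh: float = 5.0
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs whose jump or muscle metric is a robust-z outlier.

    The jump metric is the maximum absolute first difference over channels
    and samples; the muscle metric is the RMS in a high-frequency band
    (110-140 Hz, capped below Nyquist).  An epoch is rejected when either
    metric exceeds ``z_thresh`` median/MAD z-scores across epochs.
    Returns the retained set and a per-epoch rejection log.
    """
    if epochs.n_epochs < 2:
        raise ValueError("need at least 2 epochs for rejection statistics")
    jump = np.abs(np.diff(epochs.data, axis=2)).max(axis=(1, 2))
    nyq = epochs.sfreq / 2.0
    lo = min(110.0, 0.7 * nyq)
    hi = min(140.0, 0.95 * nyq)
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=epochs.sfreq,
                              output="sos")
    hf = scipy.signal.sosfiltfilt(sos, epochs.data, axis=2)
    muscle = np.sqrt((hf**2).mean(axis=(1, 2)))
    zj, zm = _robust_z(jump), _robust_z(muscle)
    reject = (zj > z_thresh) | (zm > z_thresh)
    log = pd.DataFrame({
        "epoch": np.arange(epochs.n_epochs),
        "jump_z": zj, "muscle_z": zm, "rejected": reject,
    })
    if reject.all():
        raise ValueError("all epochs rejected; raise z_thresh")
    n_rej = int(reject.sum())
    if n_rej:
        logger.info("rejected %d/%d epochs", n_rej, epochs.n_epochs)
    return epochs.select(~reject), log


def downsample(epochs: EpochSet, target_sfreq: float) -> EpochSet:
    """Anti-aliased polyphase resampling to ``target_sfreq``.

    A zero-phase 8th-order Butterworth low-pass at 90% of the new Nyquist
    precedes polyphase resampling, so content above the new Nyquist is
    strongly attenuated.  The (possibly non-integer) rate ratio is
    approximated by a rational number with denominator up to 10^4, which
    is exact for rates such as 1017.25 -> 300 Hz.
    """
    if target_sfreq >= epochs.sfreq:
        raise ValueError("target_sfreq must be below the current rate")
    sos = scipy.signal.butter(8, 0.9 * target_sfreq / 2.0, btype="lowpass",
                              fs=epochs.sfreq, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, epochs.data, axis=2)
    frac = Fraction(target_sfreq / epochs.sfreq).limit_denominator(10_000)
    data = scipy.signal.resample_poly(filtered, frac.numerator,
                                      frac.denominator, axis=2)
    return EpochSet(data, target_sfreq, epochs.condition, epochs.block,
                    epochs.order_index, epochs.sensors, epochs.start_sample)


def slice_to_epochs(series: np.ndarray, epochs: EpochSet) -> np.ndarray:
    """Cut a full-record time course into this set's epochs (concatenated)."""
    if epochs.start_sample is None:
        raise ValueError("epochs carry no start_sample information")
    nsamp = epochs.data.shape[2]
    return np.concatenate([series[s:s + nsamp] for s in epochs.start_sample])


def ica_clean(
    epochs: EpochSet,
    templates: list[np.ndarray] | None = None,
    corr_thresh: float = 0.5,
    downsample_to: float = 300.0,
    seed: int = 0,
    max_iter: int = 500,
    strict: bool = False,
) -> tuple[EpochSet, pd.DataFrame]:
    """Remove artifact components found by ICA.

    The data are decomposed into as many statistically independent
    components as good channels.  The unmixing matrix is estimated on a
    downsampled copy (for speed); components whose downsampled time course
    correlates with any template above ``corr_thresh`` (absolute Pearson)
    are flagged, and the data are reconstructed at the original sampling
    rate from the remaining components.  ``templates`` are full-rate time
    courses aligned with the concatenated epochs (see
    :func:`slice_to_epochs`).  Returns the cleaned set and a component log.

    Non-convergence is retried once with a different seed; if it persists
    the last fit is used with a logged warning (strict=True raises
    instead).  Rotations within a near-Gaussian background subspace have
    no strict fixed point, while the non-Gaussian artifact components
    stabilize early.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    good = epochs.sensors.good_index()
    n_comp = len(good)
    e, _, s = epochs.data.shape
    X = epochs.data[:, good, :].transpose(1, 0, 2).reshape(n_comp, e * s).T

    if downsample_to < epochs.sfreq:
        frac = Fraction(downsample_to / epochs.sfreq).limit_denominator(10_000)
        Xd = scipy.signal.resample_poly(X, frac.numerator, frac.denominator, axis=0)
        ratio = frac.numerator / frac.denominator
    else:
        Xd, ratio = X, 1.0
    if Xd.shape[0] < n_comp:
        raise ValueError("fewer samples than components after downsampling")
    rank = np.linalg.matrix_rank(Xd - Xd.mean(axis=0))
    if rank < n_comp:  # degenerate (e.g. noiseless) data: whitening needs full rank
        logger.warning("data rank %d < %d good channels; reducing components",
                       rank, n_comp)
        n_comp = rank

    ica = None
    for attempt, s_off in enumerate((0, 1)):
        cand = FastICA(n_components=n_comp, whiten="unit-variance",
                       random_state=seed + s_off, max_iter=max_iter, tol=1e-4)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            cand.fit(Xd)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            ica = cand
            break
        ica = cand  # keep the last fit even if not fully converged
        logger.info("FastICA did not converge (attempt %d)", attempt + 1)
    else:
        if strict:
            raise RuntimeError("FastICA failed to converge after retry")
        logger.warning("FastICA did not fully converge; using last fit")

    sources_d = ica.transform(Xd)                       # (n_d, n_comp)
    templates = templates or []
    flagged = np.zeros(n_comp, dtype=bool)
    best_r = np.zeros(n_comp)
    for tpl in templates:
        tpl = np.asarray(tpl, dtype=float)
        if ratio != 1.0:
            tpl = scipy.signal.resample_poly(
                tpl, Fraction(ratio).limit_denominator(10_000).numerator,
                Fraction(ratio).limit_denominator(10_000).denominator)
        m = min(len(tpl), sources_d.shape[0])
        if np.std(tpl[:m]) == 0:
            continue
        r = np.array([
            np.corrcoef(sources_d[:m, k], tpl[:m])[0, 1] for k in range(n_comp)
        ])
        best_r = np.maximum(best_r, np.abs(r))
    flagged = best_r > corr_thresh

    log = pd.DataFrame({
        "component": np.arange(n_comp),
        "max_abs_template_corr": best_r,
        "flagged": flagged,
    })
    logger.info("ICA: %d components, %d flagged", n_comp, int(flagged.sum()))

    # apply the (downsample-estimated) unmixing at the original rate
    sources = (X - ica.mean_) @ ica.components_.T       # (n, n_comp)
    sources[:, flagged] = 0.0
    X_clean = sources @ ica.mixing_.T + ica.mean_
    out = epochs.data.copy()
    out[:, good, :] = X_clean.T.reshape(len(good), e, s).transpose(1, 0, 2)
    cleaned = EpochSet(out, epochs.sfreq, epochs.condition, epochs.block,
                       epochs.order_index, epochs.sensors, epochs.start_sample)
    return cleaned, log
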