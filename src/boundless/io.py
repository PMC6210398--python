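"""Data containers and standard-format I/O.

Recordings travel as FIF (via :mod:`mne`), condition schedules as TSV,
statistical volumes as NIfTI (via :mod:`nibabel`), and simulation ground
truth as JSON.  Coordinates are head-frame meters with the origin at the
conductor-sphere centre; exported volumes are RAS with a millimetre,
half-voxel-centred affine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import mne
import numpy as np
import pandas as pd

from .sensors import SensorArray, orientation_basis

logger = logging.getLogger(__name__)

CONDITION_LABELS = ("SB1", "SB2", "SB3")
REST_LABEL = "REST"
#: ordinal regressor code of each graded condition
ORDINAL_CODE = {"SB1": 1, "SB2": 2, "SB3": 3}


@dataclass
class RawRecording:
    """A continuous multichannel magnetometer recording plus its schedule.

    ``schedule`` is a DataFrame with columns ``onset`` (s), ``duration``
    (s) and ``label`` (SB1/SB2/SB3/REST); intervals must be ordered and
    non-overlapping.
    """

    data: np.ndarray        # (n_channels, n_samples), tesla
    sfreq: float            # Hz
    sensors: SensorArray
    schedule: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.sensors.n_channels:
            raise ValueError("data must be (n_channels, n_samples) matching sensors")
        self.schedule = validate_schedule(self.schedule)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq


@dataclass
class EpochSet:
    """Fixed-length epochs with condition/block/order metadata.

    ``condition`` holds the labels; graded (SB) epochs and rest epochs are
    kept in separate sets.  ``order_index`` is the epoch's temporal rank
    within its block; ``start_sample`` its onset in the source recording.
    """

    data: np.ndarray            # (n_epochs, n_channels, n_samples)
    sfreq: float
    condition: np.ndarray       # (n_epochs,) str labels
    block: np.ndarray           # (n_epochs,) int
    order_index: np.ndarray     # (n_epochs,) int, temporal rank within block
    sensors: SensorArray
    start_sample: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        self.condition = np.asarray(self.condition)
        self.block = np.asarray(self.block, dtype=int)
        self.order_index = np.asarray(self.order_index, dtype=int)
        n = len(self.data)
        for name in ("condition", "block", "order_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per epoch")
        labels = set(np.unique(self.condition))
        if REST_LABEL in labels and labels != {REST_LABEL}:
            raise ValueError("rest epochs must be stored separately from SB epochs")
        if self.start_sample is not None:
            self.start_sample = np.asarray(self.start_sample, dtype=int)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def x(self) -> np.ndarray:
        """Ordinal condition codes 1..3 (SB epochs only)."""
        return np.array([ORDINAL_CODE[c] for c in self.condition])

    def select(self, keep: np.ndarray) -> "EpochSet":
        keep = np.asarray(keep)
        return EpochSet(
            self.data[keep], self.sfreq, self.condition[keep], self.block[keep],
            self.order_index[keep], self.sensors,
            None if self.start_sample is None else self.start_sample[keep],
        )


def validate_schedule(schedule: pd.DataFrame) -> pd.DataFrame:
    sched = pd.DataFrame(schedule).reset_index(drop=True)
    required = {"onset", "duration", "label"}
    if not required <= set(sched.columns):
        raise ValueError(f"schedule needs columns {sorted(required)}")
    if (sched["duration"] <= 0).any():
        raise ValueError("schedule durations must be positive")
    bad = set(sched["label"]) - set(CONDITION_LABELS) - {REST_LABEL}
    if bad:
        raise ValueError(f"unknown schedule labels: {sorted(bad)}")
    onsets = sched["onset"].to_numpy(float)
    ends = onsets + sched["duration"].to_numpy(float)
    if not np.all(np.diff(onsets) > 0):
        raise ValueError("schedule intervals must be ordered by onset")
    if np.any(onsets[1:] < ends[:-1] - 1e-9):
        raise ValueError("schedule intervals must not overlap")
    return sched


def read_schedule(path: str | Path) -> pd.DataFrame:
    """Read an onset/duration/label TSV schedule."""
    return validate_schedule(pd.read_csv(path, sep="\t"))


def write_schedule(schedule: pd.DataFrame, path: str | Path) -> None:
    validate_schedule(schedule).to_csv(path, sep="\t", index=False)


def _info_from_sensors(sensors: SensorArray, sfreq: float) -> mne.Info:
    info = mne.create_info(sensors.channel_names, sfreq, ch_types="mag")
    ex, ey = orientation_basis(sensors.orientations)
    for i, ch in enumerate(info["chs"]):
        loc = np.zeros(12)
        loc[0:3] = sensors.positions[i]
        loc[3:6] = ex[i]
        loc[6:9] = ey[i]
        loc[9:12] = sensors.orientations[i]
        ch["loc"] = loc
        ch["coil_type"] = mne.io.constants.FIFF.FIFFV_COIL_POINT_MAGNETOMETER
    with info._unlock():
        info["bads"] = list(sensors.bad_channels)
    return info


def _sensors_from_info(info: mne.Info) -> SensorArray:
    positions = np.array([ch["loc"][0:3] for ch in info["chs"]])
    orientations = np.array([ch["loc"][9:12] for ch in info["chs"]])
    return SensorArray(
        list(info["ch_names"]), positions, orientations, list(info["bads"])
    )


def write_raw(rec: RawRecording, path: str | Path, schedule_path: str | Path | None = None) -> None:
    """Write a recording to FIF (and optionally its schedule to TSV)."""
    info = _info_from_sensors(rec.sensors, rec.sfreq)
    raw = mne.io.RawArray(rec.data, info, verbose="error")
    raw.save(str(path), overwrite=True, verbose="error")
    if schedule_path is not None:
        write_schedule(rec.schedule, schedule_path)


def read_raw(path: str | Path, schedule_path: str | Path) -> RawRecording:
    """Read a magnetometer FIF recording and its TSV schedule.

    Non-magnetometer channels are dropped with a logged warning; a file
    with no magnetometer channels raises.
    """
    raw = mne.io.read_raw_fif(str(path), preload=True, verbose="error")
    picks = mne.pick_types(raw.info, meg="mag", ref_meg=False, exclude=[])
    if len(picks) == 0:
        raise ValueError(f"{path} contains no magnetometer channels")
    if len(picks) < len(raw.ch_names):
        dropped = [nm for i, nm in enumerate(raw.ch_names) if i not in set(picks)]
        logger.warning("dropping %d non-magnetometer channels: %s", len(dropped), dropped)
        raw.pick([raw.ch_names[i] for i in picks])
    sensors = _sensors_from_info(raw.info)
    schedule = read_schedule(schedule_path)
    return RawRecording(raw.get_data(), raw.info["sfreq"], sensors, schedule)


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to FIF with its metadata table."""
    info = _info_from_sensors(epochs.sensors, epochs.sfreq)
    labels = sorted(set(epochs.condition))
    event_id = {lab: k + 1 for k, lab in enumerate(labels)}
    events = np.column_stack([
        np.arange(epochs.n_epochs) * epochs.data.shape[2],
        np.zeros(epochs.n_epochs, int),
        [event_id[c] for c in epochs.condition],
    ])
    ep = mne.EpochsArray(epochs.data, info, events=events, event_id=event_id,
                         tmin=0.0, verbose="error")
    ep.metadata = pd.DataFrame({
        "condition": epochs.condition,
        "block": epochs.block,
        "order_index": epochs.order_index,
        "start_sample": (np.full(epochs.n_epochs, -1)
                         if epochs.start_sample is None else epochs.start_sample),
    })
    ep.save(str(path), overwrite=True, verbose="error")


def read_epochs(path: str | Path) -> EpochSet:
    ep = mne.read_epochs(str(path), preload=True, verbose="error")
    sensors = _sensors_from_info(ep.info)
    md = ep.metadata
    start = md["start_sample"].to_numpy(int)
    return EpochSet(
        ep.get_data(copy=True), ep.info["sfreq"],
        md["condition"].to_numpy(), md["block"].to_numpy(int),
        md["order_index"].to_numpy(int), sensors,
        None if (start < 0).all() else start,
    )


def write_stat_volume(values: np.ndarray, grid, path: str | Path) -> None:
    """Write per-voxel values on a :class:`~boundless.forward.SourceGrid` as NIfTI.

    ``values`` may cover either all lattice points or only inside voxels;
    outside voxels are written as NaN.  The affine is diagonal with the
    grid spacing in millimetres and the origin at voxel (0, 0, 0).
    """
    import nibabel as nib

    values = np.asarray(values, dtype=float)
    full = np.full(len(grid.positions), np.nan)
    if values.shape == (len(grid.positions),):
        full = np.where(grid.inside_mask, values, np.nan)
    elif values.shape == (grid.n_inside,):
        full[grid.inside_mask] = values
    else:
        raise ValueError("values must match the grid (all points or inside voxels)")
    vol = full.reshape(grid.shape).astype(np.float32)
    affine = np.diag([grid.spacing * 1e3] * 3 + [1.0])
    affine[:3, 3] = grid.origin * 1e3
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def read_stat_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI stat volume; returns (data array, affine)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return super().default(obj)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=_NumpyJSONEncoder, indent=1)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
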