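"""Spherical-conductor dipole forward model.

The magnetic field of a current dipole inside a homogeneous conducting
sphere has a closed form (Sarvas): with the sensor at ``r`` and the dipole
moment ``q`` at ``r0`` (both relative to the sphere centre),

    B(r) = mu0 / (4 pi F^2) * ( F (q x r0) - ((q x r0) . r) grad F ),

    a = r - r0,  F = |a| (|r||a| + |r|^2 - r0 . r),

which is independent of the sphere radius and conductivity.  Two analytic
properties anchor the implementation: a radially oriented dipole produces
no external field, and the field is linear in the dipole moment.  Sensors
are point magnetometers — the reading is the projection of B on the sensor
orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .sensors import SensorArray

MU0_OVER_4PI = 1e-7  # T m / (A m)


@dataclass
class SourceGrid:
    """Regular axis-aligned lattice of candidate source locations.

    ``positions`` enumerates every lattice point in C order over the
    ``shape`` of the bounding box; ``inside_mask`` marks the points lying
    strictly inside the conductor sphere minus ``margin``.
    """

    positions: np.ndarray       # (n_points, 3) meters
    shape: tuple[int, int, int]
    origin: np.ndarray          # (3,) position of voxel (0,0,0), meters
    spacing: float              # meters
    inside_mask: np.ndarray     # (n_points,) bool
    sphere_center: np.ndarray   # (3,)
    sphere_radius: float        # meters
    margin: float = 0.0

    @property
    def n_inside(self) -> int:
        return int(self.inside_mask.sum())

    @property
    def inside_positions(self) -> np.ndarray:
        return self.positions[self.inside_mask]


@dataclass
class DipoleSpec:
    """A current dipole: position (m), unit orientation, moment series (A m)."""

    position: np.ndarray
    orientation: np.ndarray
    moment_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        nrm = np.linalg.norm(self.orientation)
        if not np.isclose(nrm, 1.0, atol=1e-9):
            raise ValueError("dipole orientation must be unit norm")


def dipole_field(
    position: np.ndarray,
    moment: np.ndarray,
    sensors: SensorArray,
    sphere_center: np.ndarray = (0.0, 0.0, 0.0),
    sphere_radius: float | None = None,
) -> np.ndarray:
    """Sensor readings (T) of a current dipole in a homogeneous sphere.

    Parameters
    ----------
    position : (3,) array
        Dipole location, meters.  Must be strictly inside the sphere when
        ``sphere_radius`` is given.
    moment : (3,) array
        Dipole moment, A m (need not be unit norm).
    sensors : SensorArray
        Point magnetometers; must lie strictly outside the sphere.
    sphere_center : (3,) array
        Conductor sphere centre.
    sphere_radius : float, optional
        If given, used only to validate the geometry (the field itself does
        not depend on it).
    """
    c = np.asarray(sphere_center, dtype=float)
    r0 = np.asarray(position, dtype=float) - c
    q = np.asarray(moment, dtype=float)
    r = sensors.positions - c
    if sphere_radius is not None:
        if np.linalg.norm(r0) >= sphere_radius:
            raise ValueError("dipole must lie strictly inside the sphere")
        if np.any(np.linalg.norm(r, axis=1) <= sphere_radius):
            raise ValueError("sensors must lie strictly outside the sphere")
    a_vec = r - r0                                    # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)                 # (n,)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a == 0):
        raise ValueError("sensor coincides with the dipole")
    ar = np.einsum("ij,ij->i", a_vec, r)
    r0r = r @ r0
    F = a * (rn * a + rn**2 - r0r)
    gradF = (
        (a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, None] * r
        - (a + 2.0 * rn + ar / a)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * qxr0 - (r @ qxr0)[:, None] * gradF)
    return np.einsum("ij,ij->i", B, sensors.orientations)


def build_grid(
    sphere_center: np.ndarray,
    sphere_radius: float,
    spacing: float = 0.01,
    margin: float = 0.005,
) -> SourceGrid:
    """Regular lattice spanning the sphere's bounding box.

    Voxels with ``|p - center| < radius - margin`` are marked inside.  A
    spacing larger than the sphere admits no inside voxels (warning).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    c = np.asarray(sphere_center, dtype=float)
    # lattice anchored at the bounding-box corner (passes through the
    # centre whenever the radius is a multiple of the spacing)
    n_axis = int(np.floor(2 * sphere_radius / spacing)) + 1
    ax = -sphere_radius + np.arange(n_axis) * spacing
    shape = (len(ax),) * 3
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    positions = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + c
    dist = np.linalg.norm(positions - c, axis=1)
    inside = dist < sphere_radius - margin
    if not inside.any():
        warnings.warn("no voxels inside the sphere at this spacing", stacklevel=2)
    return SourceGrid(
        positions=positions,
        shape=shape,
        origin=c + np.array([ax[0]] * 3),
        spacing=spacing,
        inside_mask=inside,
        sphere_center=c,
        sphere_radius=sphere_radius,
        margin=margin,
    )


def leadfields(grid: SourceGrid, sensors: SensorArray) -> np.ndarray:
    """Lead fields for every inside voxel.

    Returns an array of shape (n_inside, 3, n_channels): column ``k`` of
    voxel ``v`` is the sensor reading of a unit dipole along axis ``k``.
    """
    pos = grid.inside_positions
    lf = np.empty((len(pos), 3, sensors.n_channels))
    eye = np.eye(3)
    for v, p in enumerate(pos):
        for k in range(3):
            lf[v, k] = dipole_field(p, eye[k], sensors, grid.sphere_center)
    return lf


def lattice_adjacency(grid: SourceGrid):
    """6-connected adjacency over the inside voxels (scipy CSR, bool)."""
    import scipy.sparse as sp

    idx3 = np.argwhere(grid.inside_mask.reshape(grid.shape))
    index_of = {tuple(v): i for i, v in enumerate(idx3)}
    rows, cols = [], []
    for i, v in enumerate(idx3):
        for axis in range(3):
            for step in (-1, 1):
                w = v.copy()
                w[axis] += step
                j = index_of.get(tuple(w))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
    n = len(idx3)
    return sp.csr_matrix(
        (np.ones(len(rows), bool), (rows, cols)), shape=(n, n)
    )


def save_leadfields(path, lf: np.ndarray, grid: SourceGrid, sensors: SensorArray) -> None:
    """Export lead fields (voxels x 3 x channels) to an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("leadfields", data=lf)
        fh.create_dataset("voxel_positions", data=grid.inside_positions)
        fh.create_dataset("channel_names", data=np.array(sensors.channel_names, dtype="S"))
        fh.attrs["spacing"] = grid.spacing
        fh.attrs["sphere_radius"] = grid.sphere_radius
        fh.attrs["sphere_center"] = grid.sphere_center
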