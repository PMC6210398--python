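"""Magnetometer array geometry.

A whole-head magnetometer array is modelled as a set of point sensors on a
spherical cap above the conductor sphere, each with a position (head frame,
meters, origin at the sphere centre) and a unit orientation along which the
magnetic field is measured.  A symmetric, irreflexive neighbourhood graph
over channels supports cluster-based statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


@dataclass
class SensorArray:
    """Magnetometer geometry: names, positions, orientations, neighbours.

    Parameters
    ----------
    channel_names : list of str
        One name per channel.
    positions : (n_channels, 3) float array
        Sensor positions in meters, head frame (origin at sphere centre).
    orientations : (n_channels, 3) float array
        Unit vectors; the sensor reads the field component along this axis.
    bad_channels : list of str
        Subset of ``channel_names`` flagged as unusable.
    neighbor_graph : scipy.sparse matrix, (n_channels, n_channels)
        Symmetric, irreflexive adjacency (boolean).
    """

    channel_names: list[str]
    positions: np.ndarray
    orientations: np.ndarray
    bad_channels: list[str] = field(default_factory=list)
    neighbor_graph: sp.spmatrix | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        n = len(self.channel_names)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_channels, 3)")
        if self.orientations.shape != (n, 3):
            raise ValueError("orientations must be (n_channels, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must have unit norm (within 1e-9)")
        unknown = set(self.bad_channels) - set(self.channel_names)
        if unknown:
            raise ValueError(f"bad_channels not in channel_names: {sorted(unknown)}")
        if self.neighbor_graph is None:
            self.neighbor_graph = neighbor_graph(self.positions)
        g = sp.csr_matrix(self.neighbor_graph, dtype=bool)
        if (g != g.T).nnz != 0:
            raise ValueError("neighbor_graph must be symmetric")
        if g.diagonal().any():
            raise ValueError("neighbor_graph must be irreflexive")
        self.neighbor_graph = g

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def good_index(self) -> np.ndarray:
        """Indices of channels not flagged bad."""
        bad = set(self.bad_channels)
        return np.array(
            [i for i, nm in enumerate(self.channel_names) if nm not in bad], dtype=int
        )

    def subset(self, idx: np.ndarray) -> "SensorArray":
        """Restrict the array (and its graph) to the given channel indices."""
        idx = np.asarray(idx, dtype=int)
        names = [self.channel_names[i] for i in idx]
        g = self.neighbor_graph.tocsr()[idx][:, idx]
        bad = [b for b in self.bad_channels if b in names]
        return SensorArray(names, self.positions[idx], self.orientations[idx], bad, g)


def neighbor_graph(positions: np.ndarray, scale: float = 1.6) -> sp.csr_matrix:
    """Distance-threshold adjacency over sensor positions.

    Two channels are neighbours when their separation is below ``scale``
    times the median nearest-neighbour distance of the layout.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2:
        return sp.csr_matrix((n, n), dtype=bool)
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    thresh = scale * np.median(d.min(axis=1))
    adj = d < thresh
    return sp.csr_matrix(adj)


def fibonacci_cap_array(
    n_channels: int = 248,
    shell_radius: float = 0.102,
    cap_fraction: float = 0.62,
    prefix: str = "MEG",
) -> SensorArray:
    """Quasi-uniform point-magnetometer layout on a spherical cap.

    A Fibonacci lattice on the upper ``cap_fraction`` of a sphere of radius
    ``shell_radius`` (meters), with radial orientations — a stand-in for a
    dense whole-head magnetometer helmet.
    """
    i = np.arange(n_channels)
    # z from top (=1) down to 1 - 2*cap_fraction
    z = 1.0 - (i + 0.5) / n_channels * 2.0 * cap_fraction
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    units = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    positions = shell_radius * units
    names = [f"{prefix}{k + 1:03d}" for k in range(n_channels)]
    return SensorArray(names, positions, units)


def orientation_basis(ez: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed (ex, ey) completing a unit vector ez, per row."""
    ez = np.asarray(ez, dtype=float)
    ref = np.tile([0.0, 0.0, 1.0], (len(ez), 1))
    near_pole = np.abs(ez[:, 2]) > 0.9
    ref[near_pole] = [1.0, 0.0, 0.0]
    ex = np.cross(ref, ez)
    ex /= np.linalg.norm(ex, axis=1, keepdims=True)
    ey = np.cross(ez, ex)
    return ex, ey
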