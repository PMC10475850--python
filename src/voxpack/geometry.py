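"""Voxel grid geometry and backbone reference-frame alignment.

The energy engine works on a cube of side ``dbox`` = 22 A centred on the
residue's Calpha, discretized into 44x44x44 voxels of 0.5 A.  All rotamer
field tensors and environment projections share this geometry.  The backbone
frame places Calpha at the origin, the Calpha->Cbeta vector along +z, and
the Calpha->N vector in the xz half-plane with positive x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of the voxelized simulation cube."""

    dbox: float = 22.0          #: cube side (A)
    voxel: float = 0.5          #: voxel edge (A)
    clr: float = 7.0            #: long-range cutoff for LJ/electrostatics (A)
    csoft: float = 0.25         #: width of the soft repulsive LJ band (A)
    crust: float = 0.5          #: vdW inflation for the solvation crust (A)

    def __post_init__(self):
        dims = self.dbox / self.voxel
        if abs(dims - round(dims)) > 1e-9:
            raise ValueError("dbox must be an integer multiple of voxel")
        if not self.clr < self.dbox / 2:
            raise ValueError("cutoff must fit inside the half-box")

    @property
    def dims(self) -> int:
        return int(round(self.dbox / self.voxel))

    @property
    def n_voxels(self) -> int:
        return self.dims ** 3

    @property
    def rbar(self) -> float:
        """Cube-average interatomic distance (A), 0.6617 * dbox."""
        from .constants import RBAR_FACTOR
        return RBAR_FACTOR * self.dbox

    def voxel_indices(self, coords: np.ndarray) -> np.ndarray:
        """Per-axis voxel index of each coordinate: floor((x + dbox/2)/voxel).

        Indices may fall outside [0, dims); use :meth:`in_box` to filter.
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return np.floor((coords + self.dbox / 2.0) / self.voxel).astype(np.int64)

    def in_box(self, idx: np.ndarray) -> np.ndarray:
        """Boolean mask of per-axis index triples inside the grid.

        Half-open cells: atoms exactly on the + boundary are excluded.
        """
        idx = np.atleast_2d(idx)
        return np.all((idx >= 0) & (idx < self.dims), axis=1)

    def flat_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        d = self.dims
        return idx[:, 0] * d * d + idx[:, 1] * d + idx[:, 2]

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel centre coordinates, flat C order."""
        return _centers_cache(self)

    def center_of(self, idx: np.ndarray) -> np.ndarray:
        """Centre coordinates of per-axis index triples."""
        idx = np.atleast_2d(idx)
        return -self.dbox / 2.0 + (idx + 0.5) * self.voxel

    def snap(self, coords: np.ndarray) -> np.ndarray:
        """Snap coordinates to the centre of their voxel."""
        return self.center_of(self.voxel_indices(coords))


_CENTERS: dict[tuple, np.ndarray] = {}


def _centers_cache(geom: GridGeometry) -> np.ndarray:
    key = (geom.dbox, geom.voxel)
    if key not in _CENTERS:
        d = geom.dims
        ax = -geom.dbox / 2.0 + (np.arange(d) + 0.5) * geom.voxel
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        _CENTERS[key] = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return _CENTERS[key]


class CollinearFrameError(ValueError):
    """Frame atoms are collinear; no backbone frame can be defined."""


def frame_transform(ca, cbeta, n):
    """Rigid transform (R, t) mapping world coordinates into the backbone
    frame: x_frame = R @ (x - ca).

    Calpha maps to the origin, Calpha->Cbeta to +z, and Calpha->N into the
    xz half-plane with positive x.  R is a proper rotation (det +1).
    """
    ca = np.asarray(ca, dtype=float)
    w = np.asarray(cbeta, dtype=float) - ca
    nw = np.linalg.norm(w)
    vn = np.asarray(n, dtype=float) - ca
    if nw < 1e-8 or np.linalg.norm(vn) < 1e-8:
        raise CollinearFrameError("degenerate frame atoms")
    w = w / nw
    u = vn - np.dot(vn, w) * w
    nu = np.linalg.norm(u)
    if nu < 1e-8:
        raise CollinearFrameError("Calpha->N collinear with Calpha->Cbeta")
    u = u / nu
    v = np.cross(w, u)
    rot = np.vstack([u, v, w])
    return rot, ca


def align_to_frame(coords: np.ndarray, ca, cbeta, n) -> np.ndarray:
    """Map coordinates into the backbone frame defined by (ca, cbeta, n)."""
    rot, origin = frame_transform(ca, cbeta, n)
    coords = np.asarray(coords, dtype=float)
    return (coords - origin) @ rot.T


def from_frame(coords: np.ndarray, ca, cbeta, n) -> np.ndarray:
    """Inverse of :func:`align_to_frame`: frame coordinates -> world."""
    rot, origin = frame_transform(ca, cbeta, n)
    coords = np.asarray(coords, dtype=float)
    return coords @ rot + origin
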