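"""Density-map container, MRC2014 I/O and trilinear interpolation.

Real-space convention: coordinates are in Å throughout; the centre of voxel
``(0, 0, 0)`` sits at :attr:`DensityMap.origin` and voxel ``(i, j, k)`` at
``origin + (i, j, k) * voxel_size``.  Internal arrays are always indexed
``(x, y, z)`` with x the first axis, whatever axis permutation the file used.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import gemmi
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "DensityMap",
    "MapFormatError",
    "read_density_map",
    "write_density_map",
    "trilinear_value",
    "trilinear_value_and_gradient",
    "resample_to",
]


class MapFormatError(ValueError):
    """Raised when an MRC header field is malformed or unsupported."""


@dataclasses.dataclass
class DensityMap:
    """A 3-D scalar grid with voxel size and real-space origin.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Map intensities in arbitrary map units.
    voxel_size : array-like of 3 floats
        Per-axis voxel edge length in Å (anisotropic voxels allowed).
    origin : array-like of 3 floats
        Real-space position (Å) of the centre of voxel (0, 0, 0).
    global_resolution : float, optional
        User-supplied global resolution of the map in Å.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    global_resolution: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3).copy()
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise MapFormatError("values must be a 3-D array")
        if any(n < 2 for n in self.values.shape):
            raise MapFormatError("map must have at least 2 voxels per axis")
        if not np.all(np.isfinite(self.voxel_size)) or np.any(self.voxel_size <= 0):
            raise MapFormatError("voxel_size components must be positive and finite")
        if not np.all(np.isfinite(self.origin)):
            raise MapFormatError("origin must be finite")
        if not np.all(np.isfinite(self.values)):
            raise MapFormatError("map values contain NaN/Inf")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Real-space coordinates (Å) of voxel centres along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def point_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of real-space points (Å)."""
        return (np.asarray(points, dtype=np.float64) - self.origin) / self.voxel_size

    def index_to_point(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=np.float64) * self.voxel_size + self.origin

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners in Å of the voxel-centre lattice."""
        hi = self.origin + (np.array(self.shape) - 1) * self.voxel_size
        return self.origin.copy(), hi

    def like(self, values: np.ndarray) -> "DensityMap":
        """A new map sharing this grid geometry with different values."""
        return DensityMap(
            values=np.asarray(values, dtype=np.float64),
            voxel_size=self.voxel_size,
            origin=self.origin,
            global_resolution=self.global_resolution,
        )

    def empty_like(self) -> "DensityMap":
        return self.like(np.zeros(self.shape))

    def copy(self) -> "DensityMap":
        return self.like(self.values.copy())


def _axis_order(mapc: int, mapr: int, maps: int) -> list[int]:
    order = [mapc, mapr, maps]
    if sorted(order) != [1, 2, 3]:
        raise MapFormatError(
            f"mapc/mapr/maps must be a permutation of 1,2,3; got {order}"
        )
    return [a - 1 for a in order]


def read_density_map(
    path: str | Path, global_resolution: float | None = None
) -> DensityMap:
    """Read an MRC2014 map, normalising axis order to (x, y, z).

    The real-space origin is taken from the ORIGIN header record if any
    component is non-zero, otherwise from ``nstart × voxel_size``.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi message
        raise MapFormatError(f"cannot read MRC file {path}: {exc}") from exc

    # raw header fields, before axis normalisation
    crs_to_xyz = _axis_order(m.header_i32(17), m.header_i32(18), m.header_i32(19))
    nstart_crs = [m.header_i32(5), m.header_i32(6), m.header_i32(7)]
    origin_rec = np.array([m.header_float(i) for i in (50, 51, 52)])
    mxyz = np.array([m.header_i32(8), m.header_i32(9), m.header_i32(10)])
    cella = np.array([m.header_float(11), m.header_float(12), m.header_float(13)])
    if np.any(mxyz <= 0):
        raise MapFormatError(f"mx/my/mz must be positive; got {mxyz.tolist()}")
    if np.any(cella <= 0) or not np.all(np.isfinite(cella)):
        raise MapFormatError(f"cella lengths must be positive; got {cella.tolist()}")
    voxel = cella / mxyz

    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True)

    if np.any(origin_rec != 0.0):
        origin = origin_rec.astype(np.float64)
    else:
        nstart_xyz = np.zeros(3)
        for crs, axis in enumerate(crs_to_xyz):
            nstart_xyz[axis] = nstart_crs[crs]
        origin = nstart_xyz * voxel
    if not np.all(np.isfinite(values)):
        raise MapFormatError("map values contain NaN/Inf")
    return DensityMap(
        values=values,
        voxel_size=voxel,
        origin=origin,
        global_resolution=global_resolution,
    )


def write_density_map(dmap: DensityMap, path: str | Path) -> None:
    """Write a map as MRC2014 mode 2 (float32), canonical axis order."""
    dmap.validate()
    nx, ny, nz = dmap.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    arr = np.array(grid, copy=False)
    arr[...] = dmap.values.astype(np.float32)
    cell = gemmi.UnitCell(
        nx * dmap.voxel_size[0],
        ny * dmap.voxel_size[1],
        nz * dmap.voxel_size[2],
        90.0,
        90.0,
        90.0,
    )
    grid.set_unit_cell(cell)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


def _gather_corners(values: np.ndarray, i0: np.ndarray) -> np.ndarray:
    """The 8 corner values around base index i0 (N,3) -> (N,2,2,2)."""
    out = np.empty((i0.shape[0], 2, 2, 2), dtype=np.float64)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                out[:, dx, dy, dz] = values[
                    i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz
                ]
    return out


def _trilinear_prep(
    dmap: DensityMap, points: np.ndarray, outside: str
) -> tuple[np.ndarray, np.ndarray]:
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    t = dmap.point_to_index(pts)
    n = np.array(dmap.shape)
    if outside == "error":
        if np.any(t < -1e-9) or np.any(t > n - 1 + 1e-9):
            raise ValueError("point outside grid bounding box")
    elif outside != "clamp":
        raise ValueError("outside must be 'clamp' or 'error'")
    else:
        if np.any(t < 0) or np.any(t > n - 1):
            log.debug("trilinear_value: point(s) outside grid clamped to edge")
    t = np.clip(t, 0.0, n - 1)
    i0 = np.minimum(t.astype(np.int64), n - 2)
    frac = t - i0
    return i0, frac


def trilinear_value(
    dmap: DensityMap, points: np.ndarray, outside: str = "clamp"
) -> np.ndarray | float:
    """Trilinear interpolation of the map at real-space points (Å).

    ``points`` may be a single (3,) position or an (N, 3) array.  Points
    outside the voxel-centre bounding box are clamped to the edge by
    default (``outside='clamp'``) or rejected (``outside='error'``).
    """
    scalar = np.asarray(points).ndim == 1
    i0, f = _trilinear_prep(dmap, points, outside)
    c = _gather_corners(dmap.values, i0)
    wx = np.stack([1 - f[:, 0], f[:, 0]], axis=1)
    wy = np.stack([1 - f[:, 1], f[:, 1]], axis=1)
    wz = np.stack([1 - f[:, 2], f[:, 2]], axis=1)
    vals = np.einsum("na,nb,nc,nabc->n", wx, wy, wz, c)
    return float(vals[0]) if scalar else vals


def trilinear_value_and_gradient(
    dmap: DensityMap, points: np.ndarray, outside: str = "clamp"
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated values and their analytic spatial gradient (per Å).

    The gradient is the exact derivative of the trilinear interpolant,
    i.e. the derivative of the corner weights divided by the voxel size.
    At clamped points the gradient of the clamped interpolant is returned
    (zero in the clamped direction).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    i0, f = _trilinear_prep(dmap, pts, outside)
    c = _gather_corners(dmap.values, i0)
    w = [np.stack([1 - f[:, a], f[:, a]], axis=1) for a in range(3)]
    d = [np.stack([-np.ones(len(pts)), np.ones(len(pts))], axis=1) for _ in range(3)]
    vals = np.einsum("na,nb,nc,nabc->n", w[0], w[1], w[2], c)
    grad = np.empty_like(pts)
    grad[:, 0] = np.einsum("na,nb,nc,nabc->n", d[0], w[1], w[2], c) / dmap.voxel_size[0]
    grad[:, 1] = np.einsum("na,nb,nc,nabc->n", w[0], d[1], w[2], c) / dmap.voxel_size[1]
    grad[:, 2] = np.einsum("na,nb,nc,nabc->n", w[0], w[1], d[2], c) / dmap.voxel_size[2]
    return vals, grad


def resample_to(src: DensityMap, target: DensityMap, fill: float = 0.0) -> DensityMap:
    """Resample ``src`` onto the grid of ``target`` by trilinear interpolation.

    Voxels of the target grid outside the source bounding box get ``fill``.
    """
    coords = [
        (target.axis_coords(a) - src.origin[a]) / src.voxel_size[a] for a in range(3)
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    vals = ndimage.map_coordinates(
        src.values, np.stack(grid), order=1, mode="constant", cval=fill
    )
    return target.like(vals)
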