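"""Minimal struct-based MRC2014 reader/writer used only as an independent
cross-check of the gemmi-backed map I/O (second implementation, test-only)."""

from __future__ import annotations

import struct

import numpy as np


def write_mrc(path, data_xyz, voxel, origin, axis_order=(1, 2, 3)):
    """Write an MRC2014 mode-2 file; ``axis_order`` gives the xyz axis
    (1-based) stored as columns/rows/sections, allowing permuted files."""
    data_xyz = np.asarray(data_xyz, dtype=np.float32)
    nx, ny, nz = data_xyz.shape
    perm = [a - 1 for a in axis_order]
    dims = [data_xyz.shape[p] for p in perm]
    h = bytearray(1024)
    struct.pack_into("<3i", h, 0, *dims)
    struct.pack_into("<i", h, 12, 2)  # mode 2: float32
    struct.pack_into("<3i", h, 16, 0, 0, 0)  # nstart
    struct.pack_into("<3i", h, 28, nx, ny, nz)  # mx my mz
    struct.pack_into(
        "<3f", h, 40, nx * voxel[0], ny * voxel[1], nz * voxel[2]
    )  # cella
    struct.pack_into("<3f", h, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", h, 64, *axis_order)  # mapc mapr maps
    struct.pack_into(
        "<3f", h, 76, float(data_xyz.min()), float(data_xyz.max()), float(data_xyz.mean())
    )
    struct.pack_into("<i", h, 92, 0)  # ispg
    struct.pack_into("<3f", h, 196, *origin)
    h[208:212] = b"MAP "
    h[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian machine stamp
    struct.pack_into("<f", h, 216, float(data_xyz.std()))
    arr = np.transpose(data_xyz, perm)  # (col,row,sec) indexing
    out = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)).astype("<f4"))
    with open(path, "wb") as f:
        f.write(h)
        f.write(out.tobytes())


def read_mrc(path):
    """Read an MRC file back to canonical (x, y, z) order.

    Returns (values, voxel_size, origin, header_stats) with header_stats =
    (dmin, dmax, dmean) as stored in the file.
    """
    with open(path, "rb") as f:
        h = f.read(1024)
        raw = f.read()
    ncrs = struct.unpack_from("<3i", h, 0)
    mode = struct.unpack_from("<i", h, 12)[0]
    assert mode == 2, f"oracle only reads mode 2, got {mode}"
    mxyz = struct.unpack_from("<3i", h, 28)
    cella = struct.unpack_from("<3f", h, 40)
    axis_order = struct.unpack_from("<3i", h, 64)
    stats = struct.unpack_from("<3f", h, 76)
    origin = np.array(struct.unpack_from("<3f", h, 196))
    voxel = np.array(cella) / np.array(mxyz)
    data = np.frombuffer(raw, dtype="<f4", count=ncrs[0] * ncrs[1] * ncrs[2])
    data = data.reshape(ncrs[2], ncrs[1], ncrs[0]).transpose(2, 1, 0)  # (c,r,s)
    perm = [a - 1 for a in axis_order]
    inv = np.argsort(perm)
    values = np.transpose(data, inv)
    return values, voxel, origin, stats
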