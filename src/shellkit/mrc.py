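"""Minimal MRC2014 / CCP4 volume reader and writer.

Only what the pipeline needs: modes 0 (int8), 1 (int16) and 2 (float32),
isotropic voxels, and normalisation of the MAPC/MAPR/MAPS axis-order
dialects to a fixed ``grid[ix, iy, iz]`` convention.  Written files are
always mode 2 with MAPC/MAPR/MAPS = 1/2/3 and the physical origin stored in
the MRC2014 ORIGIN header field.
"""

from __future__ import annotations

import struct

import numpy as np

HEADER_SIZE = 1024

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32}


class MrcParseError(ValueError):
    """Raised for truncated or malformed MRC files."""


class UnsupportedGridError(ValueError):
    """Raised for anisotropic voxels (>1%) or unsupported data modes."""


def read_mrc(path):
    """Read a volume; returns ``(grid, voxel_size, origin)``.

    ``grid`` is indexed ``[ix, iy, iz]`` so that the centre of voxel
    ``(i, j, k)`` sits at ``origin + voxel_size * (i, j, k)`` (Å).
    """
    with open(path, "rb") as fh:
        header = fh.read(HEADER_SIZE)
        if len(header) < HEADER_SIZE:
            raise MrcParseError(f"{path}: truncated header ({len(header)} bytes)")
        words_i = np.frombuffer(header, dtype="<i4", count=56)
        words_f = np.frombuffer(header, dtype="<f4", count=56)
        nx, ny, nz = (int(v) for v in words_i[0:3])
        mode = int(words_i[3])
        nstart = words_i[4:7].astype(int)
        mx, my, mz = (int(v) for v in words_i[7:10])
        cella = words_f[10:13].astype(float)
        mapc, mapr, maps = (int(v) for v in words_i[16:19])
        nsymbt = int(words_i[23])
        origin_field = np.array(struct.unpack("<3f", header[196:208]), dtype=float)
        if mode not in _MODE_DTYPES:
            raise UnsupportedGridError(f"{path}: unsupported MRC mode {mode}")
        if min(nx, ny, nz) < 1 or min(mx, my, mz) < 1:
            raise MrcParseError(f"{path}: non-positive grid dimensions")
        axis_order = (mapc, mapr, maps)
        if sorted(axis_order) != [1, 2, 3]:
            raise MrcParseError(f"{path}: invalid MAPC/MAPR/MAPS {axis_order}")

        fh.seek(HEADER_SIZE + nsymbt)
        dtype = _MODE_DTYPES[mode]
        count = nx * ny * nz
        data = np.frombuffer(fh.read(count * dtype().itemsize), dtype=dtype)
        if data.size != count:
            raise MrcParseError(
                f"{path}: truncated data section ({data.size} of {count} values)"
            )

    vol = data.reshape(nz, ny, nx)  # [section, row, column]
    # file axes in slow->fast order represent crystallographic axes
    # maps, mapr, mapc; destination layout is grid[ix, iy, iz]
    crys_of_file_axis = (maps - 1, mapr - 1, mapc - 1)
    vol = np.moveaxis(vol, (0, 1, 2), crys_of_file_axis)

    spacing = cella / np.array([mx, my, mz], dtype=float)
    if spacing.max() - spacing.min() > 0.01 * spacing.mean():
        raise UnsupportedGridError(
            f"{path}: anisotropic voxels beyond 1% ({spacing.tolist()})"
        )
    voxel_size = float(spacing.mean())

    if np.any(origin_field != 0.0):
        origin = origin_field
    else:
        # nstart is stored in file (column, row, section) order
        start_xyz = np.empty(3)
        start_xyz[mapc - 1] = nstart[0]
        start_xyz[mapr - 1] = nstart[1]
        start_xyz[maps - 1] = nstart[2]
        origin = start_xyz * voxel_size
    return np.ascontiguousarray(vol.astype(np.float32)), voxel_size, origin


def write_mrc(path, grid, voxel_size, origin=(0.0, 0.0, 0.0)):
    """Write ``grid[ix, iy, iz]`` as a mode-2 (float32) MRC2014 file."""
    grid = np.asarray(grid, dtype=np.float32)
    if grid.ndim != 3:
        raise ValueError("grid must be 3-dimensional")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    nx, ny, nz = grid.shape
    header_i = np.zeros(256, dtype="<i4")
    header_f = header_i.view("<f4")
    header_i[0:3] = (nx, ny, nz)
    header_i[3] = 2
    header_i[7:10] = (nx, ny, nz)
    header_f[10:13] = np.array([nx, ny, nz]) * voxel_size
    header_f[13:16] = 90.0
    header_i[16:19] = (1, 2, 3)
    header_f[19] = float(grid.min())
    header_f[20] = float(grid.max())
    header_f[21] = float(grid.mean())
    header_i[22] = 1  # P1
    header_f[49:52] = np.asarray(origin, dtype=np.float32)
    header_i[52] = int.from_bytes(b"MAP ", "little")
    header_i[53] = int.from_bytes(bytes([0x44, 0x44, 0, 0]), "little")
    header_f[54] = float(grid.std())
    with open(path, "wb") as fh:
        fh.write(header_i.tobytes())
        fh.write(np.ascontiguousarray(grid.transpose(2, 1, 0)).tobytes())
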