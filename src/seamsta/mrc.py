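"""Minimal MRC2014 volume I/O (mode 2, 32-bit float).

Implements exactly the subset of the MRC2014 specification this package
needs for interoperability with tomography tooling: a 1024-byte header with
dimensions, mode, cell size (voxel size x dimensions) and the 'MAP '
stamp, followed by the raw float32 array. Data are stored with the fastest
axis first (column-major on disk, as MRC defines); in memory the array is
indexed (x, y, z) to match the package's volume convention.
"""

from __future__ import annotations

import warnings

import numpy as np

from .tomo import VolumeGrid

__all__ = ["read_mrc", "write_mrc"]

_HEADER_BYTES = 1024
_MODE_FLOAT32 = 2


class MrcError(IOError):
    pass


def write_mrc(path, volume: VolumeGrid) -> None:
    """Write a VolumeGrid as an MRC2014 mode-2 file (voxel size in header)."""
    data = np.asarray(volume.data, dtype="<f4")
    nx, ny, nz = data.shape
    header = np.zeros(256, dtype="<i4")
    header[0:3] = (nx, ny, nz)
    header[3] = _MODE_FLOAT32
    header[7:10] = (nx, ny, nz)  # mx, my, mz
    fheader = header.view("<f4")
    # cell dimensions in Angstrom (MRC convention); voxel_size is nm
    cell = np.array([nx, ny, nz], dtype="<f4") * volume.voxel_size * 10.0
    fheader[10:13] = cell
    fheader[13:16] = 90.0  # cell angles
    header[16:19] = (1, 2, 3)  # axis order: columns=x, rows=y, sections=z
    fheader[19] = float(data.min())
    fheader[20] = float(data.max())
    fheader[21] = float(data.mean())
    header[23] = 0  # no extended header
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = int.from_bytes(bytes((0x44, 0x44, 0, 0)), "little")  # little-endian stamp
    fheader[54] = float(data.std())
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(np.ascontiguousarray(data.T).tobytes())  # x fastest on disk


def read_mrc(path) -> VolumeGrid:
    """Read an MRC mode-2 file back into a VolumeGrid.

    Unsupported modes raise; a missing/zero voxel size warns and defaults to
    1 nm. Truncated files raise without producing a partial object.
    """
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER_BYTES)
        if len(raw) < _HEADER_BYTES:
            raise MrcError(f"{path}: truncated header ({len(raw)} bytes)")
        header = np.frombuffer(raw, dtype="<i4")
        fheader = header.view("<f4")
        nx, ny, nz = (int(v) for v in header[0:3])
        mode = int(header[3])
        if mode != _MODE_FLOAT32:
            raise MrcError(f"{path}: unsupported MRC mode {mode} (only mode 2)")
        nsymbt = int(header[23])
        if nsymbt:
            fh.seek(nsymbt, 1)
        n_vox = nx * ny * nz
        buf = fh.read(4 * n_vox)
        if len(buf) < 4 * n_vox:
            raise MrcError(f"{path}: truncated data ({len(buf)} of {4 * n_vox} bytes)")
    mx = int(header[7]) or nx
    cell_x = float(fheader[10])
    if cell_x > 0 and mx > 0:
        voxel_size = cell_x / mx / 10.0  # Angstrom -> nm
    else:
        warnings.warn(f"{path}: no voxel size in header, defaulting to 1 nm")
        voxel_size = 1.0
    data = np.frombuffer(buf, dtype="<f4").reshape(nz, ny, nx).T.copy()
    return VolumeGrid(data=data, voxel_size=voxel_size)
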