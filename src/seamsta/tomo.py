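"""Synthetic decorated-microtubule tomograms with exact ground truth.

A lattice is rendered as a sum of isotropic Gaussian blobs: one per occupied
tubulin monomer on the wall cylinder, plus one per occupied beta monomer at
a larger radius for the kinesin motor-domain decoration (the 8-nm axial
marker that makes dimer registry readable). The volume is then corrupted
with the artifacts that limit real cryo-electron tomograms: the missing
wedge (or pyramid, for dual-axis acquisition) of unsampled Fourier space
from the +/-60 degree tilt range, additive Gaussian noise, and one-sided
attenuation of the decoration shell mimicking protein denaturation at the
air-water interface.

Axis convention: the volume array is indexed (x, y, z) with the microtubule
axis along z (axis 2) and the electron beam / ice-thickness direction along
x (axis 0); the single-axis tilt axis is y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import MTLattice, lattice_coordinates

__all__ = ["VolumeGrid", "GroundTruth", "RenderParams", "render",
           "apply_wedge", "add_noise", "surface_damage"]


class TomoError(ValueError):
    pass


@dataclass
class VolumeGrid:
    """3-D density with voxel size (nm) and acquisition metadata."""

    data: np.ndarray
    voxel_size: float
    axis_order: str = "xyz"  # microtubule axis along z, beam along x
    tilt_axis: str | None = None
    tilt_range: float | None = None
    dual_axis: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise TomoError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.data = np.asarray(self.data, dtype=np.float32)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.voxel_size, self.axis_order,
                          self.tilt_axis, self.tilt_range, self.dual_axis,
                          dict(self.meta))


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about a rendered volume.

    ``sites`` is the coordinate table used for rendering (nm, volume frame);
    ``center_xy`` the microtubule axis position (nm); seam sets can always
    be regenerated from ``lattice``.
    """

    lattice: MTLattice
    sites: "object"  # pandas DataFrame
    center_xy: tuple[float, float]
    decoration_offset: float
    decoration_radius: float

    def seam_set_at(self, z: float) -> frozenset[int]:
        return self.lattice.seam_set_at(z)

    def segment_seam_sets(self, n_segments: int) -> list[frozenset[int] | None]:
        """True seam set per equal segment; None where the segment straddles
        a transition (no single seam set describes it)."""
        L = self.lattice.length
        edges = np.linspace(0.0, L, n_segments + 1)
        out = []
        for a, b in zip(edges[:-1], edges[1:]):
            zz = np.arange(a, b, self.lattice.spec.monomer_rise)
            sets = {self.lattice.seam_set_at(z) for z in zz}
            out.append(sets.pop() if len(sets) == 1 else None)
        return out


@dataclass(frozen=True)
class RenderParams:
    """Blob model of the density map (all lengths nm).

    Defaults put the decoration shell 4.5 nm outside the wall with blobs
    broad enough to fuse into per-protofilament ridges yet resolve the 8-nm
    repeat.
    """

    voxel_size: float = 0.8
    monomer_sigma: float = 1.6
    monomer_amplitude: float = 1.0
    decoration_sigma: float = 1.8
    decoration_amplitude: float = 0.8
    decoration_offset: float = 4.5
    margin: float = 6.0  # nm of empty border around the outermost blob


def render(lattice: MTLattice, params: RenderParams = RenderParams(),
           shape: tuple[int, int, int] | None = None) -> tuple[VolumeGrid, GroundTruth]:
    """Rasterize a lattice into a density volume plus its ground truth.

    Gaussian blobs are splatted additively within +/-4 sigma; background is
    exactly zero, density non-negative, and total density equals
    blob count x per-blob integral up to truncation.
    """
    vx = params.voxel_size
    spec = lattice.spec
    r_out = spec.wall_radius + params.decoration_offset
    half_xy = r_out + params.margin
    need_xy = int(np.ceil(2 * half_xy / vx))
    need_z = int(np.ceil(lattice.length / vx))
    if shape is None:
        shape = (need_xy, need_xy, need_z)
    if shape[0] < need_xy or shape[1] < need_xy or shape[2] < need_z:
        raise TomoError(f"grid {shape} too small; need at least "
                        f"({need_xy}, {need_xy}, {need_z}) voxels")

    cx = shape[0] * vx / 2.0
    cy = shape[1] * vx / 2.0
    sites = lattice_coordinates(lattice, decoration_offset=params.decoration_offset)
    sites = sites.assign(x=sites.x + cx, y=sites.y + cy)

    vol = np.zeros(shape, dtype=np.float32)
    for decorated, sigma, amp in ((False, params.monomer_sigma, params.monomer_amplitude),
                                  (True, params.decoration_sigma, params.decoration_amplitude)):
        if amp == 0:
            continue
        sub = sites[sites.decorated == decorated]
        if not len(sub):
            continue
        _splat(vol, sub[["x", "y", "z"]].to_numpy() / vx, sigma / vx, amp)

    gt = GroundTruth(lattice=lattice, sites=sites, center_xy=(cx, cy),
                     decoration_offset=params.decoration_offset,
                     decoration_radius=spec.wall_radius + params.decoration_offset)
    grid = VolumeGrid(vol, vx, meta={
        "center_xy_nm": (cx, cy),
        "wall_radius_nm": spec.wall_radius,
        "decoration_radius_nm": gt.decoration_radius,
        "spec": spec.to_dict(),
    })
    return grid, gt


def _splat(vol: np.ndarray, centers_vox: np.ndarray, sigma_vox: float,
           amplitude: float, cutoff: float = 4.0) -> None:
    """Add Gaussian blobs to ``vol`` in place (centers in voxel units)."""
    r = int(np.ceil(cutoff * sigma_vox))
    ax = np.arange(-r, r + 1)
    nx, ny, nz = vol.shape
    for cxv, cyv, czv in centers_vox:
        ix, iy, iz = int(round(cxv)), int(round(cyv)), int(round(czv))
        xs = ax + ix
        ys = ax + iy
        zs = ax + iz
        mx = (xs >= 0) & (xs < nx)
        my = (ys >= 0) & (ys < ny)
        mz = (zs >= 0) & (zs < nz)
        if not (mx.any() and my.any() and mz.any()):
            continue
        gx = np.exp(-((xs[mx] - cxv) ** 2) / (2 * sigma_vox ** 2))
        gy = np.exp(-((ys[my] - cyv) ** 2) / (2 * sigma_vox ** 2))
        gz = np.exp(-((zs[mz] - czv) ** 2) / (2 * sigma_vox ** 2))
        blob = amplitude * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        vol[np.ix_(xs[mx], ys[my], zs[mz])] += blob.astype(np.float32)


def _wedge_mask(shape: tuple[int, int, int], tilt_range: float,
                dual_axis: bool) -> np.ndarray:
    """Boolean mask of the *missing* region of Fourier space.

    Single axis (tilt about y, beam along x): a wedge of half-angle
    90 - tilt_range around the kx axis in the kx-kz plane. Dual axis adds a
    second series with the in-plane tilt axis rotated 90 degrees (tilt about
    z), whose missing wedge surrounds kx in the kx-ky plane; the jointly
    missing region is the intersection (the "missing pyramid").
    """
    kx = np.fft.fftfreq(shape[0])[:, None, None]
    ky = np.fft.fftfreq(shape[1])[None, :, None]
    kz = np.fft.fftfreq(shape[2])[None, None, :]
    kx, ky, kz = np.broadcast_arrays(kx, ky, kz)
    half = np.deg2rad(90.0 - tilt_range)
    missing1 = np.arctan2(np.abs(kz), np.abs(kx)) < half
    if not dual_axis:
        return missing1 & (np.abs(kx) + np.abs(kz) > 0)
    missing2 = np.arctan2(np.abs(ky), np.abs(kx)) < half
    return missing1 & missing2 & (np.abs(kx) + np.abs(ky) + np.abs(kz) > 0)


def apply_wedge(volume: VolumeGrid, tilt_range: float = 60.0,
                mode: str = "single") -> VolumeGrid:
    """Zero the Fourier coefficients unsampled by a +/-tilt_range tilt series.

    ``mode`` 'single' removes a wedge, 'dual' the smaller pyramid left by two
    orthogonal tilt axes. The mask is symmetric under k -> -k so the output
    is real.
    """
    if not (0.0 < tilt_range <= 90.0):
        raise TomoError(f"tilt_range must be in (0, 90], got {tilt_range}")
    if mode not in ("single", "dual"):
        raise TomoError(f"mode must be 'single' or 'dual', got {mode!r}")
    out = volume.copy()
    out.tilt_axis = "y"
    out.tilt_range = tilt_range
    out.dual_axis = mode == "dual"
    if tilt_range >= 90.0:
        return out
    ft = np.fft.fftn(volume.data)
    ft[_wedge_mask(volume.data.shape, tilt_range, mode == "dual")] = 0.0
    out.data = np.fft.ifftn(ft).real.astype(np.float32)
    return out


def add_noise(volume: VolumeGrid, snr: float | None, seed: int = 0) -> VolumeGrid:
    """Additive white Gaussian noise with sigma = peak amplitude / snr.

    ``snr=None`` is the noise-free limit and returns a copy unchanged.
    """
    out = volume.copy()
    if snr is None:
        return out
    if snr <= 0:
        raise TomoError(f"snr must be > 0, got {snr}")
    sigma = float(np.max(np.abs(volume.data))) / snr
    rng = np.random.default_rng(seed)
    out.data = (volume.data
                + rng.normal(0.0, sigma, volume.data.shape)).astype(np.float32)
    out.meta["noise_sigma"] = sigma
    return out


def surface_damage(volume: VolumeGrid, side: str = "-", attenuation: float = 0.3,
                   depth: float = 6.0, inner_radius: float | None = None) -> VolumeGrid:
    """Attenuate decoration-shell density on one face of the ice layer.

    Models kinesin motor-domain denaturation where the microtubule touches
    the air-water interface: voxels within ``depth`` nm of the chosen face
    along the beam axis (x), and outside ``inner_radius`` from the
    microtubule axis, are multiplied by ``attenuation``. ``inner_radius``
    defaults to just outside the wall (from render metadata) so tubulin
    density is spared, as observed on damaged microtubules.
    """
    if not (0.0 <= attenuation <= 1.0):
        raise TomoError(f"attenuation must be in [0, 1], got {attenuation}")
    if side not in ("+", "-"):
        raise TomoError(f"side must be '+' or '-', got {side!r}")
    out = volume.copy()
    if attenuation == 1.0:
        return out
    nx = volume.data.shape[0]
    vx = volume.voxel_size
    x_nm = np.arange(nx) * vx  # node-centered voxels
    face = x_nm if side == "-" else (nx - 1) * vx - x_nm
    in_slab = face <= depth

    if inner_radius is None:
        wall = volume.meta.get("wall_radius_nm")
        inner_radius = wall + 1.0 if wall is not None else 0.0
    factor = np.ones_like(volume.data)
    if inner_radius > 0 and "center_xy_nm" in volume.meta:
        cx, cy = volume.meta["center_xy_nm"]
        xx = np.arange(volume.data.shape[0]) * vx - cx
        yy = np.arange(volume.data.shape[1]) * vx - cy
        rr = np.sqrt(xx[:, None] ** 2 + yy[None, :] ** 2)
        shell = rr > inner_radius
        factor[in_slab, :, :] = np.where(shell[in_slab, :, None], attenuation, 1.0)
    else:
        factor[in_slab, :, :] = attenuation
    out.data = (volume.data * factor).astype(np.float32)
    out.meta["surface_damage"] = {"side": side, "attenuation": attenuation,
                                  "depth": depth, "inner_radius": inner_radius}
    return out
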