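"""Sub-tomogram extraction, constrained alignment, and segmented averaging.

The workflow mirrors classic filament sub-tomogram averaging: sample points
("motive list") every decoration repeat (~8 nm) along the microtubule axis,
extract a small cubic box at each point, align the boxes by masked
cross-correlation with the rotational search restricted to about half the
angular separation between protofilaments (so protofilament identity cannot
hop), and average. Segmented averaging (SSTA) splits the motive list into
contiguous segments of equal size and averages each segment with the
whole-filament average as template, exposing axial heterogeneity that a
single full-length average blurs into "aberrant protofilaments".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .tomo import VolumeGrid

__all__ = ["MotiveList", "SubvolumeStack", "make_motive_list", "extract",
           "align_average", "split_segments", "cylinder_mask"]


class StaError(ValueError):
    pass


@dataclass(frozen=True)
class MotiveList:
    """Ordered sample points along one filament.

    ``points`` are (n, 3) voxel coordinates; ``rotations`` (n, 3, 3)
    orthonormal matrices mapping the reference frame (filament axis = +z)
    onto each point's local frame; ``scores`` per-point cross-correlation.
    """

    points: np.ndarray
    rotations: np.ndarray
    scores: np.ndarray
    voxel_size: float

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        from scipy.spatial.transform import Rotation

        eul = Rotation.from_matrix(self.rotations).as_euler("zxz", degrees=True)
        df = pd.DataFrame(self.points, columns=["x", "y", "z"])
        df.insert(0, "point", np.arange(len(df)))
        df[["phi", "theta", "psi"]] = eul
        df["score"] = self.scores
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SubvolumeStack:
    """Extracted cubic boxes plus the motive list entries they came from."""

    boxes: np.ndarray  # (n, b, b, b)
    ml: MotiveList
    box_size: int
    mask_inner: float  # nm
    mask_outer: float  # nm

    def __len__(self) -> int:
        return len(self.boxes)


def _tangent_frames(tangents: np.ndarray) -> np.ndarray:
    """Minimal rotations mapping the reference +z onto each unit tangent.

    Using the smallest rotation (about z x t) keeps the in-plane axes
    untwisted: a straight +z axis yields identity frames, so angular
    positions in extracted boxes match the source volume.
    """
    ez = np.array([0.0, 0.0, 1.0])
    mats = np.empty((len(tangents), 3, 3))
    for i, t in enumerate(tangents):
        t = t / np.linalg.norm(t)
        c = float(np.dot(ez, t))
        axis = np.cross(ez, t)
        s = np.linalg.norm(axis)
        if s < 1e-12:
            mats[i] = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
            continue
        axis = axis / s
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        mats[i] = np.eye(3) + s * K + (1 - c) * (K @ K)
    return mats


def make_motive_list(axis_nm: np.ndarray, spacing: float,
                     voxel_size: float) -> MotiveList:
    """Sample points every ``spacing`` nm of arc length along a polyline.

    ``axis_nm`` is an (m, 3) polyline in nm (volume frame). Orientations
    rotate the reference +z onto the local tangent; the twist about the
    tangent is initialized to zero.
    """
    axis_nm = np.asarray(axis_nm, dtype=float)
    if axis_nm.ndim != 2 or axis_nm.shape[0] < 2:
        raise StaError("axis polyline needs at least 2 points")
    seg = np.diff(axis_nm, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if seg_len.sum() < 2 * spacing:
        raise StaError(f"axis length {seg_len.sum():.1f} nm is shorter than "
                       f"2 x spacing ({spacing} nm)")
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    targets = np.arange(0.0, arc[-1] - 1e-9, spacing)  # half-open: L/spacing points
    pts = np.empty((len(targets), 3))
    tans = np.empty((len(targets), 3))
    for i, s in enumerate(targets):
        j = min(np.searchsorted(arc, s, side="right") - 1, len(seg) - 1)
        frac = (s - arc[j]) / seg_len[j] if seg_len[j] > 0 else 0.0
        pts[i] = axis_nm[j] + frac * seg[j]
        tans[i] = seg[j] / seg_len[j]
    return MotiveList(points=pts / voxel_size, rotations=_tangent_frames(tans),
                      scores=np.zeros(len(pts)), voxel_size=voxel_size)


def extract(volume: VolumeGrid, ml: MotiveList, box: int = 48,
            order: int = 1) -> SubvolumeStack:
    """Resample a rotated cubic box at every motive-list point.

    Points whose box would leave the volume are dropped (and counted in the
    returned motive list's length); extracting nothing is an error.
    """
    half = box / 2.0 - 0.5
    grid = np.arange(box) - half
    gx, gy, gz = np.meshgrid(grid, grid, grid, indexing="ij")
    local = np.stack([gx.ravel(), gy.ravel(), gz.ravel()])  # (3, b^3)

    boxes, keep = [], []
    shape = np.array(volume.data.shape)
    for i in range(len(ml)):
        coords = ml.rotations[i] @ local + ml.points[i][:, None]
        lo, hi = coords.min(axis=1), coords.max(axis=1)
        if (lo < -0.5).any() or (hi > shape - 0.5).any():
            continue
        sub = map_coordinates(volume.data, coords, order=order,
                              mode="constant").reshape(box, box, box)
        boxes.append(sub)
        keep.append(i)
    if not boxes:
        raise StaError("no motive-list point fits a box inside the volume")
    kept = MotiveList(points=ml.points[keep], rotations=ml.rotations[keep],
                      scores=ml.scores[keep], voxel_size=ml.voxel_size)
    return SubvolumeStack(boxes=np.stack(boxes).astype(np.float32), ml=kept,
                          box_size=box, mask_inner=6.0, mask_outer=20.0)


def cylinder_mask(box: int, voxel_size: float, inner: float, outer: float) -> np.ndarray:
    """Soft-edged cylindrical annulus mask isolating the wall densities."""
    half = box / 2.0 - 0.5
    ax = np.arange(box) - half
    rr = np.sqrt(ax[:, None] ** 2 + ax[None, :] ** 2) * voxel_size
    radial = ((rr >= inner) & (rr <= outer)).astype(np.float32)
    return np.repeat(radial[:, :, None], box, axis=2)


def _rotate_about_z(box_arr: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a cubic box about its central z axis (the filament axis)."""
    from scipy.ndimage import rotate

    return rotate(box_arr, angle_deg, axes=(0, 1), reshape=False, order=1,
                  mode="constant")


def _masked_normalize(arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    w = mask.sum()
    m = (arr * mask).sum() / w
    out = (arr - m) * mask
    n = np.sqrt((out ** 2).sum())
    return out / n if n > 0 else out


def _best_shift(cc: np.ndarray, shift_limit: float) -> tuple[np.ndarray, float]:
    """Peak of a circular cross-correlation map within a shift budget,
    refined to half-voxel precision by quadratic interpolation."""
    n = cc.shape[0]
    freqs = np.fft.fftfreq(n, d=1.0 / n)  # signed shifts per axis
    allowed = np.abs(freqs) <= shift_limit
    mask = allowed[:, None, None] & allowed[None, :, None] & allowed[None, None, :]
    masked = np.where(mask, cc, -np.inf)
    idx = np.unravel_index(np.argmax(masked), cc.shape)
    peak = cc[idx]
    shift = np.array([freqs[i] for i in idx], dtype=float)
    for ax in range(3):
        im = list(idx)
        ip = list(idx)
        im[ax] = (idx[ax] - 1) % n
        ip[ax] = (idx[ax] + 1) % n
        y0, y1, y2 = cc[tuple(im)], peak, cc[tuple(ip)]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            shift[ax] += np.clip(delta, -0.5, 0.5)
    return shift, float(peak)


def align_average(stack: SubvolumeStack, ref: np.ndarray | None = None,
                  rot_limit: float = 10.0, shift_limit: float = 2.0,
                  iterations: int = 2, rot_step: float = 1.0,
                  voxel_size: float | None = None
                  ) -> tuple[np.ndarray, MotiveList, dict]:
    """Constrained alignment and averaging of a sub-volume stack.

    Each box is compared against the reference rotated about the filament
    axis over +/-rot_limit in ``rot_step`` degree steps; for every angle the
    best 3-D shift within ``shift_limit`` voxels is found by FFT
    cross-correlation on masked, mean-subtracted boxes (quadratic peak
    interpolation to half-voxel precision). Ties break toward the smallest
    |rotation|, then smallest |shift|. The reference defaults to the
    unaligned average and is replaced by the running average each iteration.

    Returns (average, refined motive list with scores, info dict with the
    per-box rotations/shifts of the final iteration).
    """
    if len(stack) == 0:
        raise StaError("cannot align an empty stack")
    vx = voxel_size or stack.ml.voxel_size
    mask = cylinder_mask(stack.box_size, vx, stack.mask_inner, stack.mask_outer)
    if ref is None:
        ref = stack.boxes.mean(axis=0)
    angles = np.arange(-rot_limit, rot_limit + rot_step / 2, rot_step)
    order = np.argsort(np.abs(angles), kind="stable")  # small |rot| wins ties
    angles = angles[order]

    average = ref
    rots = np.zeros(len(stack))
    shifts = np.zeros((len(stack), 3))
    scores = np.zeros(len(stack))
    for _ in range(max(1, iterations)):
        ref_ffts = []
        for ang in angles:
            r = _masked_normalize(_rotate_about_z(average, ang), mask)
            ref_ffts.append(np.conj(np.fft.fftn(r)))
        new_sum = np.zeros_like(average, dtype=np.float64)
        for b in range(len(stack)):
            box_n = _masked_normalize(stack.boxes[b], mask)
            bf = np.fft.fftn(box_n)
            best = (-np.inf, 0.0, np.zeros(3))
            for ang, rf in zip(angles, ref_ffts):
                cc = np.fft.ifftn(bf * rf).real
                shift, peak = _best_shift(cc, shift_limit)
                if peak > best[0] + 1e-12:
                    best = (peak, ang, shift)
                elif abs(peak - best[0]) <= 1e-12:  # tie: smaller |shift|
                    if np.linalg.norm(shift) < np.linalg.norm(best[2]):
                        best = (peak, ang, shift)
            scores[b], rots[b], shifts[b] = best[0], best[1], best[2]
            aligned = _rotate_about_z(stack.boxes[b], -rots[b])
            aligned = _fourier_shift(aligned, -shifts[b])
            new_sum += aligned
        average = (new_sum / len(stack)).astype(np.float32)

    ml = replace(stack.ml, scores=scores.copy())
    info = {"rotations_deg": rots.copy(), "shifts_vox": shifts.copy()}
    return average, ml, info


def _fourier_shift(arr: np.ndarray, shift: np.ndarray) -> np.ndarray:
    from scipy.ndimage import fourier_shift as _fs

    return np.fft.ifftn(_fs(np.fft.fftn(arr), shift)).real.astype(np.float32)


def split_segments(ml: MotiveList, n: int) -> list[MotiveList]:
    """Split a motive list into n contiguous segments of near-equal size.

    Sizes differ by at most one (larger segments first); the concatenation
    of the pieces reproduces the input exactly.
    """
    if n < 1:
        raise StaError(f"segment count must be >= 1, got {n}")
    if n > len(ml):
        raise StaError(f"cannot split {len(ml)} points into {n} segments")
    idx_chunks = np.array_split(np.arange(len(ml)), n)
    return [MotiveList(points=ml.points[c], rotations=ml.rotations[c],
                       scores=ml.scores[c], voxel_size=ml.voxel_size)
            for c in idx_chunks]


def split_stack(stack: SubvolumeStack, n: int) -> list[SubvolumeStack]:
    """Segment an extracted stack the same way split_segments segments
    its motive list."""
    if n < 1 or n > len(stack):
        raise StaError(f"cannot split {len(stack)} boxes into {n} segments")
    chunks = np.array_split(np.arange(len(stack)), n)
    mls = split_segments(stack.ml, n)
    return [SubvolumeStack(boxes=stack.boxes[c], ml=m, box_size=stack.box_size,
                           mask_inner=stack.mask_inner, mask_outer=stack.mask_outer)
            for c, m in zip(chunks, mls)]
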