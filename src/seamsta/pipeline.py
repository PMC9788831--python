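"""End-to-end wiring: rendered volume -> STA -> segment calls -> statistics.

This module glues the stages together for the desk-scale workflow used by
the examples, the fixtures and the acceptance checks: sample a motive list
along the (straight) microtubule axis at the decoration repeat, extract and
align sub-volumes, average per segment, unwrap each segment average at the
decoration radius and call its lattice organization, then map calls back
onto ground-truth protofilament indices when a GroundTruth is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import caller as _caller
from . import sta as _sta
from .lattice import MTLattice
from .tomo import GroundTruth, VolumeGrid

__all__ = ["SstaResult", "analyze_volume", "true_contact_types",
           "remap_contact_types", "segment_truth", "calls_from_lattice"]


@dataclass
class SstaResult:
    """Output of one segmented-averaging run."""

    whole_average: np.ndarray
    whole_call: _caller.SegmentCall
    segment_averages: list[np.ndarray]
    calls: list[_caller.SegmentCall]
    motive_list: _sta.MotiveList
    info: dict


def _box_volume(avg: np.ndarray, voxel_size: float, meta_src: VolumeGrid) -> VolumeGrid:
    box = avg.shape[0]
    c = (box / 2.0 - 0.5) * voxel_size  # extraction grid center, node-centered voxels
    meta = {"center_xy_nm": (c, c)}
    if "decoration_radius_nm" in meta_src.meta:
        meta["decoration_radius_nm"] = meta_src.meta["decoration_radius_nm"]
    if "wall_radius_nm" in meta_src.meta:
        meta["wall_radius_nm"] = meta_src.meta["wall_radius_nm"]
    return VolumeGrid(avg, voxel_size, meta=meta)


def estimate_radii(volume: VolumeGrid, dimer_rise: float = 8.0,
                   r_max: float | None = None) -> tuple[float, float]:
    """Wall and decoration radii from the density itself.

    The wall radius is the peak of the radially averaged intensity; the
    decoration radius maximizes the dimer-repeat spectral power of the
    unwrapped shell outside the wall.
    """
    vx = volume.voxel_size
    nx, ny, nz = volume.data.shape
    cx, cy = volume.meta.get("center_xy_nm", (nx * vx / 2, ny * vx / 2))
    xx = np.arange(nx) * vx - cx
    yy = np.arange(ny) * vx - cy
    rr = np.sqrt(xx[:, None] ** 2 + yy[None, :] ** 2)
    proj = volume.data.mean(axis=2)
    r_hi = r_max or (min(cx, cy) - 2.0)
    bins = np.arange(0.0, r_hi, vx)
    prof = np.array([proj[(rr >= a) & (rr < a + vx)].mean() if ((rr >= a) & (rr < a + vx)).any()
                     else 0.0 for a in bins])
    wall = float(bins[np.argmax(prof)] + vx / 2)
    best_r, best_p = wall + 4.0, -np.inf
    for r in np.arange(wall + 2.0, min(wall + 9.0, r_hi - 1.0), 0.5):
        cmap = _caller.unwrap(volume, r, center_xy=(cx, cy), n_theta=128)
        z = cmap.z
        comp = np.abs(cmap.values @ np.exp(-2j * np.pi * z / dimer_rise))
        p = comp.mean()
        if p > best_p:
            best_p, best_r = p, float(r)
    return wall, best_r


def analyze_volume(volume: VolumeGrid, n_segments: int = 4, spacing: float = 8.0,
                   box: int = 48, rot_limit: float | None = None,
                   shift_limit: float = 2.0, iterations: int = 1,
                   align: bool = True, radius: float | None = None) -> SstaResult:
    """Run segmented sub-tomogram averaging on one straight microtubule.

    ``align=False`` skips the cross-correlation refinement and averages the
    extracted boxes as-is (exact for synthetic volumes whose motive list is
    already on the lattice); otherwise the whole-filament average is refined
    first and then reused as the per-segment template.
    """
    vx = volume.voxel_size
    nx, ny, nz = volume.data.shape
    cx, cy = volume.meta.get("center_xy_nm", (nx * vx / 2, ny * vx / 2))
    margin = box * vx / 2.0
    axis = np.array([[cx, cy, margin], [cx, cy, nz * vx - margin]])
    ml = _sta.make_motive_list(axis, spacing, vx)
    stack = _sta.extract(volume, ml, box=box)

    if radius is None:
        radius = volume.meta.get("decoration_radius_nm")
    if rot_limit is None:
        spec_meta = volume.meta.get("spec")
        rot_limit = (360.0 / spec_meta["N"]) / 2.0 if spec_meta else 10.0

    info: dict = {}
    if align:
        whole_avg, ml_ref, al_info = _sta.align_average(
            stack, rot_limit=rot_limit, shift_limit=shift_limit,
            iterations=iterations)
        info["whole_alignment"] = al_info
    else:
        whole_avg = stack.boxes.mean(axis=0)
        ml_ref = stack.ml

    whole_vol = _box_volume(whole_avg, vx, volume)
    if radius is None:
        _, radius = estimate_radii(whole_vol)
        info["estimated_radius_nm"] = radius
    whole_call = _caller.call_segment(whole_vol, radius=radius)

    seg_stacks = _sta.split_stack(stack, n_segments)
    averages, calls = [], []
    for si, seg in enumerate(seg_stacks):
        if align:
            avg, _, _ = _sta.align_average(seg, ref=whole_avg, rot_limit=rot_limit,
                                           shift_limit=shift_limit, iterations=1)
        else:
            avg = seg.boxes.mean(axis=0)
        averages.append(avg)
        zlo = float(seg.ml.points[:, 2].min() * vx)
        zhi = float(seg.ml.points[:, 2].max() * vx)
        seg_vol = _box_volume(avg, vx, volume)
        call = _caller.call_segment(seg_vol, radius=radius, segment=si,
                                    z_range=(zlo, zhi))
        calls.append(canonicalize_call(call))
    return SstaResult(whole_average=whole_avg, whole_call=whole_call,
                      segment_averages=averages, calls=calls,
                      motive_list=ml_ref, info=info)


def canonicalize_call(call: _caller.SegmentCall,
                      handedness: int = -1) -> _caller.SegmentCall:
    """Re-index a call's protofilaments onto the nominal angular grid.

    Ridge j detected at angle theta_j is assigned protofilament index
    round(theta_j / (handedness * 2*pi/N)); when that mapping is a
    bijection all per-protofilament arrays are reordered accordingly, making
    contact indices comparable across segments (and with a rendered ground
    truth). Calls that cannot be mapped bijectively are returned unchanged.
    """
    if call.contact_types is None or call.pf_angles is None or call.N is None:
        return call
    n = call.N
    step = handedness * 2 * np.pi / n
    idx = [int(round(a / step)) % n for a in call.pf_angles]
    if len(set(idx)) != n:
        return call
    order = np.empty(n, dtype=int)
    for j, i in enumerate(idx):
        order[i] = j
    return _caller.SegmentCall(
        segment=call.segment, z_range=call.z_range, N=n, S=call.S,
        phases=call.phases[order], coherences=call.coherences[order],
        contact_types=call.contact_types[order],
        pf_angles=call.pf_angles[order])


def remap_contact_types(call: _caller.SegmentCall,
                        handedness: int = -1) -> np.ndarray | None:
    """Contact types re-indexed onto ground-truth protofilament numbering.

    The caller labels protofilaments by angular scan order starting at its
    first detected ridge; the renderer placed true protofilament i at angle
    handedness * 2*pi*i/N. Rounding the detected ridge angles onto that
    grid recovers the true indexing.
    """
    if call.contact_types is None or call.pf_angles is None or call.N is None:
        return None
    n = call.N
    out = np.full(n, "N", dtype="<U1")
    step = handedness * 2 * np.pi / n
    for j in range(n):
        i = int(round(call.pf_angles[j] / step)) % n
        out[i] = call.contact_types[j]
    return out


def true_contact_types(lattice: MTLattice, z: float) -> np.ndarray:
    return lattice.contact_types_at(z)


def segment_truth(gt: GroundTruth, call: _caller.SegmentCall) -> np.ndarray | None:
    """Ground-truth contact types over a called segment's z range.

    Returns one type per contact when the truth is constant over the
    segment, else None (the segment straddles a transition and has no
    single truth).
    """
    zlo, zhi = call.z_range
    lat = gt.lattice
    zz = np.arange(max(0.0, zlo), min(lat.length, zhi), lat.spec.monomer_rise)
    if len(zz) == 0:
        return None
    maps = {tuple(lat.contact_types_at(z)) for z in zz}
    if len(maps) != 1:
        return None
    return np.array(maps.pop())


def score_call(call: _caller.SegmentCall, truth: np.ndarray,
               handedness: int = -1) -> dict:
    """Agreement between a segment call and its ground truth.

    Counts correct calls, ND calls, and A<->B confusions (a called A where
    the truth is B or vice versa - the error mode that must not occur).
    """
    mapped = remap_contact_types(call, handedness)
    if mapped is None:
        return {"n": len(truth), "correct": 0, "nd": len(truth), "confused": 0}
    correct = int(np.sum(mapped == truth))
    nd = int(np.sum(mapped == "N"))
    confused = int(np.sum((mapped != truth) & (mapped != "N")))
    return {"n": len(truth), "correct": correct, "nd": nd, "confused": confused}


def calls_from_lattice(lattice: MTLattice, segment_length: float,
                       coherence_split_threshold: bool = True
                       ) -> list[_caller.SegmentCall]:
    """Ground-truth segment calls straight from a lattice (no rendering).

    Mimics what a perfect caller would report: a segment entirely on one
    side of every transition yields its exact contact map; a segment
    containing a registry change on some protofilament yields ND on that
    protofilament's contacts (the in/out-of-register averaging that makes a
    protofilament "aberrant" in a real segment average).
    """
    spec = lattice.spec
    n_seg = max(1, int(round(lattice.length / segment_length)))
    edges = np.linspace(0.0, lattice.length, n_seg + 1)
    calls = []
    for si, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        zz = np.arange(a, b, spec.monomer_rise)
        if len(zz) == 0:
            zz = np.array([a])
        maps = np.stack([lattice.contact_types_at(z) for z in zz])
        types = np.full(spec.N, "N", dtype="<U1")
        for c in range(spec.N):
            col = set(maps[:, c])
            if len(col) == 1:
                types[c] = col.pop()
        phases = np.array([lattice.pf_phase(i, (a + b) / 2) for i in range(spec.N)])
        coher = np.ones(spec.N)
        for c in range(spec.N):
            if types[c] == "N":
                coher[c] = 0.0
                coher[(c + 1) % spec.N] = 0.0
        angles = spec.handedness * 2 * np.pi * np.arange(spec.N) / spec.N
        calls.append(_caller.SegmentCall(
            segment=si, z_range=(float(a), float(b)), N=spec.N, S=spec.S,
            phases=phases, coherences=coher, contact_types=types,
            pf_angles=angles))
    return calls
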