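"""Inference of lattice organization from density volumes.

The kinesin decoration marks every beta monomer, so along each
protofilament the decoration shell carries an 8-nm (dimer-repeat) intensity
wave whose *phase* encodes the dimer registry. Unwrapping the volume onto a
cylinder at the decoration radius gives an (angle, z) map with one ridge
per protofilament; the phase difference between adjacent ridges is the
lateral stagger rho = S * monomer_rise / N for a B-type (homotypic)
contact and rho + monomer_rise across a seam (A-type). A protofilament
whose 8-nm component is weak (in-register and out-of-register stretches
averaged together - the "aberrant protofilament") yields no determination
(ND) for its two contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from .lattice import LatticeSpec, make_spec
from .tomo import VolumeGrid

__all__ = ["CylinderMap", "SegmentCall", "unwrap", "infer_NS", "pf_phase",
           "classify_contacts", "layerline_filter", "phase_offset_test",
           "COHERENCE_THRESHOLD"]

#: below this relative 8-nm spectral amplitude a protofilament is "aberrant"
COHERENCE_THRESHOLD = 0.3

#: nm tolerance for typing a contact from its measured registry difference
CALL_TOLERANCE = 1.0


class CallerError(ValueError):
    pass


@dataclass(frozen=True)
class CylinderMap:
    """Intensity sampled on a cylinder: rows = angle, columns = axial z.

    ``theta`` is sampled in the protofilament ordering direction (matching
    the lattice handedness), so the angular index increases with
    protofilament index and adjacent rows differ in phase by +rho across a
    B contact.
    """

    values: np.ndarray  # (n_theta, n_z)
    theta: np.ndarray  # radians, signed, monotonic in pf order
    z: np.ndarray  # nm
    radius: float

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])


@dataclass(frozen=True)
class SegmentCall:
    """Inferred lattice organization of one filament segment."""

    segment: int
    z_range: tuple[float, float]
    N: int | None
    S: int | None
    phases: np.ndarray | None  # nm mod dimer_rise, one per pf
    coherences: np.ndarray | None
    contact_types: np.ndarray | None  # 'A' | 'B' | 'N'
    pf_angles: np.ndarray | None = None

    @property
    def determined(self) -> bool:
        return (self.contact_types is not None
                and not np.any(self.contact_types == "N"))

    @property
    def seam_set(self) -> frozenset[int] | None:
        if self.contact_types is None:
            return None
        return frozenset(int(i) for i in np.nonzero(self.contact_types == "A")[0])

    def n_contacts(self) -> int:
        return 0 if self.contact_types is None else len(self.contact_types)

    def sphere_model(self) -> pd.DataFrame:
        """Color-coded sphere model: yellow = decorated (beta), cyan =
        undecorated (alpha), red = aberrant protofilament."""
        if self.N is None:
            return pd.DataFrame(columns=["pf", "z", "color"])
        rows = []
        z0, z1 = self.z_range
        dimer = 8.0
        for pf in range(self.N):
            aberrant = (self.coherences is not None
                        and self.coherences[pf] < COHERENCE_THRESHOLD)
            psi = 0.0 if self.phases is None else float(self.phases[pf])
            z = z0 + psi % dimer
            while z < z1:
                if aberrant:
                    rows.append((pf, z, "red"))
                else:
                    rows.append((pf, z, "yellow"))
                    if z + dimer / 2 < z1:
                        rows.append((pf, z + dimer / 2, "cyan"))
                z += dimer
        return pd.DataFrame(rows, columns=["pf", "z", "color"])

    def to_dict(self) -> dict:
        return {
            "segment": self.segment,
            "z_range": list(self.z_range),
            "N": self.N,
            "S": self.S,
            "phases": None if self.phases is None else [float(p) for p in self.phases],
            "coherences": None if self.coherences is None
            else [float(c) for c in self.coherences],
            "contacts": None if self.contact_types is None
            else "".join(self.contact_types),
            "seams": None if self.seam_set is None else sorted(self.seam_set),
        }


def unwrap(volume: VolumeGrid, radius: float,
           center_xy: tuple[float, float] | None = None,
           n_theta: int = 256, handedness: int = -1) -> CylinderMap:
    """Interpolate the volume onto a cylinder of the given radius (nm).

    The axis is assumed straight along z through ``center_xy`` (defaults to
    render metadata, else the grid center). ``handedness`` sets the angular
    scan direction so rows follow protofilament order.
    """
    vx = volume.voxel_size
    nx, ny, nz = volume.data.shape
    if center_xy is None:
        center_xy = volume.meta.get("center_xy_nm", (nx * vx / 2.0, ny * vx / 2.0))
    cx, cy = center_xy
    max_r = min(cx, cy, nx * vx - cx, ny * vx - cy)
    if radius <= 0 or radius >= max_r:
        raise CallerError(f"radius {radius} nm outside grid (max {max_r:.1f} nm)")
    # voxel index i is node-centered at coordinate i * voxel_size
    theta = handedness * np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    z = np.arange(nz) * vx
    xs = (cx + radius * np.cos(theta)) / vx
    ys = (cy + radius * np.sin(theta)) / vx
    zs = np.arange(nz, dtype=float)
    coords = np.stack([
        np.repeat(xs, nz),
        np.repeat(ys, nz),
        np.tile(zs, n_theta),
    ])
    vals = map_coordinates(volume.data, coords, order=1, mode="nearest")
    return CylinderMap(values=vals.reshape(n_theta, nz), theta=theta, z=z,
                       radius=radius)


def angular_profile(cmap: CylinderMap) -> np.ndarray:
    """z-averaged intensity versus angle (one bump per protofilament)."""
    return cmap.values.mean(axis=1)


def dimer_amplitude_profile(cmap: CylinderMap, dimer_rise: float = 8.0) -> np.ndarray:
    """Per-angle amplitude of the dimer-repeat component along z.

    Decoration ridges carry the 8-nm wave, so this angular signal is
    selective for protofilaments even when the missing wedge modulates the
    plain z-averaged intensity.
    """
    phase = np.exp(-2j * np.pi * cmap.z / dimer_rise)
    return np.abs(cmap.values @ phase) / cmap.values.shape[1]


def find_pf_angles(cmap: CylinderMap, min_rel_height: float = 0.5,
                   dimer_rise: float = 8.0) -> np.ndarray:
    """Angular positions of protofilament ridges (indices into theta).

    Peaks of the dimer-amplitude angular profile, circularly tiled, kept
    when at least ``min_rel_height`` of the median peak height.
    """
    prof = dimer_amplitude_profile(cmap, dimer_rise)
    n = len(prof)
    base = prof.min()
    tiled = np.concatenate([prof, prof, prof]) - base
    peaks, _ = find_peaks(tiled, distance=max(2, n // 20))
    peaks = peaks[(peaks >= n) & (peaks < 2 * n)] - n
    if len(peaks) == 0:
        return np.array([], dtype=int)
    heights = prof[peaks] - base
    med = np.median(heights)
    if med <= 0:
        return np.array([], dtype=int)
    return np.sort(peaks[heights >= min_rel_height * med])


def detect_pf_rows(cmap: CylinderMap, n_range: tuple[int, int] = (8, 17),
                   dimer_rise: float = 8.0) -> np.ndarray | None:
    """Protofilament ridge rows, robust to angular envelope modulation.

    The protofilament count is the dominant angular Fourier harmonic of the
    dimer-amplitude profile within the physically valid range; ridge
    positions come from direct peak detection when it agrees with that
    count, else from the harmonic's phase (an N-fold comb). Returns None
    when no harmonic stands out (featureless map).
    """
    prof = dimer_amplitude_profile(cmap, dimer_rise)
    n = len(prof)
    ft = np.fft.fft(prof - prof.mean())
    lo, hi = n_range
    amps = {N: abs(ft[N]) for N in range(lo, hi + 1)}
    best_n = max(amps, key=amps.get)
    floor = np.median(list(amps.values()))
    if amps[best_n] <= 0 or (floor > 0 and amps[best_n] < 1.5 * floor):
        return None
    peaks = find_pf_angles(cmap, dimer_rise=dimer_rise)
    if len(peaks) == best_n:
        return peaks
    # comb from the harmonic phase: ridges maximize cos(N*2pi*r/n - phi)
    r0 = (-np.angle(ft[best_n]) * n / (2 * np.pi * best_n)) % (n / best_n)
    rows = (np.round(r0 + np.arange(best_n) * n / best_n).astype(int)) % n
    return np.sort(rows)


def pf_phase(cmap: CylinderMap, pf_angle_idx: int, dimer_rise: float = 8.0,
             window: int = 3) -> tuple[float, float]:
    """Registry phase and coherence of one protofilament ridge.

    The axial profile at the ridge (averaged over a small angular window) is
    projected onto the dimer-repeat Fourier component: psi is the phase of
    that component expressed in nm within [0, dimer_rise); coherence is the
    RMS amplitude of that component relative to the profile's total non-DC
    RMS amplitude (an energy ratio, robust to the spectral leakage of
    finite windows). A pure 8-nm cosine offset by 2 nm returns psi = 2,
    coherence ~ 1; a profile whose phase jumps by half a repeat midway
    destructively cancels and returns a low coherence.
    """
    n_theta = cmap.values.shape[0]
    rows = [(pf_angle_idx + d) % n_theta for d in range(-window, window + 1)]
    profile = cmap.values[rows].mean(axis=0)
    profile = profile - profile.mean()
    if np.allclose(profile, 0.0):
        return 0.0, 0.0
    z = cmap.z
    psi, coherence, _ = _phase_coherence_amplitude(cmap, pf_angle_idx,
                                                   dimer_rise, window)
    return psi, coherence


def _phase_coherence_amplitude(cmap: CylinderMap, pf_angle_idx: int,
                               dimer_rise: float = 8.0,
                               window: int = 3) -> tuple[float, float, float]:
    """pf_phase plus the absolute dimer-component amplitude of the ridge."""
    n_theta = cmap.values.shape[0]
    rows = [(pf_angle_idx + d) % n_theta for d in range(-window, window + 1)]
    profile = cmap.values[rows].mean(axis=0)
    profile = profile - profile.mean()
    if np.allclose(profile, 0.0):
        return 0.0, 0.0, 0.0
    z = cmap.z
    c = np.sum(profile * np.exp(-2j * np.pi * z / dimer_rise))
    psi = (-np.angle(c) / (2.0 * np.pi)) * dimer_rise % dimer_rise
    m = len(profile)
    amplitude = 2.0 * np.abs(c) / m  # best-fit cosine amplitude
    energy = float(np.sum(profile ** 2))  # total AC energy (mean removed)
    comp_energy = 2.0 * np.abs(c) ** 2 / m  # energy of the fitted cosine
    coherence = np.sqrt(comp_energy / energy) if energy > 0 else 0.0
    return float(psi), float(min(1.0, coherence)), float(amplitude)


def infer_NS(cmap: CylinderMap, s_candidates: tuple[int, ...] = (2, 3, 4),
             monomer_rise: float = 4.0) -> tuple[int | None, int | None]:
    """Protofilament count and helix-start number from a cylinder map.

    N is the number of significant protofilament ridges (dominant angular
    harmonic of the dimer-amplitude profile). S is chosen among the
    candidates by the least circular misfit between the measured
    ridge-to-ridge phase steps and the candidate stagger
    rho_S = S * monomer_rise / N, allowing each step to be either rho_S or
    rho_S + monomer_rise (seams). Returns (None, None) when undetermined.
    """
    peaks = detect_pf_rows(cmap, dimer_rise=2.0 * monomer_rise)
    if peaks is None or len(peaks) < 2:
        return None, None
    N = len(peaks)
    dimer = 2.0 * monomer_rise
    phases = np.array([pf_phase(cmap, p, dimer_rise=dimer)[0] for p in peaks])
    steps = (np.roll(phases, -1) - phases) % dimer
    best_s, best_cost = None, np.inf
    for s in s_candidates:
        rho = s * monomer_rise / N
        cost = 0.0
        for d in steps:
            cands = [rho % dimer, (rho + monomer_rise) % dimer]
            cost += min(_circdist(d, c, dimer) for c in cands) ** 2
        if cost < best_cost - 1e-12:
            best_cost, best_s = cost, s
    return N, best_s


def _circdist(a: float, b: float, period: float) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def classify_contacts(phases: np.ndarray, coherences: np.ndarray,
                      spec: LatticeSpec, segment: int = 0,
                      z_range: tuple[float, float] = (0.0, 0.0),
                      tolerance: float = CALL_TOLERANCE,
                      coherence_threshold: float = COHERENCE_THRESHOLD,
                      pf_angles: np.ndarray | None = None) -> SegmentCall:
    """Type every lateral contact from per-protofilament phases.

    Contact i joins protofilaments i and i+1 (mod N): B when the circular
    distance of the phase step to rho is below tolerance, A when the
    distance to rho + monomer_rise is, otherwise ND; both contacts of any
    protofilament with coherence below the threshold are ND.
    """
    phases = np.asarray(phases, dtype=float)
    coherences = np.asarray(coherences, dtype=float)
    if len(phases) != spec.N:
        raise CallerError(f"{len(phases)} phases for spec with N = {spec.N}")
    dimer = spec.dimer_rise
    types = np.full(spec.N, "N", dtype="<U1")
    for i in range(spec.N):
        j = (i + 1) % spec.N
        if coherences[i] < coherence_threshold or coherences[j] < coherence_threshold:
            continue
        d = (phases[j] - phases[i]) % dimer
        if _circdist(d, spec.rho, dimer) < tolerance:
            types[i] = "B"
        elif _circdist(d, spec.rho + spec.monomer_rise, dimer) < tolerance:
            types[i] = "A"
    return SegmentCall(segment=segment, z_range=z_range, N=spec.N, S=spec.S,
                       phases=phases, coherences=coherences,
                       contact_types=types, pf_angles=pf_angles)


def call_segment(volume_or_map, radius: float | None = None,
                 s_candidates: tuple[int, ...] = (2, 3, 4),
                 monomer_rise: float = 4.0, segment: int = 0,
                 z_range: tuple[float, float] | None = None,
                 spec: LatticeSpec | None = None) -> SegmentCall:
    """Full per-segment call: unwrap (if needed), infer N_S, classify.

    Accepts either a VolumeGrid (with ``radius``) or a ready CylinderMap.
    If ``spec`` is given, its N and S are trusted (whole-filament inference)
    and only phases/contacts are re-measured.
    """
    if isinstance(volume_or_map, CylinderMap):
        cmap = volume_or_map
    else:
        if radius is None:
            radius = volume_or_map.meta.get("decoration_radius_nm")
            if radius is None:
                raise CallerError("radius required when volume has no metadata")
        cmap = unwrap(volume_or_map, radius)
    if z_range is None:
        z_range = (float(cmap.z[0]), float(cmap.z[-1]))
    if spec is None:
        N, S = infer_NS(cmap, s_candidates, monomer_rise)
        if N is None or S is None:
            return SegmentCall(segment=segment, z_range=z_range, N=N, S=S,
                               phases=None, coherences=None, contact_types=None)
        try:
            spec = make_spec(N, S, monomer_rise)
        except Exception:
            return SegmentCall(segment=segment, z_range=z_range, N=N, S=S,
                               phases=None, coherences=None, contact_types=None)
    peaks = detect_pf_rows(cmap, dimer_rise=2.0 * monomer_rise)
    if peaks is None or len(peaks) != spec.N:
        n_found = None if peaks is None else len(peaks)
        return SegmentCall(segment=segment, z_range=z_range, N=n_found,
                           S=None, phases=None, coherences=None, contact_types=None)
    dimer = spec.dimer_rise
    ph, co, amp = zip(*[_phase_coherence_amplitude(cmap, p, dimer_rise=dimer)
                        for p in peaks])
    ph, co, amp = np.array(ph), np.array(co), np.array(amp)
    # a protofilament whose dimer amplitude collapses relative to its peers
    # averaged in- and out-of-register stretches: cap its coherence so its
    # contacts come out ND ("aberrant protofilament")
    med = np.median(amp)
    if med > 0:
        co = np.minimum(co, amp / med)
    return classify_contacts(ph, co, spec, segment=segment,
                             z_range=z_range, pf_angles=cmap.theta[peaks])


def layerline_filter(image: np.ndarray, pixel_size: float,
                     dimer_rise: float = 8.0, axial_axis: int = 1,
                     bandwidth: float = 0.15) -> np.ndarray:
    """Keep only the equatorial and +/-1/dimer_rise layer lines of a 2-D image.

    ``bandwidth`` is the half-width of each retained band as a fraction of
    the layer-line frequency. The axial extent must cover at least two dimer
    repeats for the layer line to be resolvable.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise CallerError("layerline_filter expects a 2-D image")
    n_ax = image.shape[axial_axis]
    if n_ax * pixel_size < 2 * dimer_rise:
        raise CallerError("region shorter than two dimer repeats axially")
    f_ax = np.fft.fftfreq(n_ax, d=pixel_size)
    f0 = 1.0 / dimer_rise
    keep = (np.abs(f_ax) <= bandwidth * f0) \
        | (np.abs(np.abs(f_ax) - f0) <= bandwidth * f0)
    ft = np.fft.fft(image, axis=axial_axis)
    shape = [1, 1]
    shape[axial_axis] = n_ax
    ft = ft * keep.reshape(shape)
    return np.fft.ifft(ft, axis=axial_axis).real


def phase_offset_test(profile_a: np.ndarray, profile_b: np.ndarray,
                      dz: float, dimer_rise: float = 8.0,
                      monomer_rise: float = 4.0) -> tuple[str, str]:
    """Relative registry of two axial profiles at the dimer repeat.

    Returns ('in_phase'|'out_of_phase', 'even'|'odd'). An offset within half
    a monomer (circularly) of zero is in phase (even parity); otherwise the
    profiles are offset by an odd number of monomers - the signature of a
    registry shift across a hole.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise CallerError("profiles must have equal length")
    z = np.arange(len(a)) * dz
    ca = np.sum((a - a.mean()) * np.exp(-2j * np.pi * z / dimer_rise))
    cb = np.sum((b - b.mean()) * np.exp(-2j * np.pi * z / dimer_rise))
    dpsi = (np.angle(ca) - np.angle(cb)) / (2 * np.pi) * dimer_rise
    if _circdist(dpsi, 0.0, dimer_rise) < monomer_rise / 2.0:
        return "in_phase", "even"
    return "out_of_phase", "odd"
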