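"""Microtubule surface-lattice geometry: protofilaments, seams, holes.

The microtubule wall is modelled as N protofilaments (head-to-tail stacks of
alpha/beta-tubulin dimers, 8 nm dimer repeat) closed into a tube. Moving
laterally from one protofilament to the next climbs by a stagger rho; one
full turn of N lateral contacts climbs exactly S monomers (the S-start
helix), so rho = S * monomer_rise / N. A lateral contact is B-type
(homotypic, alpha-alpha/beta-beta) when the dimer registries of the two
protofilaments differ by rho, and A-type (heterotypic, the "seam") when they
differ by rho plus one monomer. Tube closure forces the number of A-type
contacts to share the parity of S, which is why a 13_3 microtubule needs at
least one seam and a 13_4 microtubule can have none.

Registry phases are held internally as exact integers in "ticks" of
monomer_rise / N (so monomer_rise = N ticks, dimer_rise = 2N ticks and
rho = S ticks); all closure and parity arithmetic is exact, and nm values
are produced only at the API surface.

Holes (missing monomers inside the wall) of odd size flip the dimer registry
of their protofilament above the hole by one monomer, toggling both flanking
contacts between A and B; even-size holes leave the contact map unchanged.
Axial positions where the seam set changes are "lattice-type transitions".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import ceil, pi

import numpy as np
import pandas as pd

__all__ = [
    "LatticeSpec",
    "Hole",
    "MTLattice",
    "ContactMap",
    "Transition",
    "make_spec",
    "min_seams",
    "complete_seams",
    "build_lattice",
    "insert_hole",
    "find_transitions",
    "dimer_stats",
    "lattice_coordinates",
    "classify_phase_offsets",
]

N_RANGE = (8, 17)
S_VALUES = (2, 3, 4)

#: nm of slack allowed when typing contacts from continuous (measured) phases
PHASE_TOLERANCE_NM = 1.0


class LatticeError(ValueError):
    """Raised for invalid lattice specifications or operations."""


@dataclass(frozen=True)
class LatticeSpec:
    """Protofilament/helix-start geometry of one microtubule class (N_S).

    Parameters are in nm. ``rho`` is the lateral stagger per B-type contact;
    one lateral turn of N contacts climbs S monomers: N * rho = S * monomer_rise.
    """

    N: int
    S: int
    monomer_rise: float = 4.0
    inter_pf_spacing: float = 5.0
    handedness: int = -1  # -1: monomer helices left-handed (the native choice)

    def __post_init__(self) -> None:
        if not (N_RANGE[0] <= self.N <= N_RANGE[1]):
            raise LatticeError(f"N out of range: {self.N} not in [{N_RANGE[0]}, {N_RANGE[1]}]")
        if self.S not in S_VALUES:
            raise LatticeError(f"S out of range: {self.S} not in {S_VALUES}")
        if self.monomer_rise <= 0:
            raise LatticeError(f"monomer_rise must be > 0, got {self.monomer_rise}")
        if self.inter_pf_spacing <= 0:
            raise LatticeError(f"inter_pf_spacing must be > 0, got {self.inter_pf_spacing}")
        if self.handedness not in (-1, 1):
            raise LatticeError(f"handedness must be +/-1, got {self.handedness}")

    @property
    def dimer_rise(self) -> float:
        return 2.0 * self.monomer_rise

    @property
    def rho(self) -> float:
        """Lateral stagger per B contact (nm): N * rho = S * monomer_rise."""
        return self.S * self.monomer_rise / self.N

    @property
    def wall_radius(self) -> float:
        """Mid-wall radius (nm) from the lateral circumference."""
        return self.N * self.inter_pf_spacing / (2.0 * pi)

    @property
    def name(self) -> str:
        return f"{self.N}_{self.S}"

    # -- exact tick arithmetic -------------------------------------------
    @property
    def ticks_per_monomer(self) -> int:
        return self.N

    @property
    def ticks_per_dimer(self) -> int:
        return 2 * self.N

    def tick_nm(self) -> float:
        return self.monomer_rise / self.N

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "S": self.S,
            "monomer_rise": self.monomer_rise,
            "inter_pf_spacing": self.inter_pf_spacing,
            "handedness": self.handedness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatticeSpec":
        return cls(**d)


def make_spec(N: int, S: int, monomer_rise: float = 4.0,
              inter_pf_spacing: float = 5.0) -> LatticeSpec:
    """Validated lattice specification for an N_S microtubule class."""
    return LatticeSpec(N=N, S=S, monomer_rise=monomer_rise,
                       inter_pf_spacing=inter_pf_spacing)


def min_seams(spec: LatticeSpec) -> int:
    """Minimal number of A-type contacts a closed N_S tube can carry.

    Closure forces n_A == S (mod 2), so the minimum is 0 for even S and 1
    for odd S (the canonical single seam of a 13_3 microtubule).
    """
    return spec.S % 2


def complete_seams(spec: LatticeSpec, forced: set[int] | frozenset[int]) -> set[int]:
    """Extend a forced seam set to satisfy the closure parity n_A == S (mod 2).

    If parity already matches, ``forced`` is returned unchanged. Otherwise one
    contact is added: the first free contact cyclically after the highest
    forced index (contact 0 when ``forced`` is empty). Where the closure-
    imposed seam actually sits is not observable from parity alone; adjacency
    to an existing seam is the convention adopted here.
    """
    forced = set(forced)
    for i in forced:
        if not (0 <= i < spec.N):
            raise LatticeError(f"seam contact index {i} out of range [0, {spec.N})")
    if len(forced) % 2 == spec.S % 2:
        return forced
    start = (max(forced) + 1) % spec.N if forced else 0
    for off in range(spec.N):
        cand = (start + off) % spec.N
        if cand not in forced:
            return forced | {cand}
    raise LatticeError("no free contact available to restore closure parity")


@dataclass(frozen=True)
class Hole:
    """k missing monomers on one protofilament, starting at axial z (nm).

    Odd k flips the dimer registry of the protofilament above z by one
    monomer (toggling both flanking contacts A<->B); even k changes nothing.
    """

    pf: int
    z: float
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise LatticeError(f"hole size k must be >= 1, got {self.k}")

    def to_dict(self) -> dict:
        return {"pf": self.pf, "z": self.z, "k": self.k}


@dataclass(frozen=True)
class ContactMap:
    """Contact types on a grid of axial samples.

    ``types`` is an (n_z, N) array of 'A'/'B' codes; contact i joins
    protofilaments i and (i+1) mod N.
    """

    z: np.ndarray
    types: np.ndarray

    def seam_set(self, iz: int) -> frozenset[int]:
        return frozenset(int(i) for i in np.nonzero(self.types[iz] == "A")[0])


@dataclass(frozen=True)
class MTLattice:
    """A concrete microtubule lattice: base seam set plus holes.

    ``base_offsets`` holds, per protofilament, the registry offset at z = 0
    in ticks (exact integers modulo the 2N-tick dimer repeat), produced by
    walking contacts from protofilament 0. Odd holes flip registries above
    their z. Occupancy is derived from the hole list.
    """

    spec: LatticeSpec
    length: float
    base_seams: frozenset[int]
    base_offsets: tuple[int, ...]
    holes: tuple[Hole, ...] = ()

    # -- registry bookkeeping --------------------------------------------
    def _flips_below(self, pf: int, z: float) -> int:
        return sum(1 for h in self.holes if h.pf == pf and h.k % 2 == 1 and h.z <= z)

    def phase_ticks(self, pf: int, z: float) -> int:
        """Dimer-registry phase of protofilament pf at height z, in ticks."""
        n = self.spec.ticks_per_monomer
        return (self.base_offsets[pf] + n * self._flips_below(pf, z)) % (2 * n)

    def pf_phase(self, pf: int, z: float) -> float:
        """Registry phase in nm, within [0, dimer_rise)."""
        return self.phase_ticks(pf, z) * self.spec.tick_nm()

    def contact_types_at(self, z: float) -> np.ndarray:
        """'A'/'B' type of each of the N contacts at height z (exact)."""
        spec = self.spec
        n, two_n = spec.ticks_per_monomer, spec.ticks_per_dimer
        phases = [self.phase_ticks(i, z) for i in range(spec.N)]
        out = np.empty(spec.N, dtype="<U1")
        for i in range(spec.N):
            d = (phases[(i + 1) % spec.N] - phases[i]) % two_n
            if d == spec.S % two_n:
                out[i] = "B"
            elif d == (spec.S + n) % two_n:
                out[i] = "A"
            else:  # cannot happen for lattices built by walking contacts
                raise LatticeError(f"contact {i} offset {d} ticks is neither rho nor rho+monomer")
        return out

    def seam_set_at(self, z: float) -> frozenset[int]:
        return frozenset(int(i) for i in np.nonzero(self.contact_types_at(z) == "A")[0])

    def contact_map(self, sample_step: float | None = None) -> ContactMap:
        step = sample_step or self.spec.monomer_rise
        z = np.arange(0.0, self.length, step)
        types = np.stack([self.contact_types_at(zz) for zz in z])
        return ContactMap(z=z, types=types)

    # -- occupancy --------------------------------------------------------
    def n_sites(self) -> int:
        """Monomer sites per protofilament within [0, length)."""
        return int(self.length / self.spec.monomer_rise + 1e-9)

    def site_z(self, pf: int, m: int) -> float:
        frac = (self.base_offsets[pf] % self.spec.ticks_per_monomer) * self.spec.tick_nm()
        return m * self.spec.monomer_rise + frac

    def hole_start_site(self, hole: Hole) -> int:
        frac = (self.base_offsets[hole.pf] % self.spec.ticks_per_monomer) * self.spec.tick_nm()
        return max(0, round((hole.z - frac) / self.spec.monomer_rise))

    def missing_sites(self, pf: int) -> set[int]:
        out: set[int] = set()
        for h in self.holes:
            if h.pf == pf:
                start = self.hole_start_site(h)
                out.update(range(start, start + h.k))
        return out

    def occupancy(self) -> np.ndarray:
        """(N, n_sites) boolean array: True where a monomer is present."""
        occ = np.ones((self.spec.N, self.n_sites()), dtype=bool)
        for pf in range(self.spec.N):
            for m in self.missing_sites(pf):
                if m < occ.shape[1]:
                    occ[pf, m] = False
        return occ

    def is_beta(self, pf: int, m: int) -> bool:
        """True if site m of protofilament pf is a beta monomer.

        The monomer at registry offset 0 is alpha, at +monomer_rise beta;
        odd holes below flip the assignment.
        """
        n = self.spec.ticks_per_monomer
        j = self.base_offsets[pf] // n  # 0 -> site 0 is alpha, 1 -> beta
        flips = self._flips_below(pf, self.site_z(pf, m))
        return (m + j + flips) % 2 == 1

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "length": self.length,
            "seams": sorted(self.base_seams),
            "holes": [h.to_dict() for h in self.holes],
        }

    def to_json(self, path=None) -> str:
        doc = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_dict(cls, d: dict) -> "MTLattice":
        lat = build_lattice(LatticeSpec.from_dict(d["spec"]), set(d["seams"]), d["length"])
        for h in d.get("holes", []):
            lat = insert_hole(lat, h["pf"], h["z"], h["k"])
        return lat

    @classmethod
    def from_json(cls, path) -> "MTLattice":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_lattice(spec: LatticeSpec, seams: set[int] | frozenset[int],
                  length: float) -> MTLattice:
    """Close an N_S tube with the requested seam set.

    Registry offsets are assigned by walking contacts from protofilament 0
    (offset 0), adding rho per B contact and rho + monomer_rise per A
    contact. Closure requires |seams| == S (mod 2); violating sets are
    rejected rather than silently repaired.
    """
    seams = frozenset(int(i) for i in seams)
    for i in seams:
        if not (0 <= i < spec.N):
            raise LatticeError(f"seam contact index {i} out of range [0, {spec.N})")
    if len(seams) % 2 != spec.S % 2:
        raise LatticeError(
            f"closure violated: {len(seams)} seam(s) with S = {spec.S} "
            f"(need |seams| == S mod 2)")
    if length <= 0:
        raise LatticeError(f"length must be > 0, got {length}")
    n, two_n = spec.ticks_per_monomer, spec.ticks_per_dimer
    offsets = [0]
    for i in range(spec.N - 1):
        step = spec.S + (n if i in seams else 0)
        offsets.append((offsets[-1] + step) % two_n)
    lat = MTLattice(spec=spec, length=float(length), base_seams=seams,
                    base_offsets=tuple(offsets))
    assert lat.seam_set_at(0.0) == seams  # closure self-check
    return lat


def insert_hole(lattice: MTLattice, pf: int, z: float, k: int) -> MTLattice:
    """Return a new lattice with k monomers removed from pf at height z.

    Odd k toggles both contacts flanking pf above z; even k only removes
    density. Overlapping an existing hole on the same protofilament is an
    error.
    """
    if not (0 <= pf < lattice.spec.N):
        raise LatticeError(f"pf {pf} out of range [0, {lattice.spec.N})")
    if not (0 <= z < lattice.length):
        raise LatticeError(f"hole z = {z} outside lattice [0, {lattice.length})")
    hole = Hole(pf=pf, z=float(z), k=int(k))
    start = lattice.hole_start_site(hole)
    new_sites = set(range(start, start + k))
    for h in lattice.holes:
        if h.pf == pf:
            s0 = lattice.hole_start_site(h)
            if new_sites & set(range(s0, s0 + h.k)):
                raise LatticeError(
                    f"hole at pf {pf}, z = {z} overlaps existing hole at z = {h.z}")
    return replace(lattice, holes=lattice.holes + (hole,))


@dataclass(frozen=True)
class Transition:
    """Axial position where the seam set changes."""

    z: float
    before: frozenset[int]
    after: frozenset[int]


def find_transitions(lattice: MTLattice,
                     sample_step: float | None = None) -> tuple[list[Transition], float]:
    """Scan the lattice axially and report seam-set changes.

    Returns the transition list and the frequency in events per micron.
    ``sample_step`` must not exceed the dimer rise or changes could be
    skipped.
    """
    step = sample_step if sample_step is not None else lattice.spec.monomer_rise
    if step > lattice.spec.dimer_rise:
        raise LatticeError(f"sample_step {step} exceeds dimer_rise {lattice.spec.dimer_rise}")
    if lattice.length <= 0:
        return [], 0.0
    z_grid = np.arange(0.0, lattice.length, step)
    transitions: list[Transition] = []
    prev = lattice.seam_set_at(z_grid[0])
    for zz in z_grid[1:]:
        cur = lattice.seam_set_at(zz)
        if cur != prev:
            transitions.append(Transition(z=float(zz), before=prev, after=cur))
            prev = cur
    freq = len(transitions) / (lattice.length / 1000.0)
    return transitions, freq


def dimer_stats(spec: LatticeSpec, length_um: float = 1.0,
                transition_freq: float | None = None) -> dict:
    """Dimer content of a microtubule and dimers per lattice-type transition.

    A 13-protofilament microtubule packs N * 1000 / dimer_rise = 1625 dimers
    per micron; at 0.1 transitions per micron that is one transition every
    16,250 dimers.
    """
    if length_um < 0:
        raise LatticeError(f"length must be >= 0, got {length_um}")
    dimers_per_um = spec.N * 1000.0 / spec.dimer_rise
    out = {
        "dimer_count": dimers_per_um * length_um,
        "dimers_per_um": dimers_per_um,
        "dimers_per_transition": None,
    }
    if transition_freq is not None:
        if transition_freq < 0:
            raise LatticeError(f"transition_freq must be >= 0, got {transition_freq}")
        if transition_freq == 0:
            out["dimers_per_transition"] = float("inf")
            out["undefined"] = True
        else:
            out["dimers_per_transition"] = dimers_per_um / transition_freq
    return out


def lattice_coordinates(lattice: MTLattice, decoration_offset: float = 4.5) -> pd.DataFrame:
    """3-D site table of the lattice on its cylinder.

    One row per occupied monomer (x, y, z in nm, pf, site index, monomer
    'alpha'/'beta', decorated flag) plus one row per decoration marker
    (kinesin motor domain bound to an occupied beta monomer) at
    wall_radius + decoration_offset. Protofilament angles run clockwise
    about +z for handedness -1, making the rendered S-start monomer helix
    left-handed.
    """
    spec = lattice.spec
    r_wall = spec.wall_radius
    rows = []
    for pf in range(spec.N):
        theta = lattice.spec.handedness * 2.0 * pi * pf / spec.N
        cx, sy = np.cos(theta), np.sin(theta)
        missing = lattice.missing_sites(pf)
        for m in range(lattice.n_sites()):
            if m in missing:
                continue
            z = lattice.site_z(pf, m)
            if z >= lattice.length:
                continue
            beta = lattice.is_beta(pf, m)
            rows.append((r_wall * cx, r_wall * sy, z, pf, m,
                         "beta" if beta else "alpha", False))
            if beta:
                r_dec = r_wall + decoration_offset
                rows.append((r_dec * cx, r_dec * sy, z, pf, m, "beta", True))
    return pd.DataFrame(rows, columns=["x", "y", "z", "pf", "site", "monomer", "decorated"])


def classify_phase_offsets(delta_nm: np.ndarray, spec: LatticeSpec,
                           tolerance: float = PHASE_TOLERANCE_NM) -> np.ndarray:
    """Type contacts from continuous registry differences (nm, mod dimer_rise).

    B where the circular distance to rho is below tolerance, A where the
    distance to rho + monomer_rise is, 'N' (not determined) elsewhere.
    """
    d = np.asarray(delta_nm, dtype=float) % spec.dimer_rise
    period = spec.dimer_rise

    def circdist(a, b):
        diff = np.abs(a - b) % period
        return np.minimum(diff, period - diff)

    out = np.full(d.shape, "N", dtype="<U1")
    out[circdist(d, spec.rho) < tolerance] = "B"
    out[circdist(d, spec.rho + spec.monomer_rise) < tolerance] = "A"
    return out


def export_point_model(df: pd.DataFrame, path, voxel_size: float = 1.0) -> None:
    """Write sites as an IMOD-style ASCII point list: object contour x y z.

    Coordinates are converted to voxel units (0-based). Object 1 holds
    undecorated monomer sites, object 2 decoration sites.
    """
    with open(path, "w") as fh:
        fh.write("# object contour x y z (voxel units, 0-based)\n")
        for obj, sub in ((1, df[~df.decorated]), (2, df[df.decorated])):
            for contour, (_, row) in enumerate(sub.iterrows(), start=1):
                fh.write(f"{obj} {contour} {row.x / voxel_size:.3f} "
                         f"{row.y / voxel_size:.3f} {row.z / voxel_size:.3f}\n")
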