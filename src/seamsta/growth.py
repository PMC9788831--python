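"""Stochastic microtubule tip elongation with lateral-only additions.

Classical elongation adds dimers through longitudinal bonds (with or without
simultaneous lateral ones), which can only propagate the existing lattice.
If an incoming dimer instead engages a *lateral* bond to a taller neighbour
protofilament without longitudinal support, it leaves a vacancy (hole)
beneath it. A homotypic lateral bond preserves the dimer registry (the gap
has an even number of monomers; the contact map is unchanged); a heterotypic
bond shifts the registry by one monomer (odd gap), toggling both flanking
contacts A<->B — creating or removing seams, and at an existing seam
displacing it laterally by one protofilament.

The simulator is parameterized by per-addition probabilities, not kinetic
rate constants, and makes no claim to kinetics: ``p_lat`` is the chance an
addition is lateral-only, ``q_flip`` the chance such an addition takes the
registry-shifted (odd-gap) configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import LatticeError, LatticeSpec, MTLattice, build_lattice, insert_hole, min_seams

__all__ = ["GrowthParams", "GrowthEvent", "grow", "defect_frequency"]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one growth run (lengths in nm, probabilities in [0,1])."""

    spec: LatticeSpec
    target_length: float = 2000.0
    p_lat: float = 0.02
    q_flip: float = 0.5
    odd_gap_sizes: tuple[int, ...] = (1,)
    even_gap_sizes: tuple[int, ...] = (2,)
    seams: frozenset[int] | None = None  # None -> minimal seam set
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_lat <= 1.0 and 0.0 <= self.q_flip <= 1.0):
            raise LatticeError("p_lat and q_flip must lie in [0, 1]")
        if any(k < 1 for k in self.odd_gap_sizes + self.even_gap_sizes):
            raise LatticeError("gap sizes must be >= 1")
        if any(k % 2 == 0 for k in self.odd_gap_sizes):
            raise LatticeError("odd_gap_sizes must all be odd")
        if any(k % 2 == 1 for k in self.even_gap_sizes):
            raise LatticeError("even_gap_sizes must all be even")
        if self.target_length < self.spec.dimer_rise:
            raise LatticeError(
                f"target_length {self.target_length} nm is shorter than one dimer")


@dataclass(frozen=True)
class GrowthEvent:
    """One dimer addition: kind, protofilament, axial position, gap size."""

    kind: str  # longitudinal | lateral_even | lateral_odd | seam_step
    pf: int
    z: float
    k: int = 0


def _initial_seams(params: GrowthParams) -> frozenset[int]:
    if params.seams is not None:
        return frozenset(params.seams)
    return frozenset(range(min_seams(params.spec)))


def grow(params: GrowthParams) -> tuple[MTLattice, list[GrowthEvent]]:
    """Elongate an N_S tube to target length, recording every addition.

    Each step elongates one uniformly chosen protofilament (so tip
    raggedness emerges from the multinomial addition order rather than an
    imposed tip model). An addition is longitudinal with probability
    1 - p_lat; otherwise it is lateral-only, which requires a neighbour
    protofilament locally taller by at least k + 2 monomers (if none
    qualifies the event is re-drawn as longitudinal). Holes left by
    lateral-only additions are inserted into the final lattice, so the
    grown tube satisfies every closure invariant by construction.
    """
    rng = np.random.default_rng(params.seed)
    spec = params.spec
    mr = spec.monomer_rise
    seams = _initial_seams(params)
    n_target = 2 * int(np.ceil(params.target_length / spec.dimer_rise))  # monomers per pf

    # per-pf axial stagger fraction, so logged event z matches true site z
    probe = build_lattice(spec, seams, spec.dimer_rise * 2)
    frac = [(off % spec.ticks_per_monomer) * spec.tick_nm()
            for off in probe.base_offsets]

    heights = np.full(spec.N, 2, dtype=int)  # one dimer seeded per pf
    # current A/B state of each contact at the tip, tracked to label seam steps
    tip_seams = set(seams)
    events: list[GrowthEvent] = []
    holes: list[tuple[int, int, int]] = []  # (pf, start_site, k)

    while heights.min() < n_target:
        pf = int(rng.integers(spec.N))
        if heights[pf] >= n_target:
            continue
        lateral = rng.random() < params.p_lat
        flip = rng.random() < params.q_flip
        sizes = params.odd_gap_sizes if flip else params.even_gap_sizes
        k = int(sizes[rng.integers(len(sizes))]) if len(sizes) > 1 else int(sizes[0])
        left, right = (pf - 1) % spec.N, (pf + 1) % spec.N
        can_lateral = max(heights[left], heights[right]) >= heights[pf] + k + 2
        if lateral and can_lateral:
            z = float(heights[pf]) * mr + frac[pf]
            holes.append((pf, int(heights[pf]), k))
            if k % 2 == 1:
                c_left, c_right = (pf - 1) % spec.N, pf
                at_seam = c_left in tip_seams or c_right in tip_seams
                tip_seams.symmetric_difference_update({c_left, c_right})
                events.append(GrowthEvent("seam_step" if at_seam else "lateral_odd",
                                          pf, z, k))
            else:
                events.append(GrowthEvent("lateral_even", pf, z, k))
            heights[pf] += k + 2
        else:
            events.append(GrowthEvent("longitudinal", pf, float(heights[pf]) * mr + frac[pf], 0))
            heights[pf] += 2

    length = float(n_target) * mr
    lattice = build_lattice(spec, seams, length)
    for pf, start, k in holes:
        z = lattice.site_z(pf, start)
        if z < length:
            lattice = insert_hole(lattice, pf, z, k)
    return lattice, events


def defect_frequency(replicates: list[tuple[MTLattice, list[GrowthEvent]]],
                     n_boot: int = 1000, seed: int = 0) -> dict:
    """Mean lattice-type transition frequency across grown replicates (per um).

    Returns the per-replicate frequencies, their mean, and a 95% percentile
    bootstrap interval (seeded).
    """
    from .lattice import find_transitions

    if not replicates:
        raise LatticeError("defect_frequency requires at least one replicate")
    freqs = np.array([find_transitions(lat)[1] for lat, _ in replicates])
    rng = np.random.default_rng(seed)
    boots = np.array([
        rng.choice(freqs, size=len(freqs), replace=True).mean()
        for _ in range(n_boot)
    ])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "frequencies": freqs,
        "mean": float(freqs.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": n_boot,
    }
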