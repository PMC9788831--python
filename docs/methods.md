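# Methods

## Lattice model

A microtubule class is written N_S: N protofilaments, S-start monomer
helices. The geometry is fixed by three lengths: the monomer rise
a = 4.0 nm (dimer rise 8.0 nm; the crystallographic 4.05/8.1 nm values are
deliberately rounded so all registry arithmetic is exact), the
protofilament spacing 5.0 nm (wall radius r = N·w/2π, ≈ 10.3 nm for 13
protofilaments, ~25 nm outer diameter once decoration is added), and the
lateral stagger per contact ρ, defined by helical closure: one turn of N
contacts climbs exactly S monomers, so ρ = S·a/N. The stagger is not a
free parameter — it is the unique value that lets an S-start helix close.

A lateral contact between protofilaments i and i+1 is typed from the dimer
registry difference of the two stacks: B (homotypic) when the offset is ρ
modulo the dimer rise, A (seam, heterotypic) when it is ρ + a. Because the
contact offsets around a closed ring must sum to 0 modulo the dimer rise,
the A-contact count satisfies n_A ≡ S (mod 2) at every height — the source
of the "13_3 needs one seam / 13_4 needs none" rule and of the parity
invariant every simulated or called lattice is checked against.

Internally all registry phases are integers in units of a/N ("ticks":
a = N ticks, dimer = 2N ticks, ρ = S ticks). Closure, parity, hole flips
and contact typing are exact integer arithmetic modulo 2N; nanometres
appear only at the API surface. Contact typing from *measured* (continuous)
phases uses a ±1.0 nm tolerance around ρ and ρ + a; for N ≤ 17 the two
windows never overlap and leave genuine dead zones that map to ND.

Holes remove k consecutive monomers from one protofilament. An odd k flips
the registry of that protofilament above the hole by one monomer, toggling
both flanking contacts A↔B; an even k changes nothing but occupancy. Holes
are instantaneous registry switches — no elastic relaxation of the
neighbouring lattice is modelled. Contact indexing: contact i joins
protofilaments i and (i+1) mod N; protofilament angles run clockwise about
+z (handedness −1) so the rendered S-start monomer helix is left-handed.
When a forced seam set has the wrong parity, `complete_seams` adds one
contact cyclically after the highest forced index; where the
closure-imposed seam really sits is not observable from parity alone, and
adjacency to an existing seam is simply the convention here.

`find_transitions` scans the lattice at a fixed axial step (default one
monomer) and reports seam-set changes. Two odd holes falling inside the
same sampling step merge into one reported transition; the per-monomer step
makes this essentially impossible for generated lattices, and the brute
force oracle used in the tests scans at the same granularity.

## Growth simulator

The simulator makes no kinetic claims: it is parameterized by per-addition
probabilities, not rate constants. Each step elongates one uniformly chosen
protofilament by one dimer. With probability `p_lat` the addition is
lateral-only: the dimer binds a neighbour protofilament that is locally
taller by at least k + 2 monomers (if none qualifies the event reverts to
longitudinal), leaving a k-monomer vacancy beneath it. With probability
`q_flip` the lateral bond is registry-shifting (odd gap, default k = 1):
both flanking contacts toggle, which creates or removes seam pairs, and at
a contact that is already a seam realizes the one-protofilament seam step.
Otherwise the bond is homotypic (even gap, default k = 2) and the contact
map is untouched. Tip raggedness — the height disparity lateral-only
capture needs — emerges from the multinomial addition order rather than an
imposed tip-structure model; a strict round-robin visit order would keep
all tips level and could never trigger a lateral-only event, which is why
single random steps are used. `q_flip` defaults to 0.5 as a neutral choice:
nothing in the data constrains the odd/even event ratio, and even-gap
events are invisible to seam analysis anyway.

Grown lattices satisfy every closure invariant by construction (the final
tube is rebuilt from the base seam set plus the recorded holes), and the
event log obeys the exact law the tests enforce: the seam set changes
across z if and only if an odd-gap event occurred there.

## Synthetic tomograms

Density is a sum of isotropic Gaussian blobs: one per occupied monomer on
the wall cylinder (σ 1.6 nm) and one per occupied β monomer on the
decoration shell at wall radius + 4.5 nm (σ 1.8 nm, amplitude 0.8 of the
monomer blob), at 0.8 nm voxels. None of these widths is measured from
data; they are chosen so decoration ridges are resolved per protofilament
and the 8 nm repeat is strong — the phantom is a geometry testbed, not a
physical scattering model. Voxel indices are node-centered (index i at
coordinate i·voxel).

The missing wedge zeroes Fourier coefficients whose (k_beam, k_axis)
direction lies within 90° − tilt_range of the beam axis; dual-axis
acquisition replaces the wedge with the intersection pyramid of two
orthogonal tilt axes. The mask depends only on |k| components, so it is
Hermitian-symmetric and the output stays real. Beam direction is grid x,
tilt axis y, microtubule axis z. Noise is additive white Gaussian with
σ = peak amplitude / SNR. Interface damage multiplies density within a
given depth of one x face — outside the wall radius, so tubulin is spared —
by an attenuation factor (default 0.3; the real attenuation is not
quantified anywhere, so the factor is free and recorded in the volume
metadata). No CTF, no fiducials, no dose weighting, no reconstruction
artifacts beyond the wedge: passing tests show the *geometry* pipeline is
correct, not that the caller would survive every pathology of real
tomograms (membranous background, lattice bending, magnification errors).

## Sub-tomogram averaging

Motive lists sample the axis polyline every 8 nm of arc length (half-open,
so an 800 nm axis yields 100 points); orientations are the minimal
rotations taking the reference +z onto the local tangent, which keeps the
in-plane axes untwisted. Boxes (default 48 voxels ≈ 38 nm) are resampled
with trilinear interpolation. Alignment is masked cross-correlation
(cylindrical annulus 6–20 nm, mean-subtracted, unit-normalized) with the
rotational search restricted to ± half the angular protofilament spacing in
1° steps — protofilament identity cannot hop — and shifts found by FFT
correlation with quadratic peak interpolation to half-voxel precision; ties
break toward the smallest |rotation|, then the smallest |shift|. No
missing-wedge compensation is applied during alignment: all synthetic boxes
share one wedge orientation, so the wedge bias is common mode. This is a
deliberate simplification relative to constrained-correlation approaches
and would need revisiting for boxes with heterogeneous wedge orientations.

Segmented averaging splits the motive list into n contiguous segments whose
sizes differ by at most one and re-aligns each segment against the
whole-filament average as template (one iteration).

## Lattice calling

The volume (or a segment average) is unwrapped onto a cylinder at the
decoration radius — known from render metadata, or estimated as the radius
maximizing the dimer-repeat spectral power outside the wall peak.
Protofilament ridges are found on the per-angle amplitude of the 8 nm
component (not the plain z-mean, which the wedge modulates with a strong
twofold envelope): N is the dominant angular Fourier harmonic within 8–17,
ridge angles come from direct peak detection when it agrees with that
harmonic and from the harmonic's phase comb otherwise. S is the candidate
in {2, 3, 4} minimizing the circular misfit between measured ridge-to-ridge
phase steps and ρ_S or ρ_S + a.

Per protofilament, the decoration phase ψ is the phase of the 8 nm Fourier
component of the ridge's axial profile, and coherence is that component's
RMS amplitude relative to the profile's total non-DC RMS amplitude (an
energy ratio, robust to the spectral leakage of finite windows). A segment
average that mixes in- and out-of-register stretches cancels the 8 nm
component on the affected protofilament; because the residual after
cancellation can itself be 8 nm-ish, the effective coherence is additionally
capped by the protofilament's absolute dimer amplitude relative to the
per-segment median (an aberrant protofilament is weak compared to its
peers; measured separations are ~0.06 vs ≥ 0.93 of the median). Contacts
touching a protofilament with coherence below 0.3 are ND, and the sphere
model colors them red. The 0.3 threshold and the 1.0 nm typing tolerance
are package choices calibrated on the synthetic phantoms; the source
material for this analysis style states only qualitative criteria.

Transition counting compares consecutive determined segments; ND-containing
segments are bridged and any change is localized to the bridged interval.
A same-size seam set displaced to an adjacent contact is a "seam-offset";
differing N or S is an "N_S change" counted once; anything else is a
"seam-count" change. Condition tables report both frequency conventions —
aggregate (Σ transitions / Σ length) and per-microtubule mean ± SD — since
they differ on heterogeneous data and each answers a different question.
The rank-sum test enumerates all midrank assignments exactly up to 12
pooled observations and otherwise uses the normal approximation with tie
correction.

## Problem sizes and fixtures

Desk-scale defaults keep every workflow on one CPU: single-tube fixtures
are 640 nm (four ~160 nm segments, ~76 sub-volumes), per-class end-to-end
checks 176 nm, and the planted-rate condition is 20 microtubules of 1.6 µm
with odd holes planted as a Poisson process at 0.25 µm⁻¹. The planted rate
sits in the low-defect regime on purpose: at rates around 1 µm⁻¹ a fixed
~160 nm segmentation structurally undercounts (~40% in simulation), because
multiple transitions inside one segment interval collapse and
back-and-forth registry flips cancel — the same effect that finer
re-segmentation exposes on real filaments. Recovery "within sampling error"
is therefore only a meaningful claim where segment-scale saturation is
negligible. The condition fixture bypasses rendering and derives its
segment calls from ground-truth lattices; rendering-based recovery is
exercised separately per N_S class.

Every stochastic stage consumes a seed derived deterministically from a
global seed and the stage name (CRC32-based, < 2³¹), so fixtures and
pipeline runs are byte-reproducible.

## Known limitations

- Protofilament skew and the associated local dislocations of 12_2/13_4
  tubes are not modelled; lattices are straight cylinders (a curved-axis
  hook exists in the motive-list layer, but rendering is straight).
- Tubulin polarity, GTP state and dimer conformation are out of scope; the
  caller reads decoration phases, so α/β assignment is relative, exactly as
  sphere models built on kinesin density are.
- Dynamic instability (catastrophe, rescue, GTP caps) is not simulated; the
  growth model stops at lattice bookkeeping.
- MRC support is mode 2 (float32) only, which is all the pipeline emits.
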