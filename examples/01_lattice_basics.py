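"""Surface-lattice geometry: seams, closure parity, holes, transitions.

Builds a 13-protofilament, 3-start microtubule with its canonical single
seam, punches a one-monomer hole into the wall, and shows how the seam set
changes above the hole.
"""

import numpy as np

from seamsta import (
    build_lattice,
    complete_seams,
    dimer_stats,
    find_transitions,
    insert_hole,
    make_spec,
    min_seams,
)

spec = make_spec(13, 3)
print(f"13_3 geometry: stagger rho = {spec.rho:.3f} nm per lateral contact, "
      f"wall radius = {spec.wall_radius:.2f} nm")
print(f"closure parity: a 13_3 tube needs at least {min_seams(spec)} seam, "
      f"a 13_4 tube {min_seams(make_spec(13, 4))}")
print(f"forcing one A contact on a 12_2 tube closes with seams "
      f"{sorted(complete_seams(make_spec(12, 2), {3}))}")

lattice = build_lattice(spec, {0}, length=640.0)
print(f"\nbuilt 640 nm lattice, seam set at z=0: {sorted(lattice.seam_set_at(0))}")

# an odd (one-monomer) hole flips the registry of its protofilament above it
holed = insert_hole(lattice, pf=6, z=320.0, k=1)
print(f"after a k=1 hole on pf 6 at z=320 nm:")
print(f"  seams below: {sorted(holed.seam_set_at(100))}")
print(f"  seams above: {sorted(holed.seam_set_at(500))}   (contacts 5 and 6 toggled)")

transitions, freq = find_transitions(holed)
print(f"  lattice-type transitions: {len(transitions)} "
      f"({freq:.2f} per micron over 0.64 um)")

stats = dimer_stats(spec, length_um=1.0, transition_freq=0.1)
print(f"\ndimer arithmetic: {stats['dimer_count']:.0f} dimers per micron of 13-pf "
      f"lattice; at 0.1 transitions/um that is one transition every "
      f"{stats['dimers_per_transition']:.0f} dimers")
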