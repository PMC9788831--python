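"""Registered desk-scale scenarios with exact ground truth.

Each fixture reproduces, in miniature, one situation the segmented
averaging strategy was designed to resolve:

- ``fig3_5to3seams``: a 13_3 tube that starts with five seams and drops to
  three mid-length through two single-monomer holes on adjacent
  protofilaments.
- ``fig5_gmpcpp_hole``: a single-seam 13_3 tube where one one-monomer hole
  turns 1 seam into 3.
- ``fig8_seam_offset``: a single-seam 13_3 tube whose seam steps laterally
  by one protofilament across a one-monomer hole.
- ``fig9_variants``: short 12_2 (two seams), 12_3 (one), 13_4 (none) and
  14_3 (one) tubes.
- ``fig6_interface``: a single-seam 13_3 tube with one-sided decoration
  attenuation mimicking the air-water interface.
- ``condition_sim``: twenty microtubules with Poisson-planted odd holes at
  a known rate, for condition-level statistics.

Expected-call files are derived from the ground-truth lattice, never from
the analysis pipeline under test.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .lattice import MTLattice, build_lattice, insert_hole, make_spec
from .mrc import write_mrc
from .pipeline import calls_from_lattice
from .tomo import RenderParams, VolumeGrid, add_noise, apply_wedge, render, surface_damage

__all__ = ["SCENARIOS", "make_fixture", "build_scenario_lattice",
           "planted_rate_lattices"]

SCENARIOS = ("fig3_5to3seams", "fig5_gmpcpp_hole", "fig8_seam_offset",
             "fig9_variants", "fig6_interface", "condition_sim")

#: default axial extent (nm) of single-tube scenarios; four ~160 nm segments
FIXTURE_LENGTH = 640.0


def build_scenario_lattice(name: str, length: float = FIXTURE_LENGTH):
    """Ground-truth lattice (or list of lattices) for a scenario."""
    if name == "fig3_5to3seams":
        lat = build_lattice(make_spec(13, 3), {0, 1, 2, 3, 4}, length)
        z = 0.5 * length  # mid-length: segments 1-2 keep 5 seams, 3-4 get 3
        lat = insert_hole(lat, pf=2, z=z, k=1)  # toggles contacts 1 and 2
        lat = insert_hole(lat, pf=3, z=z, k=1)  # toggles contacts 2 and 3
        return lat  # seams above: {0, 2, 4}
    if name == "fig5_gmpcpp_hole":
        lat = build_lattice(make_spec(13, 3), {0}, length)
        return insert_hole(lat, pf=6, z=0.5 * length, k=1)  # 1 -> 3 seams
    if name == "fig8_seam_offset":
        lat = build_lattice(make_spec(13, 3), {5}, length)
        # a flip on pf 5 toggles contacts 4 and 5: the seam steps 5 -> 4
        return insert_hole(lat, pf=5, z=0.5 * length, k=1)
    if name == "fig9_variants":
        return {
            "12_2": build_lattice(make_spec(12, 2), {3, 4}, length / 2),
            "12_3": build_lattice(make_spec(12, 3), {0}, length / 2),
            "13_4": build_lattice(make_spec(13, 4), set(), length / 2),
            "14_3": build_lattice(make_spec(14, 3), {0}, length / 2),
        }
    if name == "fig6_interface":
        return build_lattice(make_spec(13, 3), {0}, length / 2)
    raise KeyError(f"unknown scenario {name!r}; valid: {', '.join(SCENARIOS)}")


def planted_rate_lattices(n_mt: int = 20, length: float = 1600.0,
                          rate_per_um: float = 0.25, seed: int = 0) -> list[MTLattice]:
    """Microtubules with odd single-monomer holes planted at a Poisson rate.

    Every hole flips the registry of its protofilament, so the true
    lattice-type transition count per tube equals its number of distinct
    hole heights; the condition-level recovered frequency estimates
    ``rate_per_um``.
    """
    rng = np.random.default_rng(seed)
    spec = make_spec(13, 3)
    out = []
    for _ in range(n_mt):
        lat = build_lattice(spec, {0}, length)
        n_holes = rng.poisson(rate_per_um * length / 1000.0)
        placed = 0
        attempts = 0
        while placed < n_holes and attempts < 50 * (n_holes + 1):
            attempts += 1
            pf = int(rng.integers(spec.N))
            z = float(rng.uniform(spec.monomer_rise, length - spec.monomer_rise))
            try:
                lat = insert_hole(lat, pf, z, 1)
                placed += 1
            except ValueError:
                continue
        out.append(lat)
    return out


def _render_noisy(lat, seed: int, params: RenderParams,
                  tilt_range: float = 60.0, snr: float | None = 3.0,
                  mode: str = "single") -> tuple[VolumeGrid, object]:
    vol, gt = render(lat, params)
    vol = apply_wedge(vol, tilt_range=tilt_range, mode=mode)
    vol = add_noise(vol, snr, seed=seed)
    return vol, gt


def make_fixture(name: str, seed: int = 0, out_dir=None,
                 params: RenderParams = RenderParams(),
                 snr: float | None = 3.0) -> dict:
    """Build a deterministic scenario bundle, optionally writing it to disk.

    The returned dict holds the lattice(s), rendered volume(s), ground
    truth, and expected per-segment seam sets (derived from the lattice).
    With ``out_dir`` the bundle is written as lattice JSON, MRC volume,
    ground-truth JSON and expected-calls JSON.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; valid: {', '.join(SCENARIOS)}")

    bundle: dict = {"name": name, "seed": seed}
    if name == "condition_sim":
        rate = 0.25
        lats = planted_rate_lattices(seed=seed, rate_per_um=rate)
        bundle["lattices"] = lats
        bundle["rate_per_um"] = rate
        bundle["expected_calls"] = [
            [c.to_dict() for c in calls_from_lattice(lat, 160.0)] for lat in lats
        ]
    elif name == "fig9_variants":
        lats = build_scenario_lattice(name)
        bundle["lattices"] = lats
        bundle["volumes"] = {}
        bundle["ground_truths"] = {}
        for key, lat in lats.items():
            vol, gt = _render_noisy(lat, seed, params, snr=snr)
            bundle["volumes"][key] = vol
            bundle["ground_truths"][key] = gt
        bundle["expected_calls"] = {
            key: [c.to_dict() for c in calls_from_lattice(lat, lat.length)]
            for key, lat in lats.items()
        }
    else:
        lat = build_scenario_lattice(name)
        vol, gt = _render_noisy(lat, seed, params, snr=snr)
        if name == "fig6_interface":
            vol = surface_damage(vol, side="-", attenuation=0.3, depth=6.0)
        bundle["lattice"] = lat
        bundle["volume"] = vol
        bundle["ground_truth"] = gt
        n_seg = 4 if lat.length >= 600 else 2
        bundle["expected_calls"] = [c.to_dict()
                                    for c in calls_from_lattice(lat, lat.length / n_seg)]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "lattice" in bundle:
            bundle["lattice"].to_json(out / "lattice.json")
            write_mrc(out / "volume.mrc", bundle["volume"])
        if "lattices" in bundle and isinstance(bundle["lattices"], dict):
            for key, lat in bundle["lattices"].items():
                lat.to_json(out / f"lattice_{key}.json")
                write_mrc(out / f"volume_{key}.mrc", bundle["volumes"][key])
        if "lattices" in bundle and isinstance(bundle["lattices"], list):
            for i, lat in enumerate(bundle["lattices"]):
                lat.to_json(out / f"lattice_mt{i:02d}.json")
        with open(out / "expected_calls.json", "w") as fh:
            json.dump({"name": name, "seed": seed,
                       "expected_calls": bundle["expected_calls"]}, fh, indent=1)
    return bundle
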