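"""Lattice geometry: closure, seams, holes, transitions, coordinates."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seamsta.lattice import (
    LatticeError,
    MTLattice,
    build_lattice,
    classify_phase_offsets,
    complete_seams,
    dimer_stats,
    export_point_model,
    find_transitions,
    insert_hole,
    lattice_coordinates,
    make_spec,
    min_seams,
)

from conftest import random_valid_lattice


class TestSpec:
    def test_stagger_and_radius_13_3(self):
        s = make_spec(13, 3, 4.0, 5.0)
        assert s.rho == pytest.approx(12.0 / 13.0)
        assert s.N * s.rho == pytest.approx(s.S * s.monomer_rise)
        assert s.wall_radius == pytest.approx(13 * 5.0 / (2 * np.pi))
        assert s.wall_radius == pytest.approx(10.345, abs=1e-3)

    def test_stagger_13_4(self):
        assert make_spec(13, 4, 4.0, 5.0).rho == pytest.approx(16.0 / 13.0)

    @pytest.mark.parametrize("n,s,msg", [
        (13, 9, "S out of range"), (13, 1, "S out of range"),
        (7, 3, "N out of range"), (18, 3, "N out of range"),
    ])
    def test_out_of_range_rejected(self, n, s, msg):
        with pytest.raises(LatticeError, match=msg):
            make_spec(n, s)

    def test_dimer_rise_is_twice_monomer(self):
        assert make_spec(12, 3, monomer_rise=4.05).dimer_rise == pytest.approx(8.1)


class TestSeamCombinatorics:
    @pytest.mark.parametrize("n,s,expected", [(13, 3, 1), (13, 4, 0), (12, 2, 0),
                                              (14, 3, 1), (15, 4, 0)])
    def test_min_seams_parity(self, n, s, expected):
        assert min_seams(make_spec(n, s)) == expected

    def test_complete_seams_12_2_adds_adjacent(self):
        assert complete_seams(make_spec(12, 2), {3}) == {3, 4}

    def test_complete_seams_noop_when_parity_matches(self):
        assert complete_seams(make_spec(13, 3), {0}) == {0}
        assert complete_seams(make_spec(13, 4), set()) == set()

    @given(st.integers(8, 17), st.sampled_from([2, 3, 4]), st.data())
    @settings(max_examples=60, deadline=None)
    def test_complete_seams_always_restores_parity(self, n, s, data):
        forced = data.draw(st.sets(st.integers(0, n - 1), max_size=n - 1))
        out = complete_seams(make_spec(n, s), forced)
        assert forced <= out
        assert len(out) % 2 == s % 2
        assert len(out) - len(forced) <= 1


class TestBuildLattice:
    def test_single_seam_contact_map(self, spec13_3):
        lat = build_lattice(spec13_3, {0}, 160.0)
        types = lat.contact_types_at(0.0)
        assert np.sum(types == "A") == 1 and np.sum(types == "B") == 12
        assert lat.seam_set_at(80.0) == frozenset({0})

    def test_parity_violation_rejected(self, spec13_3):
        with pytest.raises(LatticeError, match="closure"):
            build_lattice(spec13_3, {0, 5}, 160.0)

    def test_five_seams(self, spec13_3):
        lat = build_lattice(spec13_3, {0, 1, 2, 3, 4}, 160.0)
        assert np.sum(lat.contact_types_at(10.0) == "A") == 5

    @given(st.integers(8, 17), st.sampled_from([2, 3, 4]), st.data())
    @settings(max_examples=80, deadline=None)
    def test_closure_parity_fuzz(self, n, s, data):
        """Accepted iff |seams| == S (mod 2); n_A has S's parity at all z."""
        seams = data.draw(st.sets(st.integers(0, n - 1), max_size=n))
        spec = make_spec(n, s)
        if len(seams) % 2 != s % 2:
            with pytest.raises(LatticeError):
                build_lattice(spec, seams, 100.0)
        else:
            lat = build_lattice(spec, seams, 100.0)
            assert lat.seam_set_at(0.0) == frozenset(seams)
            for z in np.linspace(0, 99, 7):
                assert len(lat.seam_set_at(z)) % 2 == s % 2


class TestHoles:
    def test_odd_hole_toggles_flanking_contacts(self, single_seam_lattice):
        lat = insert_hole(single_seam_lattice, 6, 80.0, 1)
        assert lat.seam_set_at(10.0) == frozenset({0})
        assert lat.seam_set_at(120.0) == frozenset({0, 5, 6})

    def test_even_hole_leaves_contacts(self, single_seam_lattice):
        lat = insert_hole(single_seam_lattice, 6, 80.0, 2)
        assert lat.seam_set_at(120.0) == lat.seam_set_at(10.0)
        occ = lat.occupancy()
        assert occ.sum() == 13 * lat.n_sites() - 2

    @pytest.mark.parametrize("k", range(1, 7))
    def test_hole_parity_law_exhaustive(self, k):
        """Odd k flips the seam set above the hole; even k never does."""
        rng = np.random.default_rng(k)
        for _ in range(10):
            lat = random_valid_lattice(rng)
            pf = int(rng.integers(lat.spec.N))
            lat2 = insert_hole(lat, pf, 100.0, k)
            changed = lat2.seam_set_at(150.0) != lat2.seam_set_at(50.0)
            assert changed == (k % 2 == 1)
            assert len(lat2.seam_set_at(150.0)) % 2 == lat.spec.S % 2

    def test_overlap_rejected(self, single_seam_lattice):
        lat = insert_hole(single_seam_lattice, 3, 80.0, 2)
        with pytest.raises(LatticeError, match="overlap"):
            insert_hole(lat, 3, 82.0, 1)

    def test_out_of_range_z_rejected(self, single_seam_lattice):
        with pytest.raises(LatticeError):
            insert_hole(single_seam_lattice, 3, 500.0, 1)


class TestTransitions:
    def test_single_odd_hole_one_transition(self, single_seam_lattice):
        lat = insert_hole(single_seam_lattice, 6, 80.0, 1)
        trans, freq = find_transitions(lat)
        assert len(trans) == 1
        assert trans[0].z == pytest.approx(80.0, abs=lat.spec.monomer_rise)
        assert freq == pytest.approx(1 / 0.176)

    def test_no_holes_no_transitions(self, single_seam_lattice):
        assert find_transitions(single_seam_lattice) == ([], 0.0)

    def test_matches_bruteforce_scan_on_random_lattices(self):
        """find_transitions equals an independent per-monomer seam-set scan."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            lat = random_valid_lattice(rng, length=400.0)
            for _ in range(int(rng.integers(0, 10))):
                try:
                    lat = insert_hole(lat, int(rng.integers(lat.spec.N)),
                                      float(rng.uniform(4, 396)),
                                      int(rng.integers(1, 4)))
                except LatticeError:
                    pass
            trans, _ = find_transitions(lat)
            zg = np.arange(0.0, lat.length, lat.spec.monomer_rise)
            sets = [lat.seam_set_at(z) for z in zg]
            brute = sum(a != b for a, b in zip(sets, sets[1:]))
            assert len(trans) == brute


class TestDimerStats:
    def test_thirteen_pf_dimer_content(self, spec13_3):
        assert dimer_stats(spec13_3, 1.0)["dimer_count"] == pytest.approx(1625.0)

    def test_dimers_per_transition(self, spec13_3):
        out = dimer_stats(spec13_3, 1.0, transition_freq=0.1)
        assert out["dimers_per_transition"] == pytest.approx(16250.0)

    def test_zero_length_and_zero_freq(self, spec13_3):
        assert dimer_stats(spec13_3, 0.0)["dimer_count"] == 0.0
        out = dimer_stats(spec13_3, 1.0, transition_freq=0.0)
        assert out["undefined"] and np.isinf(out["dimers_per_transition"])

    def test_linear_in_length_and_N(self):
        a = dimer_stats(make_spec(13, 3), 2.0)["dimer_count"]
        b = dimer_stats(make_spec(13, 3), 4.0)["dimer_count"]
        c = dimer_stats(make_spec(14, 3), 2.0)["dimer_count"]
        assert b == pytest.approx(2 * a)
        assert c / a == pytest.approx(14 / 13)

    def test_negative_rejected(self, spec13_3):
        with pytest.raises(LatticeError):
            dimer_stats(spec13_3, -1.0)


class TestCoordinates:
    def test_site_and_decoration_counts(self, spec13_3):
        lat = build_lattice(spec13_3, {0}, 160.0)
        df = lattice_coordinates(lat)
        assert (~df.decorated).sum() == 13 * 40
        assert df.decorated.sum() == 13 * 20

    def test_decoration_axial_spacing_is_dimer_repeat(self, single_seam_lattice):
        df = lattice_coordinates(single_seam_lattice)
        z = np.sort(df[(df.pf == 5) & df.decorated].z.values)
        assert np.allclose(np.diff(z), 8.0)

    def test_no_decoration_on_missing_monomers(self, single_seam_lattice):
        lat = insert_hole(single_seam_lattice, 2, 80.0, 2)
        df0 = lattice_coordinates(single_seam_lattice)
        df1 = lattice_coordinates(lat)
        assert len(df1) == len(df0) - 3  # 2 monomers gone, one was decorated

    def test_roundtrip_seam_set_from_coordinates(self):
        """Phases re-measured from decoration coordinates reproduce seams."""
        rng = np.random.default_rng(3)
        for _ in range(8):
            lat = random_valid_lattice(rng, length=160.0)
            spec = lat.spec
            df = lattice_coordinates(lat)
            dec = df[df.decorated]
            psi = np.zeros(spec.N)
            for pf in range(spec.N):
                psi[pf] = np.sort(dec[dec.pf == pf].z.values)[0] % spec.dimer_rise
            steps = (np.roll(psi, -1) - psi)
            types = classify_phase_offsets(steps, spec)
            seams = frozenset(np.nonzero(types == "A")[0].tolist())
            assert seams == lat.seam_set_at(1.0)


class TestSerialization:
    def test_json_roundtrip_with_holes(self, single_seam_lattice):
        lat = insert_hole(single_seam_lattice, 4, 72.0, 3)
        doc = json.loads(lat.to_json())
        back = MTLattice.from_dict(doc)
        assert back.seam_set_at(10.0) == lat.seam_set_at(10.0)
        assert back.seam_set_at(150.0) == lat.seam_set_at(150.0)
        assert np.array_equal(back.occupancy(), lat.occupancy())

    def test_point_model_export(self, tmp_path, single_seam_lattice):
        df = lattice_coordinates(single_seam_lattice)
        path = tmp_path / "model.txt"
        export_point_model(df, path, voxel_size=0.8)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == len(df)
        obj, contour, x, y, z = lines[0].split()
        assert obj == "1" and contour == "1"
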