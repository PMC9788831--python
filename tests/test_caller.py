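"""Lattice inference: unwrapping, N_S, phases, contacts, layer lines."""

import numpy as np
import pytest

from seamsta.caller import (
    COHERENCE_THRESHOLD,
    CallerError,
    CylinderMap,
    call_segment,
    classify_contacts,
    infer_NS,
    layerline_filter,
    pf_phase,
    phase_offset_test,
    unwrap,
)
from seamsta.lattice import build_lattice, make_spec
from seamsta.pipeline import remap_contact_types
from seamsta.tomo import RenderParams, VolumeGrid, add_noise, apply_wedge, render

from conftest import random_valid_lattice


def _flat_map(values, dz=0.8):
    n_theta, nz = values.shape
    theta = -np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    return CylinderMap(values=values, theta=theta, z=np.arange(nz) * dz, radius=10.0)


class TestUnwrap:
    def test_uniform_volume_gives_constant_map(self):
        vol = VolumeGrid(np.full((40, 40, 30), 1.7, dtype=np.float32), 0.8)
        cm = unwrap(vol, 8.0)
        assert np.allclose(cm.values, 1.7, atol=1e-5)

    def test_thirteen_ridges_on_decorated_render(self, clean_render):
        vol, gt = clean_render
        cm = unwrap(vol, gt.decoration_radius)
        from seamsta.caller import detect_pf_rows

        rows = detect_pf_rows(cm)
        assert rows is not None and len(rows) == 13

    def test_map_mean_matches_shell_mean(self, clean_render):
        """Interpolated cylinder mean equals a direct shell average."""
        vol, gt = clean_render
        r = gt.decoration_radius
        cm = unwrap(vol, r, n_theta=512)
        vx = vol.voxel_size
        cx, cy = gt.center_xy
        xx = np.arange(vol.data.shape[0]) * vx - cx
        yy = np.arange(vol.data.shape[1]) * vx - cy
        rr = np.sqrt(xx[:, None] ** 2 + yy[None, :] ** 2)
        shell = (np.abs(rr - r) < vx / 2)
        shell_mean = vol.data[shell, :].mean()
        assert cm.values.mean() == pytest.approx(shell_mean, rel=0.05)

    def test_radius_outside_grid_rejected(self, clean_render):
        vol, _ = clean_render
        with pytest.raises(CallerError):
            unwrap(vol, 100.0)


class TestPfPhase:
    def test_pure_cosine_phase_and_coherence(self):
        z = np.arange(0, 160, 0.8)
        vals = np.tile(np.cos(2 * np.pi * (z - 2.0) / 8.0), (8, 1))
        psi, coh = pf_phase(_flat_map(vals), 0, window=0)
        assert psi == pytest.approx(2.0, abs=0.05)
        assert coh == pytest.approx(1.0, abs=0.01)

    def test_flat_profile_zero_coherence(self):
        psi, coh = pf_phase(_flat_map(np.ones((8, 100))), 0)
        assert coh == 0.0

    def test_destructive_phase_split_drops_coherence(self):
        """Half the profile in register, half offset by one monomer: the
        dimer components cancel."""
        z = np.arange(0, 160, 0.8)
        half = np.where(z < 80, np.cos(2 * np.pi * z / 8),
                        np.cos(2 * np.pi * (z - 4.0) / 8))
        psi, coh = pf_phase(_flat_map(np.tile(half, (8, 1))), 0, window=0)
        assert coh < 0.3


class TestInferNS:
    @pytest.mark.parametrize("n,s,seams", [(13, 3, {0}), (14, 3, {0}),
                                           (13, 4, set()), (12, 2, {3, 4})])
    def test_rendered_classes_recovered(self, n, s, seams):
        lat = build_lattice(make_spec(n, s), seams, 176.0)
        vol, gt = render(lat)
        cm = unwrap(vol, gt.decoration_radius)
        assert infer_NS(cm) == (n, s)

    def test_featureless_map_undetermined(self):
        assert infer_NS(_flat_map(np.zeros((64, 100)))) == (None, None)


class TestClassifyContacts:
    def test_single_seam_lattice_phases(self, spec13_3):
        lat = build_lattice(spec13_3, {0}, 160.0)
        phases = np.array([lat.pf_phase(i, 80.0) for i in range(13)])
        call = classify_contacts(phases, np.ones(13), spec13_3)
        assert np.sum(call.contact_types == "A") == 1
        assert np.sum(call.contact_types == "B") == 12
        assert call.seam_set == frozenset({0})

    def test_five_seam_lattice_phases(self, spec13_3):
        lat = build_lattice(spec13_3, {0, 1, 2, 3, 4}, 160.0)
        phases = np.array([lat.pf_phase(i, 10.0) for i in range(13)])
        call = classify_contacts(phases, np.ones(13), spec13_3)
        assert np.sum(call.contact_types == "A") == 5

    def test_low_coherence_pf_yields_two_nd_contacts(self, spec13_3):
        lat = build_lattice(spec13_3, {0}, 160.0)
        phases = np.array([lat.pf_phase(i, 80.0) for i in range(13)])
        coher = np.ones(13)
        coher[4] = 0.0
        call = classify_contacts(phases, coher, spec13_3)
        assert call.contact_types[3] == "N" and call.contact_types[4] == "N"
        assert np.sum(call.contact_types == "N") == 2
        assert not call.determined

    def test_count_mismatch_rejected(self, spec13_3):
        with pytest.raises(CallerError):
            classify_contacts(np.zeros(11), np.ones(11), spec13_3)

    def test_exact_phase_classification_matches_contact_map(self):
        """Classification from exact lattice phases reproduces the contact
        map for random lattices of every valid class (oracle equivalence)."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            lat = random_valid_lattice(rng, length=160.0)
            phases = np.array([lat.pf_phase(i, 80.0) for i in range(lat.spec.N)])
            call = classify_contacts(phases, np.ones(lat.spec.N), lat.spec)
            assert np.array_equal(call.contact_types, lat.contact_types_at(80.0))

    def test_sphere_model_colors(self, spec13_3):
        lat = build_lattice(spec13_3, {0}, 160.0)
        phases = np.array([lat.pf_phase(i, 80.0) for i in range(13)])
        coher = np.ones(13)
        coher[7] = 0.1
        call = classify_contacts(phases, coher, spec13_3, z_range=(0.0, 64.0))
        model = call.sphere_model()
        assert set(model[model.pf == 7].color) == {"red"}
        assert set(model[model.pf == 2].color) == {"yellow", "cyan"}


class TestLayerlineFilter:
    def test_in_band_signal_passes(self):
        z = np.arange(120) * 0.8  # 96 nm: integer number of 8-nm repeats
        img = np.tile(np.cos(2 * np.pi * z / 8), (16, 1))
        out = layerline_filter(img, 0.8)
        assert np.allclose(out, img, atol=1e-8)

    def test_out_of_band_component_removed(self):
        z = np.arange(0, 104, 0.8)
        keep = np.cos(2 * np.pi * z / 8)
        kill = 0.7 * np.cos(2 * np.pi * z / 13)
        img = np.tile(keep + kill, (8, 1))
        out = layerline_filter(img, 0.8)
        k13 = round(len(z) * 0.8 / 13)
        spec_in = np.abs(np.fft.fft(img[0] - img[0].mean()))
        spec_out = np.abs(np.fft.fft(out[0] - out[0].mean()))
        assert spec_in[k13] / max(spec_out[k13], 1e-12) > 10

    def test_zero_image_stays_zero(self):
        assert not layerline_filter(np.zeros((8, 64)), 0.8).any()

    def test_short_region_rejected(self):
        with pytest.raises(CallerError):
            layerline_filter(np.zeros((8, 16)), 0.8)


class TestPhaseOffset:
    def test_identical_profiles_in_phase(self):
        z = np.arange(0, 160, 0.8)
        a = np.cos(2 * np.pi * z / 8)
        assert phase_offset_test(a, a, 0.8) == ("in_phase", "even")

    def test_monomer_shift_is_odd(self):
        z = np.arange(0, 160, 0.8)
        a = np.cos(2 * np.pi * z / 8)
        b = np.cos(2 * np.pi * (z - 4.0) / 8)
        assert phase_offset_test(a, b, 0.8) == ("out_of_phase", "odd")

    def test_full_repeat_shift_is_even(self):
        z = np.arange(0, 160, 0.8)
        a = np.cos(2 * np.pi * z / 8)
        b = np.cos(2 * np.pi * (z - 8.0) / 8)
        assert phase_offset_test(a, b, 0.8) == ("in_phase", "even")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(CallerError):
            phase_offset_test(np.zeros(10), np.zeros(11), 0.8)


class TestEndToEndRecovery:
    """Rendered lattice -> wedge -> noise -> call, per N_S class."""

    CLASSES = [("12_2", {3, 4}), ("12_3", {0}), ("13_3", {0}), ("13_4", set()),
               ("14_3", {0}), ("15_3", {0}), ("15_4", set())]

    @pytest.mark.parametrize("name,seams", CLASSES)
    def test_class_recovery_no_confusion(self, name, seams):
        n, s = (int(x) for x in name.split("_"))
        lat = build_lattice(make_spec(n, s), seams, 176.0)
        vol, gt = render(lat)
        v = add_noise(apply_wedge(vol, 60.0, "single"), 3.0,
                      seed=sum(map(ord, name)))
        call = call_segment(v)
        assert (call.N, call.S) == (n, s)
        mapped = remap_contact_types(call)
        true = lat.contact_types_at(88.0)
        confused = np.sum((mapped != true) & (mapped != "N"))
        assert confused == 0
        assert np.sum(mapped == true) / n >= 0.95
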