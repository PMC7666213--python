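"""Barrel geometry: designed dimensions, pixel lattices, stacks."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings, strategies as st

from barrelpaint.geometry import (
    BarrelConfigError,
    BarrelSpec,
    LayerSpec,
    StackSpec,
    assembly_mass,
    cavity_diameter,
    docking_ring,
    export_lattice_csv,
    external_diameter,
    get_preset,
    list_presets,
    load_spec_yaml,
    make_stack,
    molar_concentration_from_a260,
    pixel_lattice,
    sites_to_array,
    stack_positions,
)


def barrel(outer=84.0, middle=81.5, inner=76.5, thickness=2.6, height=23.0, **kw):
    return BarrelSpec(
        name=kw.pop("name", "90-23"),
        layers=(
            LayerSpec("outer", outer),
            LayerSpec("inner_middle", middle),
            LayerSpec("inner", inner),
        ),
        monomer_height=height,
        helix_thickness=thickness,
        **kw,
    )


class TestDesignedDiameters:
    @pytest.mark.parametrize(
        "outer, thickness, rounded, exact",
        [
            (84.0, 2.6, 87.0, 86.6),     # 90-nm class design values
            (84.0, 0.0, 84.0, 84.0),     # zero thickness identity
            (28.4, 2.6, 31.0, 31.0),     # 30-nm class
        ],
    )
    def test_external_diameter(self, outer, thickness, rounded, exact):
        spec = barrel(outer=outer, middle=outer - 2.5, inner=outer - 7.5,
                      thickness=thickness)
        assert external_diameter(spec) == rounded
        assert external_diameter(spec, rounded=False) == pytest.approx(exact)

    @pytest.mark.parametrize(
        "inner, thickness, rounded, exact",
        [
            (76.5, 2.6, 74.0, 73.9),
            (76.0, 0.0, 76.0, 76.0),  # zero thickness leaves the midpoint unchanged
            (25.0, 2.6, 22.0, 22.4),
        ],
    )
    def test_cavity_diameter(self, inner, thickness, rounded, exact):
        spec = barrel(outer=inner + 7.5, middle=inner + 5.0, inner=inner,
                      thickness=thickness)
        assert cavity_diameter(spec) == rounded
        assert cavity_diameter(spec, rounded=False) == pytest.approx(exact)

    def test_missing_layer_is_config_error(self):
        spec = BarrelSpec(
            name="x", layers=(LayerSpec("outer", 84.0),), monomer_height=23.0
        )
        assert external_diameter(spec) == 87.0
        with pytest.raises(BarrelConfigError):
            cavity_diameter(spec)

    def test_layer_ordering_enforced(self):
        with pytest.raises(BarrelConfigError):
            barrel(outer=76.5, middle=81.5, inner=84.0)

    @given(
        outer=st.floats(20.0, 120.0),
        gap1=st.floats(1.0, 5.0),
        gap2=st.floats(1.0, 8.0),
        thickness=st.floats(0.1, 4.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_external_minus_cavity_identity(self, outer, gap1, gap2, thickness):
        """external - cavity = (outer - inner midpoint) + 2 * thickness, exactly."""
        inner = outer - gap1 - gap2
        spec = barrel(outer=outer, middle=outer - gap1, inner=inner, thickness=thickness)
        lhs = external_diameter(spec, rounded=False) - cavity_diameter(spec, rounded=False)
        assert lhs == pytest.approx((outer - inner) + 2 * thickness, rel=1e-12)

    def test_preset_identity_holds_for_catalog(self):
        for name in list_presets():
            spec = get_preset(name)
            d = {l.role: l.midpoint_diameter for l in spec.layers}
            lhs = external_diameter(spec, rounded=False) - cavity_diameter(spec, rounded=False)
            assert lhs == pytest.approx(d["outer"] - d["inner"] + 2 * spec.helix_thickness)
            assert abs(spec.pixel_pitch - 8.0) <= 0.2 * 8.0


class TestPixelLattice:
    def test_outer_sites_share_radius_inner_strictly_smaller(self):
        spec = get_preset("90-23")
        outer = sites_to_array(pixel_lattice(spec, "outer"))
        inner = sites_to_array(pixel_lattice(spec, "inner"))
        r_out = np.hypot(outer[:, 0], outer[:, 1])
        r_in = np.hypot(inner[:, 0], inner[:, 1])
        assert np.allclose(r_out, r_out[0], rtol=1e-9)
        assert np.allclose(r_in, r_in[0], rtol=1e-9)
        assert r_in[0] < r_out[0]

    def test_uniform_azimuthal_spacing(self):
        spec = get_preset("90-23")
        sites = [s for s in pixel_lattice(spec, "outer") if s.row_index == 0]
        pos = sites_to_array(sites)
        angles = np.sort(np.arctan2(pos[:, 1], pos[:, 0]))
        steps = np.diff(angles)
        assert np.allclose(steps, 2 * np.pi / len(sites), atol=1e-9)

    def test_interior_sites_have_six_neighbors_at_pitch(self):
        """Brute-force all-pairs neighbour count on a small lattice."""
        spec = get_preset("90-23")
        sites = pixel_lattice(spec, "outer", rows=4)
        pos = sites_to_array(sites)
        dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        pitch = spec.pixel_pitch
        interior = [i for i, s in enumerate(sites) if s.row_index in (1, 2)]
        for i in interior:
            near = np.sum((dist[i] > 0) & (dist[i] < 1.2 * pitch))
            assert near == 6
            d6 = np.sort(dist[i][dist[i] > 0])[:6]
            assert np.all(np.abs(d6 - pitch) <= 0.2 * pitch)

    def test_nearest_neighbour_distances_cluster_near_8nm(self):
        spec = get_preset("90-23")
        pos = sites_to_array(pixel_lattice(spec, "outer", rows=3))
        dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(dist, np.inf)
        nn = dist.min(axis=1)
        assert abs(np.median(nn) - 8.0) < 1.6

    def test_degenerate_parameters_rejected(self):
        spec = get_preset("90-23")
        with pytest.raises(BarrelConfigError):
            pixel_lattice(spec, rows=0)
        with pytest.raises(BarrelConfigError):
            pixel_lattice(spec, sites_per_row=2)
        with pytest.raises(BarrelConfigError):
            pixel_lattice(spec, surface="sideways")

    def test_docking_ring_on_external_radius(self):
        spec = get_preset("30-27")
        ring = docking_ring(spec)
        pos = sites_to_array(ring)
        assert len(ring) == 6
        assert np.allclose(np.hypot(pos[:, 0], pos[:, 1]), 31.0 / 2.0, atol=0.01)

    def test_export_csv(self, tmp_path):
        spec = get_preset("30-27")
        path = tmp_path / "lattice.csv"
        export_lattice_csv(spec, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "surface,row,azimuth,x,y,z,docking_id"
        assert len(lines) > 10


class TestStacks:
    @pytest.mark.parametrize(
        "preset, monomer_height, repeat",
        [("60-30", 29.0, 58.0), ("90-23", 21.0, 42.0)],
    )
    def test_alpha_beta_repeat(self, preset, monomer_height, repeat):
        spec = get_preset(preset)
        assert spec.polymer_monomer_height == monomer_height
        stack = make_stack(spec, 6, decorated="alpha")
        pos = stack_positions(stack)
        offsets = [p.axial_offset for p in pos]
        assert np.allclose(np.diff(offsets), monomer_height)
        alpha_offsets = [p.axial_offset for p in pos if p.monomer_index % 2 == 0]
        assert np.allclose(np.diff(alpha_offsets), repeat)

    def test_single_monomer_stack_height(self):
        spec = get_preset("30-27")
        stack = make_stack(spec, 1, monomer_height=spec.monomer_height)
        assert stack.height == spec.monomer_height
        assert stack_positions(stack)[0].axial_offset == 0.0

    def test_offsets_strictly_increasing_evenly_spaced(self):
        stack = make_stack(get_preset("90-23"), 10)
        offsets = np.array([p.axial_offset for p in stack_positions(stack)])
        assert np.all(np.diff(offsets) > 0)
        assert np.allclose(np.diff(offsets), offsets[1] - offsets[0])

    def test_decamer_has_nine_interfaces(self):
        stack = make_stack(get_preset("90-23"), 10)
        assert len(stack.interfaces) == 9

    def test_interface_count_invariant(self):
        spec = get_preset("90-23")
        with pytest.raises(BarrelConfigError):
            StackSpec(monomers=((spec, "alpha"), (spec, "beta")), interfaces=())

    def test_mixed_diameter_classes_rejected(self):
        s90 = get_preset("90-23")
        s30 = get_preset("30-27")
        stack = StackSpec(
            monomers=((s90, "alpha"), (s30, "beta")), interfaces=("I1",)
        )
        with pytest.raises(BarrelConfigError):
            stack_positions(stack)


class TestMassArithmetic:
    @pytest.mark.parametrize(
        "n, mw, expected", [(10, 9.05, 90.5), (1, 9.05, 9.05), (3, 9.05, 27.15)]
    )
    def test_assembly_mass(self, n, mw, expected):
        assert assembly_mass(n, mw) == pytest.approx(expected)

    def test_assembly_mass_preconditions(self):
        with pytest.raises(ValueError):
            assembly_mass(0, 9.05)
        with pytest.raises(ValueError):
            assembly_mass(1, -1.0)

    @pytest.mark.parametrize(
        "a260, mw, expected",
        [(0.0, 9.05e6, 0.0), (1.0, 9.05e6, 5.52), (1.0, 90.5e6, 0.552)],
    )
    def test_molar_concentration(self, a260, mw, expected):
        assert molar_concentration_from_a260(a260, mw) == pytest.approx(expected, abs=0.01)

    def test_molar_concentration_bad_mw(self):
        with pytest.raises(ValueError):
            molar_concentration_from_a260(1.0, 0.0)


class TestPresetsAndYaml:
    def test_catalog_contains_printed_classes(self):
        assert {"30-27", "30-65", "60-30", "90-19", "90-23"} <= set(list_presets())

    def test_unknown_preset(self):
        with pytest.raises(BarrelConfigError):
            get_preset("120-10")

    def test_custom_yaml_roundtrip(self, tmp_path):
        doc = {
            "45-20": {
                "layers": [
                    {"role": "outer", "midpoint_diameter": 42.4},
                    {"role": "inner_middle", "midpoint_diameter": 39.9},
                    {"role": "inner", "midpoint_diameter": 34.9},
                ],
                "monomer_height": 20.0,
            }
        }
        path = tmp_path / "custom.yaml"
        path.write_text(yaml.safe_dump(doc))
        spec = load_spec_yaml(path)
        assert spec.name == "45-20"
        assert external_diameter(spec) == 45.0
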