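# Barrel preset catalog.
#
# Layer mid-point diameters for the 90 nm class are the designed values
# (outer 84, inner-middle 81.5, inner 76.5 nm).  For the 30 and 60 nm
# classes only the external diameters (31, 60 nm) are part of the design
# record, so layer mid-points are back-computed as external minus one
# helix thickness (2.6 nm) for the outer layer, with the same inter-layer
# gaps as the 90 nm class (outer to inner-middle 2.5 nm, inner-middle to
# inner 5 nm); meta.back_computed marks these entries.
#
# monomer_height is the designed monomer height from the name;
# polymer_monomer_height is the per-monomer axial repeat when the class
# is polymerised coaxially (alpha-beta repeat = 2x this value).  The two
# are stored separately because neither is derivable from the other.
presets:
  "90-23":
    layers:
      - {role: outer, midpoint_diameter: 84.0, n_helix_rings: 4}
      - {role: inner_middle, midpoint_diameter: 81.5, n_helix_rings: 4}
      - {role: inner, midpoint_diameter: 76.5, n_helix_rings: 5}
    monomer_height: 23.0
    polymer_monomer_height: 21.0
    n_docking_handles: 18
    meta: {scaffold: p8634, monomer_mw_mda: 9.05, back_computed: false}
  "90-19":
    layers:
      - {role: outer, midpoint_diameter: 84.0, n_helix_rings: 4}
      - {role: inner_middle, midpoint_diameter: 81.5, n_helix_rings: 4}
      - {role: inner, midpoint_diameter: 76.5, n_helix_rings: 5}
    monomer_height: 19.0
    polymer_monomer_height: 21.0
    n_docking_handles: 18
    meta: {scaffold: p7308, back_computed: false}
  "60-30":
    layers:
      - {role: outer, midpoint_diameter: 57.4, n_helix_rings: 6}
      - {role: inner_middle, midpoint_diameter: 54.9, n_helix_rings: 6}
      - {role: inner, midpoint_diameter: 49.9, n_helix_rings: 7}
    monomer_height: 30.0
    polymer_monomer_height: 29.0
    n_docking_handles: 12
    meta: {scaffold: p7308, back_computed: true}
  "60-32":
    layers:
      - {role: outer, midpoint_diameter: 57.4, n_helix_rings: 6}
      - {role: inner_middle, midpoint_diameter: 54.9, n_helix_rings: 6}
      - {role: inner, midpoint_diameter: 49.9, n_helix_rings: 7}
    monomer_height: 32.0
    polymer_monomer_height: 29.0
    n_docking_handles: 12
    meta: {scaffold: p8064, back_computed: true}
  "30-27":
    layers:
      - {role: outer, midpoint_diameter: 28.4, n_helix_rings: 6}
      - {role: inner_middle, midpoint_diameter: 25.9, n_helix_rings: 6}
      - {role: inner, midpoint_diameter: 20.9, n_helix_rings: 7}
    monomer_height: 27.0
    polymer_monomer_height: 62.0
    n_docking_handles: 6
    meta: {scaffold: p7308, back_computed: true}
  "30-65":
    layers:
      - {role: outer, midpoint_diameter: 28.4, n_helix_rings: 14}
      - {role: inner_middle, midpoint_diameter: 25.9, n_helix_rings: 14}
      - {role: inner, midpoint_diameter: 20.9, n_helix_rings: 15}
    monomer_height: 65.0
    polymer_monomer_height: 62.0
    n_docking_handles: 6
    meta: {scaffold: p7308, back_computed: true}
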