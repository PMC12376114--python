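"""Build the icosahedral gold core used throughout the package.

Constructs the Mackay icosahedron whose mid-diameter best matches the 2.8 nm
particles seen in electron microscopy (k = 5 closed shells at the gold
lattice constant 4.08 A), keeps only the outer three atomic layers (the
inner ones never interact with the monolayer), and reports its geometry.
"""

from ligandshell import build_mackay_core, default_shell_count, trim_outer_layers

k = default_shell_count(lattice_constant=4.08, target_diameter_nm=2.8)
core = build_mackay_core(k, lattice_constant=4.08)
trimmed = trim_outer_layers(core, 3)

print(f"shell count k = {k} (closest mid-diameter to 2.8 nm)")
print(f"full cluster: {core.n_atoms} Au atoms, "
      f"{len(core.surface_atom_ids)} on the surface")
print(f"outer-3-layer model: {trimmed.n_atoms} Au atoms "
      f"(inner closed shells removed, surface unchanged)")
print(f"mid-diameter: {core.mid_diameter:.2f} nm "
      "(mean of vertex and face diameters, across atom surfaces)")
print(f"anchor sites for thiolates: {len(core.anchor_sites)} "
      "(one atop site per surface atom)")
# A 158-ligand monolayer (the largest studied composition) fits with room
# to spare; vacancies are what the Jump move hops into.
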