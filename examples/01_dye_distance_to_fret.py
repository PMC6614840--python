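"""Predict the FRET efficiency between stem-attached dyes from geometry.

Builds accessible-volume clouds for a donor and an acceptor dye around two
attachment points separated so their mean positions sit 53.6 A apart (the
modelled P1-P5 inter-dye distance of the folded lysC aptamer), then converts
that distance to an expected apparent FRET efficiency with R0 = 60 A.
"""

from fretfold import structure

# a synthetic obstacle wall below each attachment stands in for the RNA body
wall = [structure.Atom("P", "P", (float(x), float(y), -4.0), 1.8)
        for x in range(-15, 16, 3) for y in range(-15, 16, 3)]

donor = structure.DyeModel(attachment=(0.0, 0.0, 0.0), linker_length=10.0,
                           dye_radius=3.5)
acceptor = structure.DyeModel(attachment=(0.0, 0.0, 53.6), linker_length=10.0,
                              dye_radius=3.5)

av_d = structure.compute_av(donor, wall, grid_spacing=1.0)
av_a = structure.compute_av(acceptor, None, grid_spacing=1.0)
r_mp = structure.mean_dye_distance(av_d, av_a)
e = structure.forster_efficiency(r_mp, r0=60.0)

print(f"donor AV: {av_d.n_points} grid points, "
      f"mean position {av_d.mean_position.round(2)}")
print(f"mean-position dye distance R_mp = {r_mp:.1f} A")
print(f"predicted E_app = {e:.2f} (R0 = 60 A)")
print(f"reference: E(53.6 A) = {structure.forster_efficiency(53.6):.2f}")
# The predicted ~0.66 matches the high-FRET state observed for the
# ligand-bound conformation; the wall pushes the donor cloud slightly up,
# shortening R_mp a little relative to the attachment separation.
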