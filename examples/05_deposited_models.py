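"""Running the pipeline on experimentally deposited channel models.

Usage:
    python examples/05_deposited_models.py CYLINDRICAL.cif [CONICAL.cif]

Takes a coordinate file (PDB/mmCIF) of a wide oligomeric channel —
e.g. a CALHM-family decamer downloaded from the PDB — assigns van der
Waals radii, finds the symmetry axis and prints the pore geometry and
lining chemistry.  For conformational angles between two states, see
examples/03 and `porelume compare-conformers --help`.
"""

import sys

import porelume as pl

if len(sys.argv) < 2:
    sys.exit(__doc__)

model = pl.assign_vdw_radii(pl.read_structure(sys.argv[1]))
print(f"{model.label}: {len(model)} atoms, {len(model.chains)} chains")

n_sub = len(model.chains)
axis = pl.principal_channel_axis(model, symmetry_order=n_sub)
print(f"axis direction {axis.direction.round(3)}, "
      f"{n_sub}-fold self-superposition RMSD "
      f"{pl.rotational_symmetry_rmsd(model, axis, n_sub):.2f} A")

frame = axis.to_axis_frame(model.coords)
prof = pl.compute_pore_profile(
    model, axis, (frame[:, 2].min() + 2, frame[:, 2].max() - 2),
    step=1.0, search_radius=60.0)
constr = pl.min_constriction(prof)
height, _ = pl.assembly_dimensions(model, axis)
_, outer = pl.assembly_dimensions(model, axis, include_vdw=True)
print(f"constriction {2 * constr.radius:.1f} A at z = {constr.z:+.1f} A")
print(f"height {height:.1f} A, outer diameter {outer:.1f} A")

lining = pl.pore_lining_residues(model, prof, contact_cutoff=1.5)
by_class = {}
for r in lining:
    by_class[r.res_class] = by_class.get(r.res_class, 0) + 1
print(f"pore-lining residues by class: {by_class}")
band = pl.hydrophobic_membrane_band(lining, band_width=30.0)
# keep at least one station outside the band on each side; a uniformly
# hydrophobic lining (as in fully synthetic walls) can push the band
# against the profile edge
band = (max(band[0], prof.zs[1] - 0.5), min(band[1], prof.zs[-2] + 0.5))
extra, intra = pl.entrance_diameters(prof, band)
print(f"membrane band {band[0]:+.0f}..{band[1]:+.0f} A -> "
      f"entrance diameters {extra:.1f} / {intra:.1f} A")
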