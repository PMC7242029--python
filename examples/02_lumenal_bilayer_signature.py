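"""Detecting a lipid-bilayer signature in a lumenal density profile.

Generates a toy bilayer (two headgroup sheets 38 A apart plus sparse
tails), renders it to a density map at 6 A resolution / 1.34 A pixels,
and measures the axial profile of the central 6 x 6 pixel column — the
same measurement used on cryo-EM reconstructions of wide channels whose
pore encloses lipid or detergent.
"""

import numpy as np

import porelume as pl
from porelume import synthgen as sg

atoms = sg.make_toy_bilayer(sg.BilayerSpec(headgroup_separation=38.0, seed=1))
spec = pl.RenderSpec(resolution=6.0, pixel=1.34, amplitude_mode="electron-count")
profile = pl.reference_bilayer_profile(atoms, spec)
signature = pl.detect_bilayer_peaks(profile)

print(f"bilayer pseudo-atoms : {len(atoms)}")
print(f"profile              : {len(profile.z)} slices, step {profile.step:.2f} A")
print(f"detected maxima at z : {np.round(signature.peak_z, 1)} A")
print(f"peak separation      : {signature.separation:.2f} A "
      "(headgroup-to-headgroup distance; ground truth 38.0 A)")
# Two maxima separated by ~35-45 A are the axial signature of a lipid
# bilayer; recovery within one voxel (1.34 A) shows the column profile
# resolves the headgroup sheets at this resolution.
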