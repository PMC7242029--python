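# Methods

This note documents the models, conventions and parameter choices
behind `porelume`, and what the synthetic test system does and does
not establish about real data.

## Coordinate and axis conventions

All physical coordinates are Å in a right-handed frame. Density
lattices are 0-based, indexed `values[ix, iy, iz]` in physical x, y, z
order; a voxel's position is `origin + index * voxel_size`
(voxel-corner convention, matching MRC2014). Files whose header
permutes the axis order (MAPC/MAPR/MAPS) are re-indexed on read, so
profile extraction along z is axis-order invariant. Maps are written
as MRC2014 mode 2 (float32); round trips preserve values bit-exactly.

The channel axis is found as the inertia eigenvector with the most
isolated eigenvalue — for an n-fold symmetric body (n ≥ 3) the two
moments perpendicular to the symmetry axis are degenerate, so the
symmetry axis carries the distinct one. When the oligomeric order is
known, candidates are instead ranked by self-superposition RMSD under
a 2π/n rotation, which also serves as a validation statistic. The
atom subset defining the axis is whatever model the caller passes;
for channels with a flexible C-terminus, selecting the
membrane-embedded chains first is recommended. Axial (z) coordinates
reported by every analysis are signed so that +z points intracellular
(`ChannelAxis.intracellular_sign`); the sign is the caller's choice
since handedness cannot be inferred from coordinates alone.

Alternate locations other than blank/'A' are dropped, insertion codes
are kept in residue identity, and hydrogens are ignored throughout
(cryo-EM depositions at the resolutions of interest carry none).

## Inscribed-sphere pore profile

At each station the planar-constrained HOLE objective
`min_i(|p − c_i| − r_i)` is maximized over sphere centers `p` in the
axis-normal plane. The objective is a pointwise minimum of smooth
cone functions — piecewise-smooth and multi-modal — so the optimizer
is multi-start: a coarse grid (1 Å, including a sampled rim of the
search disc) seeds the best few candidates, each polished by a 0.1 Å
local grid and a Nelder–Mead simplex (xatol 1e-4). Points outside the
search disc (default bound 80 Å) are projected onto its rim, keeping
the objective continuous so rim maxima remain reachable. Against a
dense 0.02 Å brute-force grid the optimizer agrees to better than
0.02 Å on random 30–80-atom instances (the suite asserts ≤ 0.05 Å over
50 instances).

By default consecutive stations are linked by a connectivity
constraint: each station's sphere must overlap the previous one
(center-to-center distance ≤ previous radius + step + 1 Å), with the
first station anchored to the axis point. Without it, the planar
optimum at a conical or funnel-shaped mouth jumps to the open space
*outside* the channel wall, which is not the conduction path; this is
the planar analogue of HOLE's connected Monte-Carlo walk and can be
disabled (`connectivity=False`) for pure per-plane maximization, which
is what the brute-force comparisons use. Radii are clamped at 0;
stations whose optimum sits on the search-disc rim are flagged
`open_plane` rather than failing.

Derived quantities: the constriction is the station of minimal radius
(ties → smallest z); entrance diameters are twice the radius at the
first station beyond each membrane bound. Membrane bounds are a
caller input; `hydrophobic_membrane_band` estimates them as the 30 Å
window densest in hydrophobic lining residues, which is meaningful
only when the lining chemistry actually varies along z. Pore-lining
residues are those with any atom whose surface-to-surface gap to a
station sphere is ≤ 1.5 Å (configurable), classified by a four-class
table shipped as plain text (acidic ASP/GLU; basic LYS/ARG/HIS; polar
SER/THR/ASN/GLN/TYR/CYS/TRP/GLY; remainder hydrophobic). Assembly
height and width are axis-projected extents, by default on atom
centers; outer dimensions intended as the protein's physical envelope
add the vdW radii (`include_vdw=True`). The bundled Bondi-style vdW
table is a replaceable two-column text resource.

## Lumenal density profile and bilayer signature

The axial profile is the mean of the `column_px × column_px` (default
6 × 6) in-plane block of voxels nearest the axis intersection, slice
by slice; for even column sizes "nearest" is resolved by distance then
smaller index, which is deterministic. The column must be verified to
lie outside a model-derived exclusion mask (all voxels within
vdW + pad of any atom; pad default 2 Å) — `verify_column_outside_mask`
reports any slice where it does not. If the axis is tilted more than
5° from every lattice axis the map is first resampled trilinearly onto
an axis-aligned frame; reconstructions whose symmetry axis sits on a
lattice axis take the exact path.

Peak calling: a moving average (default 3 slices) followed by local
maxima filtered at a prominence of 0.1 × profile max (both
configurable). The two highest surviving maxima define the reported
separation; a lumenal bilayer shows two maxima 35–45 Å apart. For
cross-state comparison, profiles are max-1 normalized and resampled
onto their common z-overlap; peaks are greedily matched within a z
tolerance of 10 Å — large enough to track a peak that shifts by a
leaflet thickness (~8 Å), small enough not to pair opposite leaflets
(~38 Å apart). For state comparisons on the synthetic fixtures a 6 Å
smoothing window and 0.15 prominence are used to keep the sparse
pseudo-atom tail region from contributing minor ripples; both are
explicit arguments wherever used.

## Density simulation and protein subtraction

Maps are rendered as one isotropic 3D Gaussian per atom with
σ = resolution/(π√2) — the convention in which the kernel's Fourier
amplitude falls to 1/e at spatial frequency 1/resolution — truncated
at 4σ (< 0.1 % mass loss), each normalized so its integral equals the
atom's amplitude (1 in `uniform` mode, the element's electron count in
`electron-count` mode). Defaults are 6 Å resolution on a 1.34 Å
lattice; `resolution ≥ 2 × pixel` is enforced (Nyquist). The width
convention differs between rendering tools and versions; peak
*positions* — which all separation measurements rest on — are
insensitive to it. Protein subtraction zeroes voxels within vdW + pad
of any model atom: a reproducible, parameter-controlled rule in place
of interactive density selection.

## Conformational comparison

Superposition is the least-squares proper rotation over paired Cα
selections (SVD/Kabsch, via `scipy.spatial.transform`); the pairing is
an explicit residue-range input — no automatic sequence alignment is
attempted, because paralog correspondence is a modelling decision.
The recommended core for cylindrical-vs-conical comparisons is the
conformationally stable elements (TM2, TM4 and the C-terminal helix).
A helix axis is the first principal component of its Cα positions,
oriented N→C; it carries an O(1/n) bias from the linearly-weighted
helical phase (≈1° at 25 residues, <0.5° at ≥40), which cancels in
comparisons of equal-length segments. Inter-helix angles are unsigned
acute angles after mapping the second helix through the core
superposition (an oriented 0–180° variant is available). Tilt against
the membrane plane is reported with both complementary readings
(`from_axis_deg` + `from_plane_deg` = 90°) to remove any 70°/20°
ambiguity; the headline value is measured from the channel axis.

## The synthetic study system

`synthgen` encodes the geometry of the two conformational states of a
CALHM-like channel as the generators' defaults: a 90 Å-high decamer
(undecamer) with 52 Å (60 Å) lumen mouths, a 20 Å (30 Å) constriction
plateau just inside the intracellular membrane boundary, a 110 Å
(120 Å) outer envelope and a 30 Å-high intracellular helix ring; a
conical variant narrowing intracellularly; lumenal bilayers with
headgroup separation 38 Å (two P-atom sheets at ±19 Å plus a sparse
C-atom tail slab); and conformer pairs with 60° and 30° helix
rotations about a hinge plus a 70°-tilted peripheral helix.

Ring walls are built as surfaces of revolution from a
piecewise-linear lumen-radius profile r(z): atom rings are placed at
radius `(r + vdW)/√(1 − s²)` for local slope `s`, the normal offset
that makes the perpendicular distance from an on-axis point equal
r + vdW, so the inscribed-sphere radius on plateaus and linear
segments equals the prescription exactly (rasterization error < 0.01 Å
at the default 0.75 Å ring spacing). Slopes must stay below 1 —
inscribed-sphere profiles are 1-Lipschitz, so steeper prescriptions
are geometrically unrealizable and rejected. Bilayer pseudo-atoms use
Poisson-disc placement (headgroups 0.12 atoms/Å² at ≥2.2 Å spacing,
tails 0.02 atoms/Å³ at ≥2.0 Å spacing) with 0.8 Å Gaussian
jitter; rendered with electron-count amplitudes, the P/C contrast
reproduces the headgroup-dominant axial signature of real bilayers.
Noise for robustness tests is additive Gaussian voxel noise with
SNR = peak signal / noise SD; separation recovery is within one voxel
(1.34 Å) over separations 30–45 Å at SNR ≥ 5.

All generators are deterministic given their seed, and the fixture
suite writes a JSON manifest carrying every ground-truth parameter;
recovery tests read truth from the manifest, never from code
constants.

**What passing tests show — and don't.** The synthetic system
establishes that the measurement code recovers known geometry,
separations and angles through the full pipeline (axis finding →
profiling → peak detection / superposition) at the stated accuracy.
It does not emulate experimental map imperfections — anisotropic
resolution, B-factor variation, masking artifacts, partial occupancy,
detergent-vs-lipid ambiguity — so accuracy on real reconstructions is
bounded by those factors, not by the numerics tested here. All
operations accept deposited MRC/PDB/mmCIF inputs directly
(`examples/05_deposited_models.py`).

## Problem sizes

Test and acceptance runs use ~10⁴-atom assemblies, 96³ fixture maps,
1 Å station spacing and a 0.02 Å brute-force oracle on 30–80-atom
instances — sizes at which every guarantee is checked exactly while
the whole suite runs in a couple of minutes on one CPU.

## Known limitations

- The planar-constrained profile with connectivity is appropriate for
  axially pseudo-symmetric channels; strongly off-axis or branched
  pores need a full 3D walk, which is out of scope.
- `hydrophobic_membrane_band` degenerates when the lining is uniformly
  hydrophobic (as in single-material synthetic walls); pass explicit
  membrane bounds in that case.
- The helix-axis PCA bias (O(1/n)) makes absolute single-helix angles
  on short segments (< 15 residues) uncertain by ~2°; differential
  angles between equal-length segments are unaffected.
- Map origin handling follows the ORIGIN-words-then-NXSTART
  convention; exotic header combinations (nonzero both, non-orthogonal
  cells) are not supported.
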