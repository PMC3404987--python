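# Methods

This note documents the models, conventions and numerical choices behind
`dmsopore`, and what the synthetic generator does and does not emulate.

## Geometry and conventions

Coordinates are in nm throughout (GRO native; PDB Å are converted on read).
The bilayer normal is fixed to the z axis and the global frame is never
de-tilted. Positions are wrapped to [0, L) per axis; every pairwise
operation (pore clustering, pair correlation, lining counts) uses the
in-plane (x, y) minimum image for the rectangular periodic box, and
intramolecular vectors are rebuilt from minimum-image bond displacements so
molecules split by the wrap stay intact. Triclinic boxes are out of scope.

Leaflets are split about the midplane, defined as the mean z of all
phosphate markers; a molecule whose reference atom (DOPC phosphate, Chol
hydroxyl O) lies exactly on the midplane goes to the lower leaflet, a
deterministic tie-break. The outward normal is +z for the upper leaflet and
−z for the lower.

The scaled coordinate Z′ maps each leaflet's phosphate-density maximum to
±1: Z′ = (z − z_mid)/h with h the distance from the midplane to that side's
maximum, evaluated piecewise per side. The scaling is computed once per
analysis window (not per frame), so one scaled profile describes one
condition. A phosphate profile without two separated maxima (collapsed
membrane) is a scaling error, not a silently wrong profile.

## Density and free-energy profiles

Density profiles histogram atomic masses in uniform raw-z bins (default
width 0.05 nm, which resolves the headgroup peak at generator scale) and
divide by the bin volume Lx·Ly·Δz per frame. Masses are standard atomic
values (H 1.008, C 12.011, O 15.999, P 30.974, S 32.06 u); united-atom
carbons carry their implicit hydrogens (CH₂ 14.027, CH₃ 15.035 u). Mass is
conserved exactly: Σ ρ·V_bin equals the component mass in the box.

Boltzmann inversion gives ΔG(z) = −RT ln(ρ(z)/ρ₀) in kJ/mol with
R = 8.314 J mol⁻¹ K⁻¹ and T = 310 K by default. The bulk region defining ρ₀
is |Z′| > 1.5 (configurable); after inversion the bulk average of ΔG is
subtracted so the gauge is exactly zero in bulk. Bins with ρ = 0 are
reported as unbounded (NaN) and counted — they are never imputed, and
barrier heights are maxima over finite bins only. At desk-scale sampling a
deep barrier simply produces flagged bins rather than a pretended finite
value.

## Chain order, tilt, correlation, orientation

S_CD uses the two C–H directions of each interior tail carbon. With
united-atom chains the H are reconstructed assuming ideal tetrahedral
geometry: for carbon i the local axis is C(i−1)→C(i+1); the two H lie
perpendicular to it, symmetric about the local chain plane, with the H–C–H
bisector along the C–C–C bisector reversed. Explicit H positions, when a
force field provides them, would take precedence; the generator emits none.
Double-bond carbons are not special-cased (the generator carries no bond
order), a simplification that would bias the C9–C10 segments of real DOPC.

Tilt is the angle between the chain vector (first→last carbon; a
principal-axis fit is a possible alternative, not implemented) or the Chol
axis (hydroxyl O → last ring-axis carbon) and the molecule's outward leaflet
normal, folded to [0°, 90°] since the vectors are axis-like.

C(r) is computed per leaflet from DOPC centers of mass (cross-leaflet pairs
excluded — in-plane organization is a monolayer property), with ordered pair
counts per annulus normalized by annulus area × (N−1)/A × N; the (N−1)/A
reference density makes an ideal gas average to exactly 1. Leaflet and
frame contributions are pooled by counts.

Dipole profiles bin each molecule by its Z′ (DMSO: O–S midpoint; water:
oxygen) and average the angle between the dipole direction (DMSO O→S; water
O→H bisector, both negative-to-positive) and the outward normal of the
molecule's side (sign of Z′). Isotropic orientations average to 90°. In a
solvent-only box with no phosphates, Z′ falls back to z − Lz/2 in nm, which
only relabels the bins.

## Pore detection and regimes

The hydrophobic slab is the region between the leaflet mean phosphate
planes shrunk by 0.3 nm per side, which excludes ordinary headgroup
hydration water. Water oxygens inside the slab are clustered by single
linkage at a 0.35 nm O–O cutoff (first hydration shell) with in-plane
periodicity; the implementation (kd-tree + sparse connected components) is
tested for exact partition equality against a brute-force O(N²) oracle.
A cluster spans the slab when it reaches within one cutoff of both faces.
Spanning defects in consecutive frames link into one event when they share
at least one member water (single-file columns exchange members rapidly, so
the overlap threshold is deliberately minimal).

Classification thresholds are pre-registered constants, echoed into every
output: stable means a lifetime of ≥ 10 frames or persistence to the end of
the trajectory; hydrophilic means ≥ 6 phosphate/Chol-hydroxyl atoms within
0.6 nm of the column axis inside the slab, in at least half the event's
frames. A long-lived bare column is INDETERMINATE rather than forced into
either class. DMSO molecules can optionally join defect membership (they
wrap water columns) but never count toward the hydrophilic lining, which is
a lipid-headgroup property. Regime III is triggered either by a
non-intact bilayer in any frame or by ≥ 3 simultaneous spanning defects;
II by at least one stable hydrophilic pore in an intact bilayer; I
otherwise. Trajectories shorter than the stability threshold are
UNDETERMINED (unless III already triggered): they cannot distinguish stable
from transient. The lifetime threshold separating "transient" from
"stable" is a package decision — the phenomenology it encodes is
qualitative.

## The synthetic generator

Configurations are statistically sampled, not simulated: frames are i.i.d.
draws (plus planted pores), which suffices because every analysis is an
ensemble average. Defaults are the reference composition the analyses
target: 128 DOPC, 20 mol% Chol (32 molecules; counts round to nearest, ties
away from zero), 6186 solvent molecules, box_xy = 6.67 nm (area 44.5 nm²),
phosphate planes at ±2.085 nm (P–P 4.17 nm), order/tilt targets 0.1528 /
28.26° / 30.88°, water core penetration 0.05, DMSO dipole bias 110°. The
DMSO solvent fraction defaults to 5 mol%, the headline condition of the
profile analyses; it is the swept variable.

Chain order control. Each acyl chain receives a director u from a
Watson-type axial distribution p(u) ∝ exp(κ(u·n)²) about the inward leaflet
normal; κ is solved by bracketing root-finding (quadrature for the mean
angle) so the mean director tilt equals the tilt target. An ideal
tetrahedral zigzag of 18 united-atom carbons (C–C 0.153 nm) is laid along
u, and the interior carbons receive transverse Gaussian noise of amplitude
σ, solved by root-finding — Monte Carlo with common random numbers and a
fixed internal calibration seed, so (κ, σ) depend only on the targets — so
that the implied ⟨−S_CD⟩ (computed with the same tetrahedral H
reconstruction the analysis defines) equals the order target. Endpoints
stay noise-free, so the end-to-end vector remains Watson-distributed and
tilt and order decouple; a combination whose order target exceeds what the
tilt distribution allows is rejected with an explanatory error. Chol is a
rigid rod (hydroxyl O + 4 axis carbons) with its own Watson concentration
solved for the Chol tilt target.

Solvent. Water z positions are rejection-sampled from a piecewise relative
density: 1 outside the phosphate planes, decaying log-linearly to the
`water_core_penetration` value at Z′ = 0. DMSO mixes a bulk component
(uniform in |Z′| > 1) with an interfacial Gaussian centred at |Z′| = 0.9
(width `dmso_interface_width`, default 0.25 nm; interfacial weight 0.55).
Water is a rigid 3-site model (O–H 0.1 nm, 104.5°) with the dipole along
the bisector; DMSO is reduced to S, O and two methyl carbons — the minimal
sites defining every analyzed vector. Dipole polar angles vs the outward
normal are truncated normals about the requested means (DMSO everywhere,
water within |Z′| ∈ [0.7, 1.3]); a `None` mean gives isotropic
orientations. Placement enforces a coarse 0.25 nm exclusion between solvent
anchor sites (water O, DMSO S) and lipid heavy atoms via a spatial hash with
a retry cap — enough to keep the pore detector free of degenerate
zero-distance clusters without the cost of a full heavy-atom check.

Planted pores relocate existing bulk waters (bulk-most molecule ids,
deterministic) into a column of levels spaced 0.25 nm spanning the
inter-phosphate region, with a clipped lateral random walk inside the
planned radius so consecutive oxygens stay below the clustering cutoff; the
same molecule ids are used in every planted frame so tracks link.
Hydrophilic plans additionally relocate the nearest phosphate/hydroxyl
atoms onto a 0.45 nm ring around the axis in the central part of the slab.
Ground truth (kind, frames, member ids) is recorded in trajectory metadata
and in the CLI's sidecar TSV.

Two auxiliary systems support oracle tests: a water slab sampled from
exp(−U(z)/RT) for a user-supplied potential (Boltzmann inversion must give
U back), and an isotropic DMSO box (orientation profile must average 90°).

What the generator does not emulate: energetics, dynamics and kinetics
(pores are planted, not emergent; frames are uncorrelated, so lifetimes are
constructions, not physics), lipid conformational statistics beyond the
two-parameter order/tilt model, double-bond geometry, electrostatics, and
undulation spectra (`undulation_amplitude` is a free knob, default 0, with
a single-mode cosine shape). Passing recovery tests therefore certifies the
*analyses* — that they measure what they claim on data with known
structure — not that the generator reproduces real membranes.

## Problem sizes

Test and acceptance runs use desk-scale systems chosen to keep statistical
tolerances honest: 25 frames of the solvent-free 160-lipid bilayer for
order/tilt recovery (±0.005 / ±0.5°), 2 × 10⁶ water draws (10⁵ × 20 frames)
for the free-energy oracle (±0.5 kJ/mol), 1.2 × 10⁵ molecules for the 90°
orientation baseline (±0.5°), and twenty 12-frame trajectories of a
32-DOPC system for the planted-pore suite, small enough that every frame
can also be checked against the brute-force clustering oracle. Full-size
(6186-solvent) configurations generate in seconds and are exercised in the
composition bookkeeping tests.
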