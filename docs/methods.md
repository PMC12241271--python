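# Methods

This note documents the models, criteria, numerical choices, and known
limitations behind each `cesakit` module, and what the synthetic-data
generators do and do not emulate.

## Coordinate conventions and I/O

All coordinates are Å; cutoffs quoted in nm in the literature are
converted once (0.5 nm → 5.0 Å contact cutoff, 1.2 nm → 12.0 Å energy
cutoff). The canonical trajectory dialect is a multi-model PDB over a
fixed topology; a directory of per-frame PDB files is a secondary dialect
(frames ordered by filename sort). No periodic-boundary imaging is applied
anywhere: inputs are assumed wrapped and whole, which is appropriate for
an assembled membrane-protein channel exported for analysis and for all
desk-scale fixtures.

Elements missing from the PDB element column are inferred from the first
alphabetic character of the atom name, with a short two-letter exception
table (Cl, Br, Fe, Zn, Mg, Mn). `CA` is deliberately not in the table: in
protein context it is an α-carbon. Hydrogen-to-heavy bonds for files
without explicit bond lists are inferred geometrically (nearest heavy atom
within 1.4 Å); downstream logic only ever needs H-heavy bonds (donor
pairing and C–H enumeration).

The side-chain definition includes Cβ and excludes backbone N, CA, C, O
and backbone hydrogens. Rationale: the biology the contact metrics feed is
alanine scanning, which removes exactly the atoms beyond Cβ.

`kabsch_rmsd` computes the optimal-superposition RMSD via SVD with the
usual determinant correction (proper rotations only). Inputs with fewer
than 3 points or rank < 2 after centering (collinear) raise: the rotation
is not unique there and the study-scale use case (720 α-carbon pairs)
never hits it. The residue-pair mapping is always explicit — the utility
does not guess correspondences.

## Contact metrics

A residue is in contact with a glucan chain in a frame when the minimum
distance between its side-chain heavy atoms and the chain's heavy atoms is
≤ 5.0 Å (inclusive at the boundary, matching the inclusive ≥ 80%
convention of the selection rule). The per-frame score sums, over all atom
pairs within the cutoff, the sigmoid weight 1/(1 + exp(5·(d − 4.0))) —
the default weighting of widely used contact-analysis tools; midpoint,
steepness, and cutoff are all exposed in `ContactCriteria`.

Derived metrics per residue×chain pair:

* **total contact time** — 100 × (contact frames / frames);
* **mean contact lifetime** — mean length of maximal runs of consecutive
  contact frames, reported in frames and ns (frame spacing × frames). The
  exact identity mean_lifetime × n_runs = n_contact_frames holds by
  construction;
* **mean contact score** — averaged over contact frames only by default.
  Averaging over all frames would fold occupancy into the score; both
  conventions are computable and the choice is a documented flag.

Pairs whose residue has no side-chain heavy atoms under the filter
(glycine) are skipped with a warning rather than silently reported as
zero.

## Hydrogen-bond and CH-π detection

Hydrogen bonds use two criteria: donor–acceptor heavy-atom distance
≤ 3.5 Å and donor–hydrogen–acceptor angle ≥ 120°. Donors are N/O heavy
atoms with a bonded hydrogen; acceptors are N/O heavy atoms; hydroxyl
oxygens are both. Both directions between a residue side chain and the
glucan are scanned. The 3.5 Å / 120° defaults are common MD practice; the
criteria types come from the study design but the study does not print its
numeric values, so the defaults are config-exposed and must not be read as
the original analysis's exact thresholds.

CH-π stacking of a glucan C–H on a protein aromatic ring uses three
criteria: carbon-to-centroid distance ≤ 4.5 Å, in-plane offset of the
carbon's projection from the centroid ≤ 2.0 Å, and angle between the C→H
vector and the ring normal ≤ 40° (folded: min(θ, 180° − θ), since the
least-squares normal has arbitrary sign). These defaults follow the
carbohydrate–protein interaction literature's convention; again
config-exposed. Ring planes are computed per frame as the
smallest-variance principal direction of the centered ring atoms (SVD);
Phe/Tyr contribute their 6-ring, His its 5-ring, Trp both rings. Only
glucan C–H donors against protein rings are scanned (the direction the
translocation problem cares about), not protein C–H against sugar faces.

Occupancies are ANY-combination per frame: a frame counts once no matter
how many donor/acceptor or C–H/ring combinations qualify, so H-bond time
and CH-π time are genuine occupancy percentages. With the default
thresholds (3.5 ≤ 5.0 Å) hydrogen-bonded frames are necessarily contact
frames, and the suite asserts that ordering.

CH-π time for a non-aromatic residue is defined as 0% with a warning (not
an error), so whole-table sweeps remain convenient.

## Interaction energies

The per-residue energy metric is a post-processing contact energy, not a
simulation energy: Coulomb k·q_iq_j/r with k = 332.0522 kcal·Å/(mol·e²)
(the internal constant of the MD engines behind the standard
protein/carbohydrate force fields) plus Lennard-Jones
4ε[(σ/r)¹² − (σ/r)⁶] with Lorentz–Berthelot combination (arithmetic σ,
geometric ε), summed over atom pairs within a plain 12.0 Å truncation —
no switching, no Ewald, no 1–4 scaling (residue and glucan are distinct
molecules). Whole-residue atoms enter by default; a flag restricts to the
side chain. The identity total = Coulomb + LJ holds per frame to machine
precision, and the vectorized sum is tested against an independent
double-loop oracle.

## Residue selection

The strong-contact rule marks a residue when its total contact time is
≥ 80% (inclusive) for at least 2 of the 3 monomer channels of the
homotrimer; both knobs are parameters. The five-way side-chain chemistry
partition covers all 20 standard residues: cationic {Arg, Lys, His},
anionic {Asp, Glu}, aromatic {Phe, Trp, Tyr}, polar-uncharged {Ser, Thr,
Asn, Gln, Cys}, non-polar aliphatic {Gly, Ala, Val, Leu, Ile, Pro, Met}.
His is classified cationic here while remaining a π ring in the CH-π
detector — the two tables serve different questions and the class table
is override-able per call. Region annotations (TMH spans, apoplastic
tail) are supplied as a user file, never inferred.

The package ships a **synthetic** strong-contact reference table
(`synth_contact_reference_table`): the 23 strong-contact residue
identities are the channel residues a moss CESA mutagenesis campaign
tested (3 cationic, 2 anionic, 3 polar-uncharged, 10 aromatic, 5
non-polar aliphatic among 82 contact residues), while the other 59
residues and all per-chain occupancy values are synthetic draws placed on
the correct side of the filter, including exact-boundary (80.0%) cases.
It exercises the filter arithmetic; it is not measured data.

## GIWAXS / XRD texture analysis

Reduction assumes an idealized flat detector: pixel radius r gives
2θ = arctan(r/D), q = (4π/λ)·sin θ, and azimuth χ measured from the
vertical (out-of-plane) axis; pixels below the beam-center row are
masked. Grazing-incidence curvature corrections (the missing-wedge
distortion near the meridian) are not applied; instead, the low-χ part of
the pole figure comes from rocking scans and is stitched on — mirroring
the acquisition strategy the module supports. 10 keV corresponds to
λ = 1.2398 Å.

Defaults: q bin 0.005 Å⁻¹, χ bin 1°, vertical sector χ ∈ [−17°, +17°],
(110) annulus 1.0–1.3 Å⁻¹. The vertical cut is fit by nonlinear least
squares as a flat background plus Gaussians: the (200) peak initialized
at 1.55 Å⁻¹, a broad amorphous component at 1.40 Å⁻¹, and optionally a
small starch component at 1.45 Å⁻¹ (off by default; a flag, because only
some samples show it). Centers are bounded within ±0.05 Å⁻¹ of
initialization so the sharp peak cannot wander onto the amorphous hump.
Peak FWHM is reported in q and as β in 2θ radians
(β = 2θ(c + w/2) − 2θ(c − w/2)), feeding the Scherrer form
L = Kλ/(β cos θ) with K = 0.9.

Pole figures: azimuthal profiles are folded onto χ ∈ [0°, 90°]; rocking
profiles at the three rocking angles are interpolated to a common grid
and averaged pointwise; the GIWAXS branch is rescaled by the
least-squares scalar matching the rocking branch over their χ overlap,
the overlap averaged after scaling, and the branches concatenated. The
prior literature's exact geometric/solid-angle corrections are not
published in a reusable form, so the stitching contract here is this
explicit, simple rule, validated by parameter recovery on synthetic
images.

Pole FWHM subtracts a flat baseline (the profile minimum — whether the
original analyses baseline-subtracted is unstated, so the rule is
explicit and override-able) and locates half-maximum crossings by linear
interpolation. A peak abutting the χ = 0 fold axis is completed
symmetrically (width = 2 × one-sided half-width); if no crossing exists
the result is censored, not a number. RCCC is the trapezoidal integral of
sin(χ)·I(χ) with χ in radians, so I ≡ 1 integrates to exactly 1.

## Phenotype statistics

Wilson score intervals are the classic closed form without continuity
correction (the corrected variant is a flag); bounds are clamped to the
analytic endpoint values 0/1 at k = 0 and k = n. A note on coverage: at
n = 50 the interval's exact coverage oscillates with p — about 97.0% at
p = 0.1 or 0.9 and 93.5% at p = 0.5 — a standard discreteness effect of
binomial intervals. The nominal ≈95% level is met on average over p, not
pointwise, and the test suite asserts exactly that (pooled coverage in
94–96.5%, per-p simulation matching the exact analytic coverage).

The two-tailed Fisher exact test uses the probability-mass rule (sum of
hypergeometric probabilities, margins fixed, of tables no more probable
than the observed one), delegated to scipy's implementation and verified
against full enumeration in the tests. A zero margin leaves the table
unorderable; the p-value is then defined as 1.

Cell shape descriptors operate on raw hand-traced polygon vertices with
no smoothing: shoelace area, closed-polyline perimeter, circularity
4πA/P² (1 for a circle, decreasing with elongation). Self-intersecting
outlines are rejected (shapely validity test). Group comparisons beyond
pairwise Fisher tests (Welch ANOVA, Games–Howell) are out of scope.

## Synthetic data: what it emulates, and what it does not

The trajectory generator builds a linear β-1,4 glucan from idealized
chair glucose units (ring pucker ±0.25 Å, axial ring hydrogens along ±z,
equatorial hydroxyls O2/O3 plus the C6–O6 arm, bridging O4, correct
donor/acceptor/C–H labeling and explicit bonds) and places idealized
residue stubs — Ser, Arg, Glu, Phe, Trp, Leu templates with a backbone
quad and chemically correct side-chain atoms — near designated glucose
units. Per frame each residue is rigidly translated into one of four
states: detached (30 Å away), contact-only (closest side-chain heavy atom
at 4.6 Å, outside H-bond range), hydrogen-bonding (collinear D–H···A at
2.8–2.9 Å), or CH-π stacked (ring centroid 3.4 Å under an axial C–H).
State masks are deterministic Bresenham interleavings, so designed
occupancies are met exactly and stage tests are sharp rather than
statistical; unsatisfiable designs (hbond% + chpi% > contact%, CH-π on a
non-aromatic, H-bond on an apolar side chain, occupancies not
representable in the frame count) raise at generation time. Nonbonded
parameters are per-element values neutralized per residue, so the glucan
net charge is exactly 0; the truth table records per-pair mean energies
computed by a plain double-loop sum independent of the analysis module.
What this does **not** emulate: forces, dynamics, solvent, thermal noise,
backbone helicity, or realistic packing — frames are independent
placements. Passing recovery tests therefore demonstrates the detectors'
geometric correctness and bookkeeping, not robustness to conformational
noise in real trajectories.

The detector generator evaluates an analytic model per pixel — oriented
Gaussian peaks A·exp(−(q−q₀)²/2σ_q²)·exp(−χ²/2σ_χ²) with σ_χ from the
designed orientation FWHM, an isotropic amorphous ring, flat background,
optional seeded Poisson noise — on the same flat-detector geometry the
reduction uses, with an arbitrary GIWAXS intensity scale so stitching has
a real scale factor to recover. It does not emulate detector gaps,
flat-field structure, polarization, or grazing-incidence distortion.
Rescue counts are seeded binomial draws; cell outlines are noisy ellipses
(or exact rectangles, whose circularity has the closed form
4πab/(2a + 2b)²) with known aspect ratio.

Default problem sizes — 200-frame trajectories with a handful of
residue–glucan pairs, 256×384-pixel detector images, 10,000-replicate
coverage simulations — were chosen as the smallest scales at which every
recovery tolerance in the test suite is meaningful (occupancy grids
resolvable exactly, 1°-binned pole figures, sub-bin peak localization).

## Known limitations

* The PDB reader handles the ATOM/HETATM/MODEL/ENDMDL dialect it writes,
  not the full format zoo (no altLoc handling, no insertion codes, no
  CONECT).
* Contact metrics are side-chain-mediated by design; backbone- or
  water-mediated contacts are out of scope.
* The energy metric is a truncated two-group sum, not a free energy; no
  polarization, no long-range electrostatics.
* Flat-detector q-mapping ignores grazing-incidence curvature; at the
  small incident angles and q-ranges used here the error is far below the
  quoted tolerances, but the module should not be used for quantitative
  work near the missing wedge without rocking data.
* The selection module takes the contact-table universe as given; whether
  a minimum-occupancy floor defines "identified contacts" is left to the
  input table.
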