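# Methods

This note documents the models behind `contactzones`, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices a user should know before trusting a number.

## Promolecule density model

All interface constructions use a *promolecule*: the superposition of
spherically averaged, non-interacting atomic densities at the nuclear
positions, occupancy-weighted, with zero-occupancy atoms skipped.
Per-element radial densities are stored as sums of exponentials,

    rho_elem(r) = sum_k c_k exp(-z_k r)      [e/Å³, r in Å],

in `data/atomic_densities.txt` (H, C, N, O, P, S).  The coefficients were
fitted to Slater-type-orbital atomic densities built from
Clementi–Raimondi effective exponents and then rescaled so the quadrature
electron count is exact.  Two caveats are inherent to this analytic form:

* a sum of decaying exponentials is log-convex in r, while the
  r²-weighted valence shell of an atom is log-concave around its shoulder
  (~0.3–0.5 Å); pointwise deviations from the STO reference reach ~2×
  there and ~±50% in the exterior band.  Hydrogen (a pure 1s density) is
  exact.  Because the Hirshfeld weight w = rho_A/(rho_A+rho_B) is a ratio
  of like quantities, the shared radial distortion largely cancels: the
  w = 0.5 surface between identical atoms is exact by symmetry regardless
  of the radial profile, and heteroatomic interfaces shift only through
  the *difference* in profile errors.
* the model is spherical.  An aspherical (multipolar) density would bend
  the interface near lone pairs and π systems; this package deliberately
  does not model that, and says so in every output's metadata.

Elements outside the six-type chemical scheme are mapped by a
configurable table (default: S, Se, P treated as carbon-like apolar
atoms).

## Hirshfeld interface

The interface between typed sides A and B is the w = 0.5 isosurface of
the weight field sampled on a regular grid (default spacing 0.2 Å, margin
4 Å beyond the joint bounding box), extracted by marching cubes
(scikit-image).  Facets are retained only if the promolecule density at
their midpoint exceeds a cutoff, default 0.0013 e/Å³ — this trims surface
facing bulk solvent, where both densities are vanishingly small, so that
contact statistics cover genuine intermolecular area only.  Two cutoff
interpretations are implemented behind `cutoff_mode`: `"total"` (default)
tests rho_A + rho_B at the midpoint; `"partner"` tests the smaller of the
two side densities.  At w = 0.5 the two differ by exactly a factor of
two, so the choice shifts the trimming radius but not the topology.

Facet→atom attribution defaults to the atom with the largest individual
density contribution at the facet midpoint (the same partitioning spirit
as the weight itself); nearest-atom attribution is available behind
`assign="nearest"`.  The attribution rule is recorded in the patch-set
metadata.

Mesh-quality expectations (verified in the test suite on a homonuclear
two-atom fixture): facet vertices lie within one grid spacing of the
exact bisector plane; total retained area changes by <2% from 0.2 to
0.1 Å spacing; raising the cutoff strictly shrinks the area.  The
binary keep/drop trimming makes the area converge linearly at the trim
boundary, which is why the convergence bound is a few percent rather
than quadratic.

Structural waters a user wants counted as receptor surface are merged
into that side before meshing (`merge_waters_into`); waters are typed W
(bare oxygen — the scheme carries no water hydrogens).

## Contact enrichment

With S_X the percentage of a side's interface area contributed by type X
and C_XY the percentage of total area where X and Y face each other
(pooled over the two orientations), the random-mixing expectation is
R_XY = (S_A[X]S_B[Y] + S_A[Y]S_B[X])/100 for X≠Y and S_A[X]S_B[X]/100 on
the diagonal, and E_XY = C_XY/R_XY.  Conventions:

* cross-side contacts are pooled unordered (X-on-A↔Y-on-B with
  Y-on-A↔X-on-B), giving a single triangular contact table;
* pairs with R ≤ 0.05% have *undefined* E (reported as missing, printed
  as 0 in table serializations by default — matching how reference
  tables print impossible self-contacts);
* reports round S/C/R to one decimal and E to two, matching the field's
  presentation; the underlying dicts keep full precision;
* the grouped hydrophobic/hydrophilic summary pools
  {C, Hc, N} vs {Ho/n, O, W} — sp² peptide/guanidinium nitrogens carry no
  lone pair and count hydrophobic — and applies the same formulas to the
  two-class system.  The grouping is a parameter and must partition the
  type set.

On the published NRP1-b1/KDKPPR table the recomputed ratios match the
printed ones within ±0.02 for all pairs whose contact share is large
enough that one-decimal input rounding cannot dominate; for the two
smallest contacts (C ≤ 0.5%) the discrepancy is up to 0.05/R, exactly
the propagated rounding of the printed inputs.  The published text and
table disagree on which grouped ratio is 1.26 vs 1.38; the arithmetic
from the printed surface and contact values gives hydrophobic–hydrophobic
1.26 and hydrophilic–hydrophilic 1.38, which this package reports.

## Electrostatics and NIZ

The potential is the bare Coulomb sum phi(r) = Σ q_i/|r−r_i| in reduced
units of e/Å (multiply by 332.0637 for kcal/mol per unit test charge);
the field is its analytic gradient.  No dielectric screening: basins in
vacuum overestimate long-range reach compared to a solvated system, which
is acceptable for the qualitative question the analysis answers (which
nucleophile captures which approach direction).

Field lines integrate dr/ds = E/|E| with fixed-step RK4 (default step
0.05 Å) and terminate on (i) entering the capture radius (default 0.4 Å)
of any non-excluded atom — lines ending on a non-target nucleophile are
classified *other-sink*, never forced into a target basin; (ii) leaving
the domain box (*escaped*); (iii) field magnitude below 1e-8 or an
exhausted length budget (default 50 Å) (*stagnated*).  NIZ maps seed a
field line at every voxel center outside the capture radii (default
spacing 0.5 Å); basin volume is voxel count × voxel volume.  Step,
capture radius, spacing and domain are free parameters with
convergence-tested defaults: on the fixtures in the test suite, halving
the step changes <1% of terminal labels, and mirror-symmetric sinks get
basins equal within 2% (voxelization).

Ligand exclusion is first-class: excluded atoms contribute neither field
nor capture, mirroring the use case of mapping the receptor's influence
in the ligand's absence.  Target indices refer to the post-exclusion atom
list.

## Fluctuation analytics

* Kabsch superposition by SVD with the determinant correction, so
  reflection-requiring cases resolve to a proper rotation; weighted RMSD
  = sqrt(Σw|x′−y|²/Σw).
* RMSD series: per-frame superposition of the stated selection onto the
  reference, then RMSD over that selection.
* RMSF: frames superposed onto the first frame using a fit selection
  (backbone heavy atoms N, CA, C, O when working from a structural
  roster); fluctuations measured about the ensemble mean by default.
  Measuring about the first frame instead is available (`about=
  "reference"`) and is never smaller than the about-mean value.  Which
  center a published profile used is often unstated; the about-mean
  convention is the package's default and is what its tests calibrate.
* RMSTD = sqrt(B/8π²) with exact inverse; per-residue profiles use the
  C-alpha B-factor and skip (with a warning) residues lacking one.
* Profile correlation is plain Pearson r (scipy), undefined for
  zero-variance profiles.

## Synthetic data: what it emulates, what it does not

Every generator takes an integer seed and routes all randomness through
one `numpy.random.Generator`; same seed, same fixture, bit for bit.

* `make_two_atom_complex` — the analytically solvable interface (the
  bisector plane for equal elements).
* `make_random_complex` / `make_lattice_complex` — typed atoms in two
  abutting half-boxes with a minimum-separation constraint (default box
  20 Å, min_sep 1.5 Å — van der Waals-ish packing).  Types are
  independent draws from a stated composition, which makes these the
  *null model* of the enrichment statistic: position and chemistry are
  uncorrelated, so every E → 1 as the interface grows.
* `make_random_patchset` — the same null at the facet level (independent
  type draws per facet), used for calibration at large n without paying
  for meshing.  The calibration tests use 200 000 facets, for which the
  binomial 3σ band of E at R = 1% is ±0.07.
* `make_charge_system` — literal point charges with known basins.
* `make_gaussian_ensemble` — i.i.d. isotropic Gaussian displacements with
  per-atom σ (expected RMSF = σ√3).  Real trajectories have correlated,
  anisotropic motion and slow drift; passing the σ-recovery tests shows
  the estimator arithmetic is right, not that MD post-processing
  subtleties (alignment choice, convergence) are resolved.

Accordingly, passing the suite demonstrates correctness of the
*constructions and statistics* on controlled inputs.  It does not
validate the spherical density model against an aspherical one, nor
vacuum electrostatics against a solvated system — both substitutions are
deliberate, documented, and flagged in output metadata.

## Numerical choices and degenerate inputs

* Hirshfeld weights are undefined where the total density is below
  1e-30 e/Å³ (an error, not a silent 0/0); grid atoms are skipped beyond
  the radius where their density falls under 1e-18 e/Å³, far below any
  density of interest.
* A two-sided system whose weight field never crosses 0.5 (far-apart
  sides) yields an *empty, flagged* patch set, not an error.
* Facets with area < 1e-12 Å² (degenerate marching-cubes triangles) are
  dropped.
* pI bisection narrows the pH interval to 1e-6 rather than testing the
  charge magnitude, because the net charge can plateau near zero across
  a wide pH range; the returned pH always has |charge| < 1e-4.  pI values
  are pKa-set dependent and reported with the set name (default: the
  EMBOSS table).
* Altloc handling: analyses use the highest-occupancy conformer, ties
  broken toward altloc "A".
* Covalent bonds, when not supplied, come from element-pair distance
  cutoffs (sum of covalent radii + 0.4 Å).
* The riding-hydrogen placer is a valence-completion heuristic
  (sp²-carbonyl, amide and carboxylate rules; neutron-normalized X–H
  lengths C–H 1.083, N–H 1.009, O–H 0.967 Å; tetrahedral/methyl cone
  geometry for multiple H).  It completes mostly-protonated models and is
  not a protonation-state predictor — for production work, protonate
  structures with a dedicated tool first.

## Problem sizes used in the shipped checks

The acceptance checks run at desk scale by design: the enrichment
worked example is pure arithmetic on a printed table; the null
calibration uses 2×10⁵ facets; interface convergence uses a two-atom
fixture at 0.2/0.1 Å spacing; NIZ properties use 2–3 charges on grids of
~10³–10⁴ seeds; RMSF recovery uses 25 atoms × 2000 frames.  These sizes
put every stochastic tolerance at ≥3σ while keeping the full suite in
seconds.

## Known limitations

* No crystallographic symmetry expansion: contact listings cover the
  chains the user supplies.
* No fingerprint (d_i/d_e) plots, no curvature properties, no >2-body
  interfaces.
* No Poisson–Boltzmann or any solvent model in the electrostatics.
* Binary trajectory formats are out of scope; ensembles come from
  multi-model PDB (an adapter needs only a coordinate stack and a
  roster).
* The isoelectric-point model is sequence-only Henderson–Hasselbalch —
  no structure-based pKa shifts.
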