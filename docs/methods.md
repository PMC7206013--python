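# Methods

## The problem

When a protein structure must be solved from microcrystals, no single
crystal survives long enough in the beam to give a complete dataset.
Instead, each crystal contributes a short rotation wedge (20° here), and
dozens to hundreds of such partial datasets are combined.  Two things make
the combination hard: the crystals are not guaranteed to be isomorphous
(cell dimensions and packing can differ, especially after a chemical
treatment such as Ca²⁺ soaking that shrinks the cell), and individual
crystals or frames can be damaged or mis-integrated.  `micromerge`
implements the assembly strategy for this situation:

1. **cell-variation grouping** — classify datasets by unit-cell similarity
   and reject deviant cells;
2. **per-group scaling and merging** — put each group's observations on a
   common scale and merge symmetry-equivalents with quality statistics;
3. **completeness gate and ranking** — keep groups whose merged data are
   usable (overall completeness > 90% by default) and pick the best;
4. **iterative crystal-and-frame rejection** — greedily remove the crystal
   (then the frame) whose omission most improves the merging objective.

## Scaling model

Observation intensities are modelled as

    I_obs(h) ≈ k_i · exp(−2·B_i·s²/4) · ⟨I⟩_h ,   s = 1/d ,

with one multiplicative scale k_i and one isotropic temperature factor B_i
per crystal (per-frame scales optionally refine k at fixed crystal B).
The fit alternates (a) inverse-variance merging of the currently scaled
data into a reference ⟨I⟩ and (b) per-crystal weighted least squares for
(k, B), B by bounded 1-D minimization and k in closed form given B, until
the largest relative parameter shift is below 1e−6 (cap 100 iterations; the
rejection loop uses a lighter 1e−5/30 refit because it refits after every
removal).  Absolute scale is not identifiable, so the gauge is fixed at
mean log k = 0 and mean B = 0; any comparison with generating values must
first project them onto that gauge.  Crystals must share reflections
forming one connected component, otherwise the fit aborts naming the
components.

## Merging and statistics

Merged intensity per canonical index is the inverse-variance weighted mean
of scale-corrected observations; σ_merged = (Σ σ⁻²)^(−1/2).  Negative
intensities are kept throughout (truncation would bias weak data).
Resolution shells are equal-volume in 1/d³ (10 by default).  Reported per
shell: n_unique, n_possible (sphere enumeration mapped to the asymmetric
unit with systematic absences removed — the same binning rule is applied to
observed and enumerated reflections so boundary reflections cannot be
double-counted), completeness, R_merge, R_meas, R_pim (the usual
multiplicity-uncorrected/corrected agreement statistics over reflections
with multiplicity ≥ 2), CC1/2 as the Pearson correlation of two random
half-set means (split balanced within each unique reflection, seeded and
reported), and mean I/σ.  Statistics that are undefined on a shell (too few
observations) are NaN, never zero.  `cc_half_splits` quantifies split noise
by repeating the split with consecutive seeds.

For anomalous work Friedel mates are kept separate; CC_anom is the
half-split correlation of ΔI = I₊ − I₋ means, with shells below 3 complete
pairs reported NaN.

## Symmetry

Space groups are explicit operator lists (built-ins P1, P2₁, C2, P2₁2₁2₁,
P4₃2₁2; anything else by operator triplets in the config).  The canonical
asymmetric-unit representative of an orbit is its lexicographically largest
member over all rotational equivalents plus, when merging Friedel mates,
their negatives; this avoids per-group ASU boundary tables and is
deterministic.  A reflection is systematically absent when some operator
fixes it with a non-integral translation phase.  Operator sets, d-spacings
and absence flags are cross-checked against gemmi in the test suite.

## Cell-variation grouping

The distance between two cells is the Euclidean norm of their
mean-relative parameter deviations: each of (a, b, c, α, β, γ) enters as
(x − x̄)/x̄ over the input population, with a configurable extra weight on
the angles.  Mean-relative deviations (the "% cell variation" practitioners
quote) keep parameters of different magnitude comparable without inflating
parameters that carry only jitter — variance standardization would scale
pure noise up to unit size and bury a real shift in one or two parameters.
Groups come from average-linkage agglomerative clustering cut to at most
`max_groups` (default 20) or at a linkage height, then stabilized by
deterministic nearest-centroid reassignment (tree cuts occasionally strand
one point of a clearly separated population).  Rejection is scale-free: a
crystal is rejected when its distance to the group centroid exceeds
`reject_z` (default 3) times the group's median centroid distance.

## Iterative rejection

Greedy steepest-ascent leave-one-out: refit scales on the survivors,
evaluate the objective with each crystal left out (the fitted model is held
fixed within one sweep), remove the best crystal if the improvement exceeds
`tol` (default 0.001 absolute), repeat; after crystal-level convergence the
same loop runs at frame level, frames inheriting their crystal's scale.
Floors: `min_crystals` (default 3) and `min_frames_per_crystal` (default 2)
prevent degenerate emptying; setting `min_crystals` to the set size floors
the crystal pass entirely, which isolates frame-level rejection.  The
objective is overall CC1/2, or CC_anom when the aim is to enhance an
anomalous substructure signal.  The half-split labels are assigned once on
the full observation set and inherited by every subset, so leave-one-out
comparisons within a sweep are not re-randomized.  Every evaluation and
every accepted removal (objective before/after, survivors) is recorded in a
trace; the accepted objective sequence is non-decreasing by construction.

Ranking of gate-passing groups is by overall CC1/2, then completeness, then
unique count, then group id.  A refinement-based arbiter (R_free) would
require phases and model building, which are out of scope; CC1/2 is the
standard data-side proxy and is stated in the report.

## Synthetic data generator

The generator reproduces the statistical structure the assembly consumes,
not the optics of data collection:

* True unique intensities follow an acentric Wilson model: exponential with
  mean Σ(s) = Σ₀·exp(−B_wilson·s²/2).  Defaults Σ₀ = 1000, B_wilson = 15 Ų,
  d_min = 3 Å on a 50×60×70 Å orthorhombic cell in P2₁2₁2₁ — a typical
  small protein crystal; no intensity statistics are published for the
  system that motivated the design, so these are declared generator
  choices.
* Wedge geometry is not ray-traced: every symmetry equivalent of every
  unique reflection gets an independent uniform diffraction angle on
  [0, 360°), and a crystal records the equivalents falling inside its 20°
  wedge (default), binned onto frames by angle.  This preserves what
  matters downstream — per-crystal incompleteness, multiplicity growth
  with crystal count, frame granularity — at desk scale.  With ≥ 30
  crystals the pooled completeness exceeds 95%, which is why merging many
  partial sets works at all.
* Per-crystal scale k ~ U[0.5, 2] and B ~ U[0, 20] Ų (the parameter ranges
  the recovery tests quote); unit-cell jitter σ = 0.05 Å on the
  lattice-free parameters; noise is Gaussian with variance |I| +
  noise_floor (Poisson-like counting plus background, default floor 25),
  with sigma reporting the model SD; negative observations are kept.
  `noise_scale` can switch noise off entirely for exact identity tests.
* Outlier crystals (the non-isomorphous minority) draw from a second
  intensity set built by mixing normalized exponential deviates so its
  correlation with truth is ≈ ρ (`outlier_corr`), and/or from a cell whose
  lengths are all shifted by `outlier_cell_shift` (isotropic, as a
  treatment-induced cell change would be).  The two effects are
  independently switchable so the cell-clustering and intensity-rejection
  stages can be tested separately.
* An optional Friedel-antisymmetric component of relative size
  `anom_fraction` provides anomalous signal; truth intensities always live
  on Friedel-merged orbits, the anomalous delta being the only
  antisymmetric part.

Everything derives from one integer seed; a fixed config reproduces the
collection bit for bit.  What the generator does **not** model — detector
images, spot profiles, absorption, radiation damage, indexing ambiguity —
bounds what passing tests show: they certify the assembly logic under the
assumed statistical structure, not integration quality on real images.

## Cleavage mapping

Digestion rules are either explicit site lists or cut-after residue
classes (Lys/Arg for the metacaspase's own specificity, Phe/Tyr/Trp for
chymotryptic sub-digestion).  Numbering is 1-based and cleavage is
C-terminal to the named residue, so "site 225" splits a 418-residue chain
into 1–225 and 226–418 (lengths 225/193).  Fragment sets tile the parent
exactly; each fragment's mass is the sum of standard residue masses plus
one water (average and monoisotopic tables embedded as versioned data and
cross-checked against pyteomics), so a digest with c cuts gains exactly
c·18.01528 Da (average) over the parent.  The Propep1 product logic cuts at
Arg69 at low calcium and additionally at Arg6/Arg7 at high calcium, firing
only when the residue actually is Lys/Arg — an R6A/R7A mutant keeps only
the Arg69 cut.  The bundled 418- and 92-residue sequences are synthetic
stand-ins (inert backbone with the catalytically relevant residues at their
published positions); only the residue classes at named positions matter to
any computation here.

## Geometry checks

Coordinate models are read from PDB format (via gemmi) with alt-locs
resolved to the highest-occupancy conformer (ties → 'A').  The checker
counts polymer chains (≥ 20 amino-acid residues), measures atom–atom
distances, lists missing-residue gaps inside a chain's observed span, and
reports all sensible catalytic-dyad candidates (His NE2/ND1, nucleophile
SG — or CB in a Cys→Ala mutant) against the scissile residue's carbonyl
carbon, because the exact atom pair behind a quoted dyad distance is
usually not stated.  mmCIF is out of scope.

## Numerical choices and degenerate inputs

* Resolution shells use a 1e−9 relative slack at the sphere boundary so a
  reflection sitting exactly on d_min lands on the same side for the
  simulation, the merge and the completeness denominator.
* Ties in ASU mapping cannot occur (lexicographic max is unique); ties in
  clustering follow crystal-id order; rank ties fall back to group id.
* Empty shells, single-observation uniques, and insufficient Friedel pairs
  yield NaN statistics, never fabricated zeros.
* All-rejected clusterings, disconnected scaling graphs, undefined
  objectives and empty selections raise with diagnostics instead of
  returning partial results.

## Known limitations

* The greedy leave-one-out search is locally optimal per sweep; it does not
  revisit removals or search subsets jointly.
* CC1/2 as ranking objective is a data-quality proxy; it cannot see model
  phases, so it may rank groups differently from a refinement-based
  arbiter.
* The generator's angular-inclusion model has no orientation correlation
  between equivalents; real wedges observe correlated regions of
  reciprocal space, so real per-crystal completeness is lumpier than
  simulated.
* Scaling assumes isotropic B and no radiation-damage time dependence
  within a wedge.
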