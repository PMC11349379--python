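# Methods

`trainxl` implements the computational validation workflow used for
multi-copy polymeric assemblies of the intraflagellar-transport (IFT)
machinery: mapping in-situ cross-linking mass-spectrometry restraints onto
assembly models, comparing two conformational states of the same polymer
(the compact anterograde-like and extended retrograde-like train forms),
and desk-scale integrative rigid-body fitting into low-resolution density.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Cross-link distance validation

A residue-pair cross-link is a pair of (protein, author residue number)
endpoints.  On a polymer each protein exists in several copies, so an
endpoint resolves to the set of Cα sites of every copy carrying that
residue; the reported distance is the **minimum Cα–Cα distance over all
copy pairs** — the most permissive structurally consistent assignment,
matching how cross-links are conventionally assigned on multi-copy
assemblies ("best resolved between residues in the same copy" is the
special case where the intra-copy pair wins).  When both endpoints name
the same residue of the same protein, the pairing of a site with itself is
excluded, so self-links across copies report the inter-copy distance.

Classification is strict: a link is *satisfied* iff d < threshold.  The
default threshold is **35 Å**, the accepted maximum Cα–Cα span for the
DSSO lysine–lysine linker; a link at exactly 35.0 Å counts as violated.
Links whose endpoints cannot be resolved (unmodeled residues, proteins
absent from the chain map) are *unmapped* — they are excluded from
histograms and satisfaction fractions and reported separately, mirroring
the "not modeled" class of cross-link diagrams.

**Flexibility rescue.**  A violated link can be explained by local
disorder: if an endpoint residue of the minimizing chain pair — or any
residue within `rescue_window` positions of it on the same chain — has
per-residue confidence (pLDDT, carried in the B-factor column and averaged
over the residue's atoms) below the cutoff (default **50**), the link is
flagged as rescued, with the flexible residue named.  The window defaults
to 0 (endpoint only) because the underlying rule is stated per flexible
region without a numeric window; widening it is a CLI flag.  Rescue is
metadata: rescued links remain classified as violated.

Two-state comparison maps one cross-link table onto both models with
their own chain maps and reports (d_A, d_B, Δ = d_B − d_A) per link, with
links unmapped in either state flagged.

## Surface accessibility and state-specific burial

Per-residue SASA is computed in full-assembly context with a
Shrake–Rupley construction: a deterministic Fibonacci lattice (default
**960 points**) on each atom's solvent-expanded sphere (probe **1.4 Å**),
with points occluded by any neighbouring expanded sphere removed.  The
implementation is exact in the many-point limit and deterministic for a
fixed point count; it is validated against the closed-form spherical-cap
area for two spheres in contact (≤2% error) and cross-checked against an
independent Shrake–Rupley implementation.

Relative accessibility divides by a reference maximum: Tien-style
theoretical maxima for the twenty standard residues, and the residue's own
isolated-state SASA for anything else (coarse-grained bead residues
included) — the latter makes relative accessibility an exposure fraction.
Reported values are capped at 1.2.

The **burial differential** assigns a residue (matched across states by
protein, copy and author number) to the accessible-in-A set iff its
relative accessibility is ≥ `accessible_cutoff` (default **0.25**) in
state A and < `buried_cutoff` (default **0.10**) in state B, and
conversely.  The construction is exactly antisymmetric under state swap
and the two sets are disjoint by definition.  Both cutoffs are config
keys: the source analysis states no numeric values, so these follow
common relative-accessibility conventions.  Single-linkage clustering by
minimal inter-residue heavy-atom distance (default cutoff 6 Å) groups a
differential set into surface patches.

Polymer metrics: the principal axis is the first principal component of
the Cα coordinates (depositions carry no axis annotation); the repeat
length is the mean spacing of IFTA1-subcomplex chain centroids projected
on that axis; stoichiometry counts IFTB subcomplex instances against IFTA
instances (2.0 for the canonical one-IFTA + two-IFTB repeating unit).
The repeat-unit contact graph declares two units adjacent when any
inter-unit heavy-atom pair is closer than the contact cutoff (default
5 Å).  Units are supplied as an explicit chain→unit mapping because copy
indices are per-protein and therefore ambiguous as unit labels when a
protein appears twice per unit.

## Rigid-body fitting

**Density simulation.**  A model is rendered as a sum of per-atom
isotropic Gaussians with σ = resolution / (2·√(2·ln 2)) (FWHM
convention), truncated at 3σ, sampled separably on the grid.  Every atom
carries the same weight, so the integral is proportional to atom count;
translating a model by exactly one voxel shifts the rendered density by
exactly one voxel.

**Scoring.**  The EM term of a placement is the normalized
cross-correlation between the rendered density of the posed body and the
target map over the body's own support (voxels where the rendered density
exceeds 10% of its maximum — restricting to the footprint keeps
neighbouring bodies' density from diluting the score).  A multi-body
configuration is scored as a weighted sum with defaults **connectivity 1,
cross-link 30, discrete 10000, excluded volume 10, EM 1000**:

- EM = 1 − mean per-body correlation;
- cross-link = Σ max(0, d − threshold)² (flat-bottom quadratic, d the
  min-over-copies Cα–Cα distance in the posed configuration);
- excluded volume = count of inter-body atom pairs closer than 3 Å;
- connectivity = Σ max(0, gap − max_gap)² over declared chain
  continuations;
- discrete = count of declared required contacts not realized.

The named restraints' functional forms are not published; the flat-bottom
quadratic, overlap count and 1 − correlation are the simplest forms
consistent with their names and are kept behind one function.

**Fit libraries.**  `n_positions` placements (default **80,000**; tests
and the acceptance script use 5,000, a problem size chosen for the small
synthetic bodies) are drawn from a deterministic Halton sequence —
rotations quasi-uniform over SO(3) via the Shoemake map, translations
drawn from map-support voxels with probability proportional to density
(a body's centroid must sit in occupied density, so uniform box sampling
wastes nearly all placements).  Placements keeping less than the
`inside_threshold` fraction (default **0.3**) of atoms inside the map
support, or falling outside the search `radius` (default **200 Å**), are
discarded.  Because the probability of sampling a pose within a few
degrees of an optimum is vanishing, the search is two-tier: every
placement is screened with a cheap overlap objective (mean map density at
the atom positions); ~100 spatially and orientationally diverse survivors
are locally optimized under that objective (Powell); the results are
re-scored with the full correlation, greedily clustered at the
(**4°, 3 Å**) tolerances in score order, and the leading clusters are
polished against the correlation.  Clusters are ranked by best member
score.  On planted single-body problems the top exemplar lands well
inside the cluster tolerance.

**Simulated annealing.**  Metropolis Monte-Carlo over the per-body
libraries with the six-stage schedule **75000/1000, 30000/800, 10000/800,
5000/500, 1000/500, 300/300** (temperature/steps).  Moves re-pose one
body, by default to a library exemplar (rank-biased: half the proposals
come from the body's ten best clusters, the rest uniformly from the whole
library, which keeps the chain ergodic over the full discrete space);
optional local perturbation moves are available.  The schedule's
temperatures are unitless scores from the optimization protocol they
describe; their absolute magnitude presumes that protocol's score scale,
and applied literally to this package's bounded terms every move would be
accepted and the annealer would degenerate into unbiased sampling.  What
transfers is the cooling *profile*, so the package keeps the printed
ratios and step counts and calibrates the absolute scale per problem to
the score spread of random configurations (first stage ≈ free exploration,
last stage ≈ 250× colder, near-greedy); the scale is overridable.  After
the schedule a zero-temperature quench hill-climbs from the best-seen
configuration over each body's leading exemplars.  Both the chain and the
quench stay inside the discrete exemplar space, so an exhaustive
enumeration over the exemplar product is a hard lower bound on the
achievable score — a property the test suite asserts.  Runs are
bit-reproducible given the seed.

**Convergence diagnostic.**  Given ≥30 independent run scores, the run
ensemble is called *converged* iff the mean of the best 5% of scores lies
more than 2.5 robust standard deviations (IQR/1.349) below the median of
all scores.  A robust centre/scale and a 2.5σ separation are used because
the expected mean of the lowest 5% of a pure Gaussian sample is already
≈2σ below its mean, so a 2σ criterion on moment estimates misclassifies
the canonical "no good solutions" case the diagnostic exists to detect.
The verdict is invariant under positive rescaling of the scores.

## Synthetic two-state generator

The generator is the test bed's ground truth, not a fixture: it emulates
the study conditions at Cα-bead resolution.

- **State A** (compact, anterograde-like): two stacked rows of compact
  pseudo-domains with repeat distances **115 Å** (IFTA row) and **65 Å**
  (IFTB row).
- **State B** (extended, retrograde-like): repeating units of one IFTA
  complex plus two IFTB complexes (**2:1 IFTB:IFTA**) spaced
  **225 Å** apart — a **450 Å visible repeat** spanning a configurable
  number of units (default 2, exposed as `units_per_visible_repeat`
  because whether the visible repeat spans one or two symmetry-related
  units is a modelling choice, not a constant).  Consecutive units
  alternate orientation by a 180° rotation about an axis perpendicular to
  the polymer axis, so the noise-free lattice has an exact C2 operator
  (for even unit counts; the RMSD under the operator is checked in
  tests).  A central thread overhangs each unit cell so consecutive units
  interlock, and peripheral arms bridge second neighbours: an interior
  unit touches four surrounding units, reproducing the contact topology
  of the extended train.
- Chains, protein identities and residue numbering are identical between
  states; the conformational change is purely coordinates, mirroring how
  deposited states of the same complexes are compared.
- Pseudo-domains are Cα-only bead threads and reflected random-walk
  coils (step 3.8–4 Å).  No sequences, side chains, membrane or
  microtubule geometry are modelled, so passing tests demonstrate the
  pipeline's bookkeeping and numerics, not chemical realism — real data
  add side-chain geometry, missing residues and identification noise that
  these tests do not probe.

**Planted cross-links** are constructed, not sampled: candidate residue
pairs are drawn, their true min-over-copies distances computed in both
states by an exhaustive oracle kept independent of the validation code,
candidates within `margin` (default **5 Å**) of the threshold discarded,
and a subset selected to meet both per-state satisfied fractions exactly
(defaults 0.75 in the compact state, 0.90 in the extended one — most
links satisfied with a handful of outliers, echoing the observed pattern;
48 links, the scale of the IFT cross-link set).  An infeasible
combination of fractions raises with the candidate-pool diagnostic.
Confidence annotations plant one contiguous low-confidence segment
(pLDDT 30) per chain, 15% of residues by default, against a confident
background (pLDDT 90).  Coordinate noise is added only after the truth
table is computed.

**Planted occlusion** builds the ground truth for the burial
differential: the exposed residues on a named face are covered by a
molded blocking pseudo-domain — block beads placed at contact distance
along each selected residue's actually-exposed directions (found with
the same Fibonacci construction the SASA stage uses), the way a docked
binding partner would wrap a surface.  The occluded list is that residue
set; burial is then genuine rather than threshold-dependent.

**Planted fitting cases** build bodies as distinct chiral anisotropic
bead shapes (unequal orthogonal arms, a bent rod with an out-of-plane
hook, a tapered one-handed spiral — shapes with any internal dyad or
mirror make orientation recovery ill-posed at 15–30 Å), packed along an
axis with fixed clearance so each body owns a distinct density region,
then rendered into a map at the requested resolution (default 18 Å,
voxel 4 Å).  Inter-body cross-links are drawn preferentially from bead
pairs far from both body centroids (a link at an arm tip pins
orientation; one near the centroid does not), cycling over body pairs so
every interface is restrained.

## Numerical choices and degenerate inputs

- Distances are exact Euclidean quantities in double precision; oracle
  agreement is asserted with zero tolerance.
- Density grids are float32; the Gaussian splat is separable and
  truncated at 3σ.
- Zero-variance overlap in the correlation (empty or flat support)
  scores 0; an empty fit library is a warning from the library builder
  and an error for the annealer.
- Greedy clustering assigns each pose to the first (best-scoring)
  cluster within tolerance; ties in score preserve sampling order.
- The histogram operation requires at least one mapped link; the burial
  differential requires at least one residue matched across states; the
  convergence diagnostic requires ≥30 scores.
- Multi-model structure files use the first model (logged); decoy rows
  in cross-link tables are dropped; rows with unparseable residue
  numbers are skipped with their row index logged.

## Problem sizes

Tests and the acceptance script run the generator at its default
conditions (4 repeating units, ~900 atoms; 5 units for the contact
graph), fit libraries at 5,000 positions, three-body annealing with the
full six-stage schedule over 10–20 independent seeds, and the two-body
exhaustive oracle over a 25×25 exemplar product.  These sizes are the
package's chosen desk-scale study conditions; the defaults for real use
(80,000 positions) follow the source protocol.

## Known limitations

- Cα-level only: no side-chain (e.g. lysine NZ–NZ) linker geometry; the
  threshold criterion is the conventional Cα–Cα one.
- The EM term uses real-space correlation of Gaussian-rendered density;
  no CTF, no Fourier-space weighting, no map symmetrization.
- Score magnitudes are not comparable across problems (and not to other
  packages' scores); only orderings and the convergence shape are
  meaningful.
- Ambiguous-site cross-links (alternative residue assignments) are
  separate rows by design; the package does not collapse them to a
  minimum.
- The ~70% train-length comparison between states is deliberately left
  to the user: the package exposes raw repeat geometry (extent, repeat
  length, unit count) but does not pick which polymer defines the
  anterograde length.
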