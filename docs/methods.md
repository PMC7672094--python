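# Methods

## 1. Rigid-body jaw model

### Geometry and frames

Each hemimandible is a rigid body in a local right-handed frame: `+x`
anterior along the closed mandibular long axis, `+z` dorsal; for the left
side `+y` is lateral, and the right side is the exact mirror image through
the midsagittal plane.  In the assembly frame the two hemimandibles are
yawed `±ψ0/2` about their hinge points (default ψ0 = 50°, the closed
symphysial angle) so the slender anterior tips meet point-to-point at the
midline — there is no broad symphysis, which is what permits long-axis
rotation in the first place.

The jaw joint is modelled as a **pure revolute hinge** fixed to the upper
jaw.  Its axis is parameterised by two angles, both in degrees:

* `alpha` — angle between the axis and the mandibular long axis
  (default 45°);
* `beta` — ventral dip of the axis below the horizontal plane
  (default 45°).

Two conventions for `alpha` are supported.  Under the default
*horizontal-projection* convention the axis is
`n = (cosβ·cosα, ∓cosβ·sinα, −sinβ)` (upper sign left, lower right) and
`alpha` is the angle between the axis's horizontal projection and the long
axis.  Under the *direct* convention `alpha` is the true 3-D angle; the
pair (45°, 45°) then forces the axis into the hemimandible's sagittal
plane, because `cos²α + sin²β ≤ 1` is required for a real axis — the two
printed angle constraints are mutually incompatible with a mediolaterally
sloping axis read literally, which is why horizontal-projection is the
default.

The **sign of the mediolateral component** is a modelling decision with
anatomical consequences.  Of the four sign combinations, only one both (a)
permits depression beyond ~15° and (b) everts the dentition on opening;
the alternatives either cap the gape far below the observed range or
invert the teeth while the mouth opens.  The package uses that feasible,
everting orientation (mediolateral component directed medially on the
ventrally descending end).

### Gape, roll, symphysial angle

* **Gape θ** is the angle of the (rotated) mandibular long axis below the
  horizontal plane, `θ = asin(−u_z)` — the number a protractor would read
  off a lateral photograph of the physical model.  (An alternative
  convention, the angle of the strict sagittal x–z projection, gives
  smaller hinge rotations; the package standardises on the
  horizontal-plane definition.)
* **Hinge angle φ for a requested gape** has a well-behaved 1-D root:
  `−u_z(χ) = n_y sinχ − n_x n_z (1 − cosχ)` is a single-harmonic sinusoid
  in the hinge angle χ, so the depression rises monotonically from zero to
  a unique maximum along the depressing branch.  The maximiser is obtained
  in closed form from `tanχ* = n_y/(n_x n_z)` and the root is bracketed on
  `[0, χ*]` and solved with Brent's method at `xtol = 1e-14` rad
  (residuals below 1e-9 degrees).  A gape beyond the maximum raises an
  error carrying the achievable maximum (75° for the default axis).
* **Roll τ** is the signed twist of the hinge rotation about the closed
  long axis, from the swing–twist decomposition `R = R_swing ∘ R_twist`
  (twist applied first, in the body frame, because the roll is a
  body-fixed rotation of the hemimandible about its own long axis).
  τ is reported eversion-positive on both sides.  Quaternions are
  canonicalised to `w ≥ 0`, which makes τ invariant under the quaternion
  double cover; the degenerate half-turn exactly perpendicular to the
  reference axis is defined to have zero twist.
* **Symphysial angle ψ** is the *signed* ventral-view angle between the
  left and right long-axis projections, positive when anteriorly
  convergent (closed value ψ0).  Under the default axis the projections
  cross the midline near a 21° gape; the signed angle decreases
  monotonically through zero, whereas an unsigned angle would fold back.
  A negative ψ flags the idealisation's limit: real jaws would meet at the
  symphysis before crossing.

### What the revolute idealisation does and does not predict

With the printed 45°/45° axis the model predicts ≈55° of eversion and a
strongly reduced signed ψ at a 60° gape.  Measurements on a physical
model of the fossil report ≈20° of roll and ψ ≈ 45° at the same gape.
The package deliberately does **not** treat that pairing as a target: the
discrepancy is attributable to joint translation/sliding at the sigmoid
articular surfaces, compliance of the physical printout, or a different
operational gape measurement — none of which a single fixed revolute axis
represents.  The supported workflow is *calibration*: fit (α, β) to any
measured roll-vs-gape table and report the residual.

### Axis calibration and its identifiability limit

`fit_axis_to_roll_curve` minimises Σ(τ_model − τ_obs)² by bounded least
squares (multi-start: a deterministic coarse grid plus seeded jitter;
infeasible gapes are given a graded penalty so the optimiser retreats from
axes whose maximum depression falls short of the data).  On noiseless
synthetic curves both angles are recovered to < 0.1°.

The forward map (α, β) → roll curve is, however, *sloppy*: a ridge of
axes (e.g. α = 48°, β = 21°) reproduces the default 45°/45° curve to
≈0.3° RMS over gapes 0–60°, and the ridge persists even with observations
near the feasibility limit.  With 0.5°-SD observation noise the fitted β
therefore wanders tens of degrees along the ridge while α stays within a
few degrees, and the fitted *curve* matches the true one within the noise
scale.  Calibration against roll data alone should be read as recovering
the functional roll response and α, not a point estimate of β; pinning β
would need an additional observable (e.g. the symphysial-angle trace).

### Dentition kinematics

Teeth are carried at perpendicular radii `r_i` from the long axis, graded
so the labial (older) teeth of a family sit at larger radii than their
lingual (younger) successors.  During roll at rate ω each crown moves at
`v_i = r_i ω` — the labial teeth are strictly faster, the velocity
advantage that snags prey as the dentition sweeps inward on closure — and
a roll increment Δτ displaces each crown along a chord
`d_i = 2 r_i sin(Δτ/2)` of its circle about the long axis.

## 2. Landmark registration

The composite-model step estimates a seven-parameter similarity transform
(uniform scale s > 0, proper rotation R, translation t) between matched,
named landmark sets by the closed-form centroid/SVD construction: rotation
from the SVD of the centred cross-covariance, scale from the projected
variance ratio, translation from the centroids.  Configurations whose
least-squares optimum is a reflection raise an error by default (an
`allow_reflection` flag accepts the best proper rotation instead);
collinear landmark sets are rejected as degenerate because the rotation
about their common axis is unconstrained.  RMSD of the aligned points is
always reported.  STL meshes (binary or ASCII) are read and written
through `trimesh`, preceded by a structural validation pass so truncated
binary files fail loudly with a byte offset instead of loading partially.

## 3. Parsimony analysis

### Matrix model

A character matrix stores each cell as a non-empty *state set* over the
declared symbol space (bitmask integers): singleton = observed state,
full set = missing, multi-element = polymorphism.  Both `?` and `-` are
treated as fully missing — the usual convention for morphological
matrices, where a gap has no indel interpretation.  Characters are
unordered with unit (or user-supplied positive integer) weights.
Original 1-based character numbers survive subsetting, so partition
experiments (e.g. neurocranium-only: characters 1–4 and 100–180 of a
230-character matrix → 85 characters) can be expressed in the source
numbering.

### Step counting and fit indices

Tree length is Fitch's intersection/union pass vectorised across
characters, anchored at taxon 0's edge; polymorphic tips contribute their
state set directly, and missing cells never force steps.  Per-character
bounds use unambiguous singleton codings only: `m` = distinct observed
states − 1 (floor 0), `g` = coded taxa − frequency of the commonest
state.  Ensemble indices follow the standard definitions
(CI = Σm/Σs, RI = (Σg−Σs)/(Σg−Σm), RC = CI·RI, exactly) and are reported
both over all characters and over parsimony-informative characters only
(a character is uninformative when m = g), because published values do
not always state which variant they use.

### Search

The ratchet: from each random-addition start (greedy stepwise insertion
in a seeded random taxon order), iterate — upweight a random quarter of
the characters ×2, SPR-swap to a local optimum under the perturbed
weights, restore weights, swap again, accept if no longer than the
incumbent.  Defaults (50 iterations, 4 starts, SPR, archive window 2) are
desk-scale and fully configurable; searches are byte-reproducible from a
single integer seed.  Distinct topologies are compared as strict binary
bipartition sets, so the reported count of equally most-parsimonious
trees follows that convention (tree-collapsing conventions differ between
programs and change such counts).  Every local optimum visited within the
archive window of the best length is retained, which makes near-optimal
("best + k steps") strict consensus trees and decay indices readable from
a single search.  For ≤ 9 taxa an exhaustive enumerator scores every
unrooted binary topology and yields exact versions of all of the above.

### Supports and consensus

* **Bootstrap**: characters resampled with replacement per replicate;
  each replicate analysed with a reduced-effort ratchet; a replicate
  contributes the strict-consensus bipartitions of its best trees;
  frequencies in percent.
* **Bremer decay**: for each consensus clade, a converse-constraint
  ratchet searches among trees *not* displaying the clade (proposals
  containing it are rejected; the start tree is broken away from the
  clade first); B = shortest such length − best length.  An
  archive-based fallback reads the same quantity from the suboptimal-tree
  archive when the constraint search is disabled.
* **Strict consensus** intersects bipartition sets and rebuilds the tree
  from the (automatically compatible) survivors.  **Adams consensus**
  operates on trees rooted at the first outgroup taxon (configurable) and
  recursively partitions the leaf set by the common refinement of the
  root partitions — retaining shared nestings that strict consensus
  destroys when rogue taxa wander.

### Raw values

No multiple-testing correction or support threshold is applied anywhere;
bootstrap percentages and decay indices are reported raw.

## 4. Synthetic data: what it emulates, what it does not

* **Trees**: Yule (pure-birth) topologies with exponential waiting times.
  Branch lengths are either clock-scaled to a total depth or set to a
  constant per-branch expected number of substitutions.  Recovery
  experiments use the constant-length mode (default 0.1) because
  clock-scaled Yule trees routinely contain interior branches with
  essentially zero expected changes — splits that no method can recover
  from finite data, which would measure the tree prior rather than the
  search.
* **Characters**: independent k-state symmetric (Mk) evolution,
  `P(stay | t) = 1/k + (k−1)/k · exp(−k t/(k−1))`; missing cells and
  two-state polymorphisms (among observed states) injected at set rates.
  The desk-scale recovery condition is 12 taxa × 100 characters with 4
  states — multistate characters carry more signal per change, matching
  the mixed binary/multistate composition of real morphological matrices.
  What the simulation does *not* emulate: correlated characters,
  ascertainment toward variable characters, among-character rate
  variation, and non-random missingness concentrated in fossil taxa.
  Passing recovery tests therefore demonstrate the correctness of the
  search machinery under the model's assumptions, not expected
  performance on real matrices.
* **Jaw fixtures**: a watertight tapered-prism hemimandible mesh (the
  slender anterior symphysial tip), nine tooth-family landmarks at radii
  graded labially, closed symphysial angle exactly 50° — a geometric
  stand-in, not an anatomical model.
* **Roll curves**: forward-model τ(θ) plus seeded Gaussian noise; zero
  noise returns the exact forward values (the basis of the calibration
  round-trip tests).

## 5. Numerical and degenerate-case choices

* Angles are radians internally, degrees at every I/O boundary; lengths mm.
* Quaternion equality is tested after `w ≥ 0` canonicalisation.
* Gape root-finding: Brent on an analytically bracketed monotone branch
  (see above); all sweeps deterministic.
* Swing–twist of a half-turn perpendicular to the reference axis: twist
  := identity (the projection of the quaternion onto the axis vanishes).
* Registration rejects collinear sets and reflection-optimal sets rather
  than silently proceeding; scale is read from the rotated projection so
  the reflection check cannot corrupt it.
* An all-invariant matrix has Σs = 0 and CI undefined; this raises an
  explicit error rather than returning NaN.
* Tests and the acceptance script run at desk scale (≤ 12 taxa, ≤ 230
  characters, 945-topology exhaustive baselines at 7 taxa) — sizes at
  which every stochastic result is cross-checked against an exhaustive or
  closed-form oracle.

## 6. Known limitations

* The revolute joint ignores translation at the sigmoid articular
  surfaces; measured roll/ψ pairings from physical models are expected to
  differ (see §1) and are handled by calibration, not assertion.
* Fitch scoring requires strictly binary trees; consensus trees are for
  reporting, not scoring.
* The ratchet at desk-scale effort is not tuned for matrices of hundreds
  of taxa; scale the iteration and start counts for larger problems.
* β from roll-only calibration is ridge-ambiguous at realistic noise
  (§1); report the residual alongside any fitted axis.
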