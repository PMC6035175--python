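# Methods

## Curvature by subunit superposition

The curvature of a protofilament is defined operationally: for consecutive
subunits *i* and *i + 1*, build a Cα residue correspondence, superpose *i*
onto *i + 1*, and take the rotation angle of the optimal rigid transform.
Correspondence is one-to-one by residue order when the two chains have
identical sequences (synthetic filaments, identical tubulin isoforms), and
comes from a global sequence alignment (BLOSUM62, gap open −11, extend −1,
matched pairs only) when the chains are homologous but not identical —
α- and β-tubulin share roughly 40% identity, so a pure residue-number
pairing would misregister them.

Superposition is the weighted Kabsch algorithm: SVD of the weighted
covariance of the centered point sets, with the smallest singular direction
flipped when the determinant would otherwise be negative, so reflections are
never returned. Collinear or coincident point sets (second singular value
numerically zero) are rejected rather than silently resolved. On top of the
single fit sits an iterative trimming loop in the style of
interactive-graphics `align` commands: fit, drop pairs whose residual
exceeds `reject_factor` × current RMSD, refit, up to `max_cycles` times
(defaults 2.0 and 5; `reject_factor = inf` reduces to one plain fit). The
published angle for a real structure depends mildly on the trimming and atom
set used, which no deposition records; both parameters are config-exposed
and the defaults are stated here so reported angles are reproducible.

The rotation angle is recovered from the rotation matrix as
θ = atan2(‖skew(R)‖/2, (tr R − 1)/2), which is algebraically arccos((tr R − 1)/2)
but keeps full precision at small angles; near 180° the axis is taken from
the dominant column of R + I (the skew part vanishes there). The identity
rotation returns a zero axis with an explicit degenerate flag.

### Bend/twist decomposition and the reference axis

The interface rotation is split by an exact quaternion swing–twist
decomposition about a reference axis **a**: the twist factor is the
normalized projection of the rotation quaternion onto **a**, the swing
factor is the remainder, and swing ∘ twist reproduces the input rotation to
machine precision. Bend (swing) and twist magnitudes are each bounded by the
total angle; they do not add linearly.

The default reference axis at each interface is the **local rise
direction** — the unit vector between consecutive subunit Cα centroids.
For a curved filament this is the only axis for which programmed bend and
twist are recovered exactly from the generator (a single global axis mixes
bend into twist as the filament turns); a global least-squares axis through
all subunit centroids (first principal component, oriented minus→plus) is
available as an option for straight-filament conventions. The `rise`
reported per interface is the centroid step projected on this axis; the
screw translation (translation component along the rotation axis itself) is
reported separately, since the two coincide only for pure-twist interfaces.

### Extension and motif displacement

Extended protofilaments are built by computing the rigid transform mapping
dimer 1 onto dimer 2 over their concatenated matched Cα sets and applying
it repeatedly to the last dimer, renaming chains. When the two measured
interfaces of the seed structure differ, no exact joint dimer→dimer
transform exists; the Kabsch fit is then the least-squares compromise, and
the appended copies repeat *that* transform exactly (consecutive appended
dimers are related by precisely the fitted transform — the property the
tests assert). For a uniformly curved filament the construction is exact.

Motif comparisons superpose structure B onto A over a frame selection that
must exclude the motif (the caller controls both selections), then measure
per-residue Cα displacement over the motif without refitting; the RMSD and
maximum displacement are reported with the frame RMSD alongside. Helix-group
rotation uses the same frame superposition and then reports the rotation
angle of the best rigid transform between the two frame-aligned helix Cα
sets.

## Solvent accessibility and interfaces

SASA is Shrake–Rupley dot sampling: each atom's van der Waals sphere is
expanded by the probe radius (default 1.4 Å, water), covered with a
deterministic golden-section spiral of `n_points` dots (default 960), and a
dot counts as accessible iff it lies outside every other expanded sphere
(neighbor search via a k-d tree). The radius table is a single Bondi-style
element table (C 1.70, N 1.55, O 1.52, S 1.80 Å, …) with a carbon fallback
plus warning for unknown elements; hydrogens are ignored throughout and
waters never enter a selection. A 960-dot sphere reproduces the analytic
isolated-sphere area to well under 1%, and doubling the dot count moves
cluster totals by <0.5%.

Interface burial is ΔSASA = SASA(A) + SASA(B) − SASA(A∪B), computed over
heavy atoms; both ΔSASA and the one-interface convention ΔSASA/2 are
reported, because published "buried surface area" figures use either
convention and rarely say which. Contacts are purely distance-geometric:
heavy-atom pairs within a cutoff (default 4.0 Å), classified as salt-bridge
candidates (basic-residue N vs acidic-residue O ≤ 4.0 Å), hydrogen-bond
candidates (N/O vs N/O ≤ 3.5 Å) or plain contacts. No angular criteria are
applied — at the ~3.5 Å resolutions typical of these complexes, distance
geometry is all the coordinates support.

## SAXS

Theoretical intensities use the Debye double sum
I(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sin(qr)/(qr), with the q → 0 limit handled by the
sinc form. Three scatterer models: `point` (constant f = electron count,
used by the analytic tests), `atomic` (Cromer–Mann Gaussian-sum form
factors minus a Gaussian excluded-solvent dummy term at bulk density
0.334 e/Å³ with Fraser-type displaced volumes), and `residue` (one bead per
residue at the residue centroid, f = residue electron count). The sum is
O(N²), so `auto` mode switches from atomic to residue-level coarse graining
above 10,000 atoms; the mode used is recorded in pipeline output. No
hydration-shell layer is modeled: χ² values against experiment therefore
carry a model-dependence of order the shell contrast, and the pipeline
treats them with corresponding tolerance.

Guinier analysis fits ln I against q² over the largest low-q window
satisfying q·Rg ≤ 1.3 (config-exposed), found self-consistently by
fit-shrink-refit; a nonnegative slope raises "no Guinier region" rather
than returning a complex Rg. The direct-space Rg (electron-weighted second
moment) and the Guinier Rg of a profile computed from the same coordinates
agree within 1% for compact particles when fitted to q·Rg ≤ 1.0.

P(r) from coordinates is the electron-weighted pair-distance histogram
(dmax = maximum pair distance, density normalized to unit integral). From a
measured profile it is a regularized indirect transform: nonnegative least
squares on I(q) = ∫ p(r) sinc(qr) dr with a second-difference smoothness
penalty, endpoints pinned to zero. The penalty weight is auto-scaled to the
data (Frobenius-norm ratio of the design and penalty blocks) and chosen as
the smoothest solution whose χ² stays within a factor 2 of the best over a
log-spaced scan — an L-curve compromise. Dmax is selected from a candidate
grid as the **smallest** support whose score (fit χ² inflated by any
probability mass piled against the endpoint) is within 10% of the best:
over-large supports fit equally well with an empty tail, so without the
compactness preference the search drifts upward. On profiles synthesized
from uniform-density particles the recovered Dmax is within a few percent
of the true maximum extent; for particles whose pair-distance density
decays gradually (Gaussian clouds), the extreme pair distance is physically
invisible to any indirect transform and the recovered Dmax reflects the
bulk of the density instead.

Model-vs-experiment agreement is χ² = (1/(N−1)) Σ ((c·I_calc + b − I_exp)/σ)²
with scale c and constant offset b solved in closed form by weighted least
squares. The pipeline evaluates the Debye curve directly on the
experimental q-grid, so no interpolation error enters the statistic.

## Synthetic ground truth

The generator builds filaments of rigid copies of one pseudo-subunit: three
mutually skew helical arcs of Cα pseudo-atoms (element carbon), chiral and
with distinct principal moments of inertia so superposition is
well-conditioned and cannot lock onto a mirror image. Subunit *i + 1* is
subunit *i* rotated about its own centroid by twist (about the current
filament axis) then bend (about a perpendicular axis carried along with the
frame), then stepped by the rise along the current axis — so the local
centroid-step direction equals the decomposition axis and the analyzer must
recover the programmed values exactly in the noise-free case (< 10⁻⁶°,
asserted). Gaussian coordinate noise is applied after placement, modeling
coordinate uncertainty rather than conformational change, from a stream
seeded by the spec's single integer seed; every fixture is bitwise
reproducible. Default geometry: 42 Å rise (the tubulin monomer repeat),
4 subunits (two dimers, as in the crystallized complex), 120 atoms per
subunit.

Under 0.2 Å coordinate noise the *bend* component is recovered essentially
without bias (mean error < 0.01° over 100 seeds; the tests assert < 0.1°),
while the *total* angle acquires a small positive bias (~0.1–0.3°) because
it is a nonnegative magnitude and noise can only add apparent rotation —
one reason the bend/twist split is reported alongside the total.

What the generator does not emulate: real tubulin folds, side chains,
sequence homology between distinct subunit types, conformational
flexibility, and crystallographic artifacts. Passing parameter-recovery
tests therefore demonstrates correctness of the geometry pipeline, not the
biological interpretation of any particular measured angle.

## Numerical and design choices

* Altlocs collapse to the highest-occupancy conformer (ties → altloc 'A');
  geometry needs one position per atom.
* Author residue numbering is preserved verbatim; motif definitions are
  config-supplied residue ranges.
* The PDB writer emits fixed-column v3.3 records (coordinates exact to
  0.001 Å, the format's precision) and rejects |x| ≥ 10⁴ Å.
* The headline curvature number is the total rotation angle of the
  superposition transform, matching the convention of the interactive
  rotation-axis tools used in the field; bend/twist are supplementary.
* Reports round angles to 0.1°, areas to 1 Å², RMSDs to 0.01 Å in
  human-readable output; JSON carries full precision.
* Acceptance and test problem sizes (subunits of 100–250 pseudo-atoms,
  filaments of 4–6 subunits, 100-seed noise ensembles, 140-point SAXS
  profiles) are chosen so the whole suite completes in seconds while every
  statistical assertion still has comfortable margin.

## Known limitations

* No flexible or structure-based alignment: correspondence is sequence
  alignment only, so very remote homologs or circular permutants are out of
  scope.
* No hydration shell or explicit-solvent term in the Debye model; χ²
  against experimental data is comparable across models but not identical
  to shell-modeling programs.
* Contact classification is candidate-level distance geometry, not
  energetics.
* No lattice (multi-protofilament) modeling, no symmetry expansion, no
  density-map comparison.
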