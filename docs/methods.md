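# Methods

`oxisense` simulates multi-electrode bioimpedance monitoring of an ECMO
oxygenator and asks whether a shallow neural classifier can flag a forming
thrombus from changes in a frame of four-point voltage measurements.  This
note records the model, its assumptions, the parameters that matter, and the
design choices made where the design was genuinely open.

## Physical model

The oxygenator interior is a rectangular box of 9 x 9 x 5 cm (origin at the
centre, z vertical).  Blood fills the box at a single-frequency conductivity
sigma_blood = 0.662 S/m; clots are spheres at sigma_clot = 0.0662 S/m (one
tenth of blood, the optimistic end of the reported blood/clot contrast); a
separation grid of cylindrical polycarbonate rods (diameter 0.4 cm,
sigma = 1e-6 S/m) spans the mid-height plane.  Individual gas-exchange
fibres are not modelled, and the conduction problem is purely real-valued
(no frequency-dependent impedance spectroscopy).

The default separation grid is a 5 + 5 orthogonal rod lattice at 18 mm
spacing.  The real module's rod count is not public; the lattice spacing is
a config parameter and the rods only need to reproduce the qualitative
effect of a non-conductive obstruction at mid-height.

### Discretisation

The box is meshed by splitting structured hexahedral cells into five
tetrahedra with checkerboard parity.  This conserves the box volume exactly,
keeps meshing deterministic, and — for even in-plane cell counts — makes the
mesh invariant under the 90-degree rotations and reflections of the square
cross-section, so the discrete solution inherits the continuum symmetries to
machine precision.  `max_h` is the cell edge length: 2 mm reproduces the
full-study scale (~2.5e5 elements); 5 mm (~1.6e4 elements) is the desk-scale
replication surface; 1 cm (~2e3 elements) drives the smoke fixtures.
Elements are labelled by region (background / separation grid / target)
through centroid tests, so a "grid" element is simply a tetrahedron whose
centroid falls inside a rod.

### Electrodes and the forward problem

Sixteen electrodes sit on the top and bottom planes, one per 45-degree
spoke, each parameterised by a single radial distance — a search
space, which both respects the device's construction and collapses the
placement problem to 16 scalars.  The forward problem uses the complete
electrode model: circular contact patches (radius 4 mm) built from boundary
faces, a contact impedance z_c, electrode-wise current conservation, and
P1 tetrahedral elements.  Four-point measurements (disjoint inject and
measure pairs) suppress the contact-impedance drop at the measuring pair.

z_c defaults to 0.01 Ohm m^2.  With much smaller values the electrode
patches shunt more current than the bulk carries, which distorts
measurements without changing any conclusion drawn from relative voltage
differences; all selection metrics and the classifier input are ratios and
are insensitive to the nominal value.

The singular constant mode is removed by pinning one node with a diagonal
penalty.  Because every right-hand side injects zero net current (it is
orthogonal to the constant nullspace), the pin is exact, not approximate;
solutions are afterwards shifted to a zero-mean nodal gauge.  This keeps the
sparse LU factorization fill-in low, and one factorization per conductivity
field is reused for all injection and adjoint solves (batched right-hand
sides).

Sensitivities use the adjoint identity: the derivative of a four-point
voltage with respect to one element's conductivity equals minus the volume
integral of grad(u_inject) . grad(u_measure), with u_measure the field
driven through the measuring pair.  The Jacobian J (one row per measurement,
one column per element, V per S/m per unit ampere) is verified against
central finite differences in the test suite (< 1e-3 relative on a
1,600-element mesh; observed ~1e-6).

Injected current is 1 A nominal.  All downstream quantities — relative
voltage differences dVr[i] = (v_inh[i] - v_hom[i]) / v_hom[i], selection
scores, figures of merit — are amplitude-invariant.

## Measurement-pattern selection

Candidate four-point measurements are built from an electrode-pair ruleset
defined on (plane, spoke) labels, so a selected pattern transfers between
arrays that share the slot structure.  The default ruleset takes all 28
intra-plane pairs per plane plus inter-plane pairs between spoke-aligned and
spoke-adjacent electrodes (80 pairs); every unordered combination of two
disjoint pairs yields one candidate, which removes reciprocity twins by
construction (~2.5e3 candidates).  The exact enumeration behind the original study's
1,560 candidates is not recoverable and is explicitly out of scope; the
ruleset is config-switchable including an all-pairs mode.

Three criteria pick the 208-measurement frame from the candidates'
sensitivity rows: 144 by greedy Gram-determinant (parallelotope-volume)
maximization — each step adds the candidate with the largest orthogonal
component relative to the span of the current selection, a rank-one update
of det(J J^T) — then the top 32 by L1 row norm and top 32 by L2 row norm
among the remainder, ties breaking on the lowest candidate index.  Exhaustive
subset search at 144-of-2500 is combinatorially impossible; on exhaustively
enumerable instances the greedy volume ranks in the top decile of all
subsets (tested).  The L1 score uses absolute values (without them it is not
a norm), and the volume criterion is used as the squared volume
det(J J^T) — monotone-equivalent for ranking.

Candidates whose homogeneous reference voltage is essentially zero are
excluded before selection (relative floor 1e-6 of the median |v|).  For
symmetric arrays some four-point combinations are exactly null by symmetry;
they carry no usable dVr (the normalisation divides by v_hom) and would be
discarded by any practical system.  For this reason the selection mesh uses
even cell counts, so that continuum symmetry nulls are exact at selection
time too.

Pattern design runs once on a coarse mesh (max_h 9 mm) with a reference
array placed near the plane edges (90% of each spoke's maximal radius),
mirroring the decoupling of pattern design from electrode placement.

## Thrombus placement

Clots form preferentially where flow stagnates: near walls and corners.
The flow field is approximated by a centred trivariate Gaussian with
standard deviations (0.045, 0.045, 0.025) m — half the box dimensions — and
the thrombus likelihood is its exact reciprocal,

    L(x,y,z) = sx sy sz (2 pi)^{3/2} exp( x^2/(2 sx^2) + y^2/(2 sy^2)
                                          + z^2/(2 sz^2) ),

smallest at the core and largest in the corners (corner/centre ratio
exp(3/2)).  The field is voxelised (2 mm default) and normalised; scenario
targets are drawn by percentile of the voxel-value CDF.  Because the
isosurfaces are ellipsoids, many voxels share one CDF value; the sampler
draws uniformly among the voxels within a 0.5% relative band of the
percentile's likelihood.  Training scenarios use 12 sets of 6 targets with
percentiles spread equidistantly from 5 to 98, covering core to corner; the
sets' target diameter defaults to 1 cm (the original study does not state diameters for
these sets; matching the detection grid keeps one contrast scale).

The detection grid is a regular lattice of 1-cm spheres held strictly inside
the box; the default 4.2 mm spacing yields 4,000 centres, matching the scale
of the published 3,971-target grid (the exact lattice is unstated).

This Gaussian stand-in is empirical: it reproduces the rim-heavy placement
statistics reported for real oxygenators but none of the local flow
structure a CFD model would give.

## Electrode-array optimization

Each random array (per-spoke radii drawn from N(mu, sigma), default
mu = 30 mm, sigma = 12 mm, out-of-range draws rejected and re-sampled) is
scored by three scale-free figures of merit over the fixed 208-measurement
frame: median/min of the L1 row norms of J; the singular-value condition
number of J; and median/min of pooled |dVr| over the 12 scenario sets.  All
three have an ideal value of 1 ("perfectly homogeneous measurement
quality").  Arrays are deduplicated under the rule that at least two
electrodes must differ in position.

A shallow regression net (3 -> 254 -> 203 -> 48, leaky ReLU slope 0.01)
learns features -> flattened electrode coordinates by momentum SGD
(lr 1e-3 decaying x0.95 every 10 epochs, momentum 0.9, L2 1e-6, 200
epochs, 80/10/10 split).  Inputs are min-max scaled on the training split
and targets standardised; both transforms are stored with the model, and the
ideal query [1, 1, 1] passes through the same scaler.  Raw ratio features
span orders of magnitude (the condition number alone reaches O(10^2-10^3)),
which destabilises constant-step SGD — the same reason the original
workflow scaled its inputs.  Querying the trained net at the ideal features
and snapping the output to the admissible slots (nearest (plane, spoke,
clamped radius); a contested slot goes to the nearer electrode, the other
moves to its nearest free slot) proposes an optimized array.  An optional,
explicit symmetrization averages the proposal's radii per plane — the
counterpart of the published manual adjustment — and is never applied
silently.

The canonical optimized array used by the detection study is the fully
symmetric near-wall array (radius 40 mm on every spoke): the symmetrization
output at the radius where electrodes approach the high-likelihood rim while
all 16 slots remain admissible.

## Thrombus detection

Deployment logic: the first frame after priming is the homogeneous
reference; later frames are normalised to dVr against it.  The simulated
dataset is balanced:

* positives — one grid target per simulation, clot conductivity jittered by
  N(0, sigma_clot / 10) (truncated at 1e-4 S/m);
* negatives — clot-free background with per-element jitter
  N(0, sigma_blood / 100), i.e. a spatially independent 1% conductivity
  texture.

Both receive additive white Gaussian frame noise at 15 dB power SNR,
implemented exactly per frame: the noise vector is scaled so
||signal||^2 / ||noise||^2 = 10^{SNR/10}.  The SNR definition (on dVr rather
than raw voltages, per frame rather than in expectation) is a design
reading; defining it on raw voltages would make the noise enormous relative
to the differential signal and is not compatible with the reported
detectability.

The classifier is a 208 -> 200 -> 100 -> 2 ReLU softmax net trained with the
same optimizer family (momentum SGD, lr 1e-3, L2 1e-6, batch 32, 200
epochs) on standardised inputs, with an 80/10/10 stratified split.
Evaluation reports the confusion matrix, sensitivity, precision, F1,
accuracy and the false-positive fraction of all test cases, with
thrombus-present as the positive class.

## Desk-scale replication and problem sizes

The published study ran 7,942 simulations on a 373k-element mesh; this
package's replication surface is deliberately scaled down: a 5 mm mesh
(16,200 elements, 3,971 nodes), 800 positives + 800 negatives, pattern
selection on a 9 mm mesh.  `run_detection_experiment` executes this end to
end in a few minutes on one CPU, and `scripts/acceptance.py` recomputes the
held-out test metrics from scratch.  On these conditions the classifier
reaches test F1 / sensitivity / precision of 100% with 0% false positives
(seeded runs; the published full-scale figures are >94% / >92% / >97% with
1.3% false positives).  The coarser mesh smooths small-scale sensitivity
structure, and the 1-cm clot contrast at one-tenth conductivity is strong
relative to the 1% background texture, so near-perfect separation at desk
scale is expected rather than suspicious; mesh-resolution limits would first
appear as missed central (low-sensitivity) clots.

## Numerical choices and degenerate inputs

* dVr normalisation fails loudly when a reference voltage falls below
  1e-12 V (degenerate measurement) rather than amplifying noise silently.
* Spherical targets must capture at least one element centroid; smaller
  spheres raise an explicit sub-resolution error.
* Rejection sampling of radii caps at 1e4 attempts per electrode before
  raising (infeasible mean/sd combinations).
* Greedy selection tie-breaks and top-k sorts are stable (lowest candidate
  index), making pattern selection fully deterministic.
* Training raises a divergence error on non-finite loss with the offending
  hyperparameters in the message; every stochastic stage takes an explicit
  seed and reruns bit-identically.

## Known limitations

* The likelihood field is an empirical stand-in for flow, and thrombus
  morphology is spherical with a single global conductivity per clot.
* Passing the desk-scale detection test demonstrates the pipeline's
  behaviour under the stated simulation conditions — an idealised contrast,
  white frame noise and a clean reference frame — not clinical performance;
  hematocrit, flow, temperature and electrode drift are outside the model.
* One published qualitative statistic does not transfer to this
  re-implementation: the correlation between the J-homogeneity ratio
  median(J)/min(J) and max(J) is consistently positive here (arrays with a
  hyper-sensitive measurement near clustered electrodes also tend to have a
  starved one), whereas the original study reports it strongly negative.
  The remaining reported correlation signs reproduce.  The statistic depends
  on the candidate enumeration, mesh resolution and array population, none
  of which are fully recoverable.
* The classifier detects presence only; localisation and sizing are
  out of scope.
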