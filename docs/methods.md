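# Methods

## The physical model

`ceikit` simulates and analyzes *complete* Coulomb explosion imaging (CEI):
a molecule is multiply ionized essentially instantaneously, every atom
becomes a singly (or multiply) charged cation, and the mutual Coulomb
repulsion drives the fragments apart.  When all fragments of one molecule
are detected in coincidence, the set of asymptotic momentum vectors
{p_i} is a per-event fingerprint of the molecular structure at the instant
of ionization.

The simulator makes three assumptions, stated explicitly because everything
downstream inherits them:

1. **Vertical ionization.**  Charges appear instantaneously at the neutral
   equilibrium positions (plus sampling spread); there is no charge buildup
   dynamics and no laser-field interaction.
2. **Purely Coulombic forces.**  After ionization the only interaction is
   the pairwise point-charge repulsion k·q_i·q_j/r_ij with
   k = e²/(4πε₀) = 14.399645 eV·Å.  Chemical bonding is neglected; this is
   accurate for high charge states, where Coulomb repulsion dominates, and
   is known to reproduce angular correlations well while overestimating
   momentum magnitudes.
3. **Complete atomization.**  Every atom leaves as an atomic cation with no
   internal energy; the fragmentation channel is an input (per-atom integer
   charges), not a prediction.

Newton's equations m_i·r̈_i = Σ_{j≠i} k q_i q_j (r_i − r_j)/r_ij³ are
integrated in Hartree atomic units with an adaptive 8th-order Runge–Kutta
scheme (DOP853), relative tolerance 1e-8 by default.  Integration stops when
the remaining potential energy falls below `termination_fraction` (default
1e-4) of the conserved total energy; the resulting momentum-magnitude bias
is below 5e-5 relative — far under the sampling broadening — and no
analytic far-field extrapolation is applied.  Energy is conserved to better
than 1e-6 relative at tolerance 1e-9 (tested per trajectory), and momentum
to ~1e-13 a.u.

## Initial-condition ensemble

Each simulated event draws an initial condition that emulates the spread of
a real measured ensemble (zero-point and thermal motion, nuclear motion
during the pulse, multiple cationic surfaces), lumped into two parameters:

- **Positional spread σ** (default 0.25 Å): every atom is displaced from
  equilibrium by an isotropic Gaussian.  By default σ is interpreted as the
  RMS *total* displacement of an atom (each Cartesian component has SD
  σ/√3, `sigma_mode="radial"`).  The per-component interpretation
  (`sigma_mode="component"`, RMS total displacement σ√3) is also available.
  We default to the radial reading because it reproduces the clean
  separation of the cis/trans Cl⁺–Cl⁺ angle distributions that complete CEI
  measurements of dichloroethylene show: under the component reading the
  broadened tails of the two isomers' θ₅₆ distributions overlap, under the
  radial reading they are separated by a ~20° gap at 2000 events per class.
- **Total kinetic energy E_kin** (default 0.5 eV): per-atom energy fractions
  are drawn from a flat Dirichlet simplex with isotropic velocity
  directions; the center-of-mass momentum is removed and the speeds are
  rescaled so the event's total kinetic energy equals E_kin exactly.  This
  is the simplest reading of "randomly partitioned" that leaves the total
  exact and the net momentum zero (a prerequisite for the
  momentum-conservation gate).

The broadened variant (σ = 0.5 Å, E_kin = 3 eV) emulates photoexcited
product geometries with large internal energy.  Default ensemble size is
20,000 events; the bundled analyses use 2,000 per class, which is already
deep into the regime where the embeddings and rankings are stable.

**What the generator does not model:** detector acceptance and momentum
resolution, ToF reconstruction errors, multi-hit dead time, non-Coulombic
forces, and charge-state distributions.  Passing tests therefore demonstrate
the *method* (frames, descriptors, gating, embedding, ranking, transfer) on
physically structured data, not detector-limited performance on real data.
One concrete consequence is documented below (feature-ranking ties).

## Geometries

Bundled fixtures (cis-, trans-, twisted-1,2-dichloroethylene, 1,1-DCE,
isoxazole) are idealized structures from standard bond lengths and angles
(C=C 1.33 Å, C–Cl 1.73 Å, C–H 1.08 Å, sp² angles; regular-pentagon ring for
isoxazole); the twisted structure is the cis geometry with one CHCl group
rotated 90° about the C=C axis (the torsional midpoint).  Cl carries the
³⁵Cl isotopic mass, matching the ³⁵Cl⁺ coincidence channel.  The analysis
pipeline is geometry-agnostic: any XYZ file can be substituted, and results
that depend on fine geometric detail (exact peak positions) will differ
slightly from quantum-chemically optimized structures while the qualitative
separations do not.  Atom order is H, H, C, C, Cl, Cl, matching the fragment
slot convention 1–2 = H⁺, 3–4 = C⁺, 5–6 = Cl⁺.

## Recoil frames and slot assignment

Each event is rotated into a frame built from its own momenta: a reference
vector along +x and a second reference fixing the x–y half-plane (positive
y).  The bundled `cis_dce` convention uses the difference of the two Cl⁺
momentum *unit* vectors along x with their sum (the bisector) in the upper
half-plane; `trans_dce` replaces the bisector — ill-defined when the Cl⁺
momenta are back-to-back — with the difference of the two C⁺ momenta.

Two subtleties matter and are exposed as options:

- **Identical-ion ordering** (`identical_ion_order`): same-species ions are
  experimentally indistinguishable, so by default the reference-ion
  assignment is randomized per event (seeded), which symmetrizes Newton
  plots exactly as the detection ambiguity does.  For simulated data the
  true identity is known and `"fixed"` keeps it.
- **Slot assignment** (`slot_order` in `build_features`): the canonical
  per-event rule assigns same-species fragments to slots by ascending
  recoil-frame azimuth (ties by p_z, then input order), making features
  well defined without ion identification.  This rule — like *any*
  deterministic per-event rule — is discontinuous where two same-species
  azimuths cross.  For a class whose frame roll is ill-defined (trans-DCE
  in the cis convention: the bisector is noise, so events are uniformly
  distributed over the roll angle), the discontinuities slice a connected
  ring of events into several disconnected arcs in feature space, which a
  density clusterer faithfully reports as separate (pure) sub-clusters.
  The bundled demos therefore cluster simulated data with truth identity
  (`identical_ion_order="fixed"`, `slot_order="input"`), where each
  structure is one connected manifold; the canonical azimuth rule remains
  the default for experiment-like data, with this caveat documented.

## Descriptors

Per event, after the frame rotation:

- Cartesian components p{slot}{axis} — 18 dimensions for a six-fragment
  channel.  (In the cis convention the two Cl⁺ z-components are identically
  zero by construction of the frame; standardization drops them with a
  warning.)
- Rotation-invariant internal coordinates: pair distances
  d_ij = |p_j − p_i| (a.u.), pair angles θ_ij = ∠(p_i, p_j) ∈ [0°, 180°],
  and plane–plane angles φ_ijkl between the normals of the planes spanned
  by (p_i, p_j) and (p_k, p_l).  Normals are taken in index order and φ is
  kept in [0°, 180°] without folding to [0°, 90°], preserving orientation
  information.  Default quadruples: φ₁₂₅₆ (H-plane vs Cl-plane — the
  natural momentum-space analogue of the dihedral angle), φ₁₂₃₄, φ₃₄₅₆.

## Coincidence filtering

Complete events conserve momentum, so |Σp_i| gates out false coincidences
(fragments from more than one molecule).  The gate accepts iff |Σp_i| ≤
threshold, with a relative mode (default 5% of the event's RMS fragment
momentum) and an absolute mode (a.u.); true simulated events carry residuals
at the integrator level (~1e-13 a.u.), chimeric events tens of a.u., so any
threshold between is equivalent — the default is a calibration choice, not
a tuned value.  Detection imperfections are modeled directly in momentum
space: independent per-ion detection with probability ε (complete fraction
ε^n), and chimera construction by swapping a random fragment subset between
two events.  No spectrometer, ToF, or ion-optics model.

## Machine-learning pipeline

Features are z-scored (fit on training data, stored for held-out data)
before any embedding.  Defaults are the algorithms' canonical values, all
exposed: UMAP n_neighbors 15, min_dist 0.1, 2 output dimensions; HDBSCAN
min_cluster_size max(50, 1% of events), root cluster allowed so unimodal
data yields one cluster; Random Forest 100 trees, impurity-based
importances, 100 repeats with consecutive seeds, mean ± SE (SD/√n)
reported.  Supervised UMAP uses the label-conditioned graph at the library's
default target weight.  Cluster-to-label matching is by majority vote (ties
toward the larger class); the misclassification rate is computed over
assigned (non-noise) events, with noise counted separately.  PCA, t-SNE and
LDA are available as baselines behind the same interface; t-SNE has no
out-of-sample projection and says so.

All stochastic stages are reproducible bit-for-bit from their seeds; UMAP
is run single-threaded under a fixed random_state, and `repeat_with_seeds`
uses the deterministic schedule base_seed + k.

## Problem sizes and observed results

The bundled analyses run at 2,000 events per class (narrow conditions
σ = 0.25 Å / 0.5 eV; broadened twisted/1,1-DCE at 0.5 Å / 3 eV with 600
events per class for supervised training, 400 per class held out), chosen
so the full pipeline — including the N-body integration — completes on a
single CPU in minutes while leaving the qualitative results unchanged from
larger runs.  The supervised-transfer repetition uses 20 seeded refits of
the supervised embedding.  At these sizes (`scripts/acceptance.py`):

- two-body kinetic-energy release matches the closed form k q₁q₂/r₀ to the
  termination tolerance (~1e-4 relative);
- cis/trans θ₅₆ distributions are disjoint with a ~20° gap; unsupervised
  UMAP + HDBSCAN on the 18 Cartesian dimensions yields exactly 2 clusters
  at purity 1.0, and the four-geometry mixture yields exactly 4;
- θ₅₆ alone leaves twisted vs 1,1-DCE heavily overlapping (overlap
  coefficient ~0.5) while the (θ₅₆, θ₁₂, φ₁₂₅₆) triple classifies a 25%
  holdout at ≥ 0.99 accuracy, with φ₁₂₅₆ the rank-1 discriminator of the
  twisted/1,1 pair;
- the simulation-trained supervised embedding recovers held-out cis/trans
  events at ~100% per class (mean over 20 seeded repetitions);
- complete events pass the momentum gate at rate 1.0, > 95% of chimeras are
  rejected at a threshold of 3× the true-event 99th-percentile residual,
  and the gated azimuthal distributions have a zero inter-peak baseline.

## Known limitations

- **Feature-ranking ties on ideal data.**  In this simulation the H⁺–H⁺
  angle θ₁₂ separates cis/trans essentially as cleanly as the Cl⁺–Cl⁺ angle
  θ₅₆ (both with zero overlap), because simulated H⁺ momenta are as
  noise-free as Cl⁺ momenta.  Random-Forest rank 1 therefore alternates
  between θ₁₂ and θ₅₆ across seeds instead of settling on θ₅₆, as it does
  on measured data where light-ion momenta are noisier.  The corresponding
  stability assertion in the acceptance suite is left failing rather than
  adding a detector-noise dial to force it.
- Momentum magnitudes are systematically overestimated by the point-charge
  model; analyses should rely on angular/relative observables, as the
  pipeline's descriptors do.
- Fixture geometries are idealized; peak positions (not separations) shift
  slightly against optimized structures.
- The azimuth slot canonicalization fragments ill-defined-roll classes into
  sub-clusters (see above); use truth ordering for simulated data or a
  structure-appropriate frame convention.
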