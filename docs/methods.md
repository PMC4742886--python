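# Methods

This note records the models, conventions and numerical choices behind
`translodyn`, and what the synthetic-data tests do and do not demonstrate
about real ribosome data.

## The structure-based potential

A single-basin all-atom structure-based model defines an experimentally
derived conformation as the global minimum of the potential. The terms
are, in reduced energy units (ε = 1) and Ångström:

- bonds: `k_b (r − r0)²` with `k_b = 100 ε/Å²`;
- angles: `k_a (θ − θ0)²` with `k_a = 40 ε/rad²`;
- dihedrals: `k_d [1 − cos(φ − φ0)] + (k_d/2)[1 − cos 3(φ − φ0)]`;
- native contacts: `w [(r0/r)¹² − 2 (r0/r)⁶]`, minimum `−w` at the native
  separation `r0`;
- generic repulsion on all remaining pairs: a force-shifted inverse-12,
  `ε_ex [(σ/r)¹² − 1 + 12(r − σ)/σ]` for `r < σ`, zero beyond, with a
  uniform atom diameter `σ = 2.5 Å` and `ε_ex = 0.01`.

Native contacts come from a cutoff map (default 4.0 Å between heavy
atoms, minimum intra-chain residue separation 4) rather than a shadow
algorithm; the choice is a `ForcefieldParams` field, and externally
generated maps can be supplied as `ContactMap` objects. Force-shifting
the repulsion to zero at σ, together with automatic exclusion of any
native pair closer than σ, makes the input structure an *exact* stationary
point (per-atom net force below 10⁻⁶), which the test suite asserts.

The stabilizing energy is normalized so that contacts plus dihedrals carry
`1 ε` per atom, split 2:1 between contacts and dihedrals. The bead-model
toys this package simulates have no backbone/side-chain split, so the 2:1
convention is applied to the contact:dihedral partition as a whole; both
numbers are parameters.

**Multi-basin construction.** The topology is built from the
post-translocation (P/P–E/E) endpoint; the contact set of the second
endpoint (A/A–P/P-derived) is merged in as additional labelled terms.
Contacts present in both basins are kept as two independent entries with
their own `r0` and weight, preserving both minima. Weight-rescaling rules
act on group pairs across the merged set: ribosome ↔ mRNA–tRNA contacts
are rescaled by 0.3 (reflecting the transience of mRNA–tRNA binding
relative to ribosome structural integrity), and the 30S–50S and
head–body interface contacts are weakened by a default factor of 0.5 —
the interface factor is not pinned by a published number and is exposed
as a parameter. tRNA dual-site affinity arises purely from the merged
contact sets; no extra biasing terms are used.

**Steric perturbations.** `remove_steric_pairs` disables the generic
repulsion between every cross pair of two groups while leaving attractive
contacts untouched. Deletions use set semantics, so they are idempotent
and composable: the model variants of the tilt-perturbation series are
Model 1 (full sterics), Model 2 (no S13↔tRNA sterics), Model 3 (no
PE-loop↔tRNA sterics) and Model 4 (both removed), with Model 4 equal to
the composition of the Model 2 and Model 3 deletions.

## Langevin dynamics

The integrator is the BAOAB splitting (half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity update, half-drift, half-kick) with unit
masses. At zero friction and temperature it reduces to velocity Verlet;
the suite bounds the microcanonical energy drift at 10⁻⁴ (relative) over
10⁵ steps at the production time step dt = 0.002. The production
temperature is 0.5 reduced units. The friction coefficient defaults to
γ = 1 (reduced); it is a stand-in, as only "Langevin dynamics" is
prescribed for the protocol, and configurational averages are
γ-independent. Reduced time maps only roughly onto physical time and is
never used in computation.

Termination predicates (e.g. "post-state reached") are evaluated on saved
frames only. Runs are bitwise reproducible for a fixed seed.

**Sampling validation.** The engine's Boltzmann sampling is checked two
ways. A harmonic oscillator's bond-length variance must match T/(2k)
within three standard errors. On a two-basin polymer, basin populations
from the Langevin run are compared against an independent Metropolis
Monte-Carlo sampler (single-atom moves plus rigid arm swings) targeting
the same distribution — a dual-route check in which basin entropies
cancel identically. We deliberately do *not* compare occupancy ratios to
`exp(−ΔU/T)` alone: setting the inter-basin gap by scaling contact
weights also scales basin stiffness, so measured ratios contain a
configurational-entropy factor on top of the Boltzmann energy factor
(at a gap of 1 with T = 0.5 the entropy factor is of order e²; its soft
docking modes are anharmonic enough that a normal-mode correction is
only qualitative). At the canonical gap of 5 reduced units — the scale
of tRNA internal strain in hybrid states, 10 kT at the production
temperature — the energy factor dominates any plausible entropy factor,
and the acceptance test asserts that the docked upper basin is at least
an order of magnitude less populated than the lower one.

## Head rotation and tilt decomposition

All angles are defined against a `ReferenceAxes` frame built from a pair
of endpoint structures. The swivel (head) axis is the rotation axis of
the head-group Kabsch fit between the classical and head-rotated
references after body alignment, oriented so the classical → rotated
transition has positive φ_head; an inter-reference head rotation below 2°
is rejected as ill-defined. The mRNA axis is the principal axis of the
mRNA group, sign-resolved along the first→last atom direction. The body
(intersubunit) axis comes from the body-group rotation after
large-subunit alignment when the reference pair contains a body rotation
of at least 0.5°, else it falls back to the swivel axis.

Each frame is body-aligned, the head pose is fitted (Kabsch on the head
group; phosphorus/Cα bead positions in the toys), and the rotation is
factored as `R = R_tilt · R_swivel` with the swivel applied first. The
factorization is closed-form and exact: R_swivel is the rotation about
the head axis n that R induces, and R_tilt is the minimal rotation
carrying n to R·n; θ_head = ∠(n, R·n) ≥ 0 and χ_head is the signed
azimuth of the tilt axis from the mRNA direction's projection into the
plane ⊥ n. The two factor orders differ at second order in the angles;
tilt∘swivel (swivel first) is the package's fixed convention. χ_head is
reported missing below a tilt floor of 0.5°, where the azimuth is
numerically meaningless. Angles are degrees externally, radians
internally. A head-fit RMSD above 2 Å raises, as it signals non-rigid
deformation outside the model's assumptions.

Noise-free constructed poses are recovered to numerical precision for
θ ∈ [0°, 25°], φ ∈ [−25°, 25°]; with 0.3 Å per-atom coordinate noise the
mean absolute angle error stays below 0.5° (both asserted in the suite).

## Reaction coordinates

ASL positions are centroids of the ASL bead groups (tRNA residues 30–40;
configurable), the elbow is residues 54–60, evaluated after alignment:
30S-body alignment for the ASL distances, large-subunit alignment for the
elbow. `R_P−ASL = 0` when the P-site tRNA occupies the 30S E site of the
POST reference. The pair coordinates (R_gate between the P atoms of 16S
U1340 and A790; R_A31 between the tRNA A31 P atoms; R_pe between P-tRNA
A31 and 16S A1229) need no alignment. All built-ins are invariant under
global rigid transforms. Outputs are written to 0.1 Å; full precision is
kept internally.

## Ensembles and statistics

Ensemble predicates are interval conjunctions, priority-ordered:
ap/P–pe/E is φ_head ∈ [14°, 20°] ∧ R_P−ASL ∈ [4, 6] Å; HT is
θ_head ≥ 6° ∧ φ_head ≤ 8°; the endpoint P/P–E/E requires near-zero
angles and R_P−ASL < 2 Å. These boundaries are read off reported ranges,
are configurable, and frames matching nothing are "unassigned".
Statistics are frame-pooled across events (per-event averaging is
available by grouping the tables); standard deviations use the population
(n) convention. Default histogram bins are 0.5 Å and 1°. The FWHM of
circular angle distributions uses a fixed-bandwidth (2°) Gaussian kernel
on a 0.5° grid with wrap-around, measuring the width between the
half-maximum crossings that bracket the global peak; densities that never
fall below half maximum raise. The kernel convolution widens a true
Gaussian of σ to FWHM 2.3548·√(σ² + 4) — about 2% at σ ≈ 10° — which is
inside the tolerances used. Ensemble-average structures align every
member to the parent reference on the alignment group before averaging,
which makes the average independent of frame order.

## The synthetic generator

The mini-ribosome is geometrically, not chemically, realistic: Gaussian
bead clouds for the 30S body (200 beads), head (100), large subunit (150)
and protein S13 (15), a 20-bead mRNA laid along +x, and two 40-bead
L-shaped tRNAs, with every named landmark placed explicitly — the gate
P atoms 16.7 Å apart in the classical pose, A31 beads, A1229, the PE-loop
beads, and the S13 C-terminal tail. Site spacing is 25.2 Å so the
classical-state ASL separation R_A31 equals its crystallographic value by
construction, and tRNA displacements span the ~25 Å the full system
exhibits.

Programmed trajectories apply exact rigid motions in the generator's
fixed frame (swivel about +z, mRNA along +x, body axis +y): the head
(including S13) is rotated by `R_tilt·R_swivel` about the head centroid,
the tRNAs are rigidly translated to meet the frame's distance targets,
the whole small subunit is rotated by φ_body, and iid isotropic Gaussian
noise (default σ = 0.3 Å) is added last. tRNA placement solves the
programmed (R_P−ASL, R_pe) and (R_A−ASL, R_A31) constraints sequentially
in closed form as sphere–sphere intersections, resolved deterministically
toward the mRNA track; geometrically inconsistent programs raise. R_gate
and R_A−ELB are dependent coordinates of the rigid construction and
cannot be programmed directly.

The stage-resolved translocation program draws per-frame targets from the
stage means and standard deviations of the four-stage sequence
(pre-translocation → ap/P–pe/E → head-tilted → P/P–E/E), e.g.
φ_head = 16.5 ± 1.5° with R_A31 = 19.1 ± 1.6 Å and R_pe = 11.5 ± 1.3 Å
in the chimeric stage, θ_head = 9.5 ± 2.2° with tilt direction
0 ± 10.19° in the head-tilted stage. Distance targets are truncated at
±1.5 s.d. so that every frame's rigid construction is geometrically
consistent; this narrows the realized R-coordinate spreads by ~20% while
leaving their means and all angle statistics untouched. Because frames
are drawn independently, the generator emulates the pooled-frame
statistics of many events, not their time correlation, barrier-crossing
kinetics, or any coupling between coordinates beyond the programmed
constraints — passing recovery tests therefore validates the estimators,
not the physics of a real trajectory.

The two-basin polymer is a high-zigzag backbone with a rigid arm bonded
to its end: docked above, the arm contacts only the raised odd beads;
docked below, only the low even beads, giving disjoint basin contact
sets at identical internal geometry. Hinge terms whose native values
differ between the conformations are zeroed so both poses sit exactly at
the bonded minimum, and the basin-B weight scale is solved linearly so
the two constructed minima differ by the requested gap exactly (gaps
requiring non-positive weights raise).

## Problem sizes and determinism

The default study sizes are chosen for a single CPU: 25 synthetic events
of 100 frames for the ensemble statistics, 400-frame datasets per
steric-model variant, 10⁵-step dynamics runs for the thermostat and
drift checks. All generators and the integrator take explicit seeds and
are bitwise reproducible; `scripts/acceptance.py` derives every stream
from its single `--seed` argument.

## Known limitations

- Bead-chain connectivity (one atom per residue) is the only bonded
  template; all-atom residue topologies (and hence chemically realistic
  polymers) are out of scope.
- The generator's per-frame independence means kinetic quantities
  (transition rates, dwell times) cannot be studied on synthetic data.
- The steric-perturbation *consequences* (reduced tilt in Models 2–4) are
  programmed into the synthetic datasets at the study's reported
  amplitudes; at desk scale the package demonstrates that the analysis
  pipeline measures them correctly, not that the forcefield reproduces
  them from first principles — that requires full-scale simulation.
- mmCIF input, electrostatics/desolvation, free-energy estimation and
  targeted/steered protocols are out of scope.
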