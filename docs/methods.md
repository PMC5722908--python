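# Methods

`stepmd` implements, at desk scale, the enhanced-sampling machinery used to
drive a nuclease domain from a pre-catalytic to a catalytic conformation:
accelerated-MD boosting, targeted-MD steering, and a step-by-step adaptive
ensemble protocol, together with the trajectory-analysis workflow used to
characterize the transition.  Everything runs on synthetic bead systems; the
note below records the models, the defaults and why, the numerical choices,
and what the toy systems do and do not show.

## Dynamics

The engine integrates Langevin dynamics with the BAOAB splitting
(half-kick, half-drift, Ornstein–Uhlenbeck velocity refresh, half-drift,
half-kick).  BAOAB was chosen for its accurate configurational averages at
moderate time steps; with friction γ = 0 and T = 0 the O-step is the
identity and the scheme reduces exactly to velocity Verlet, which is how the
energy-conservation checks are run.  There are no constraints and no
barostat: the toy systems are unconstrained NVT.

Two unit systems exist.  The engine default is reduced units (k_B = 1, unit
mass and length); a temperature of 1 makes "kT" the energy unit, so basin
depths in the fixtures read directly in thermal units.  A physical mode
(Å, kcal/mol, ps, amu; k_B = 1.987×10⁻³ kcal/mol/K, 1 kcal/mol =
418.4 amu Å²/ps²) is used wherever numbers are compared against
laboratory-scale quantities: the steering schedule in Å/ns, ion-count box
arithmetic, and manifest times.

Randomness: every replica stream is a `numpy` PCG64 generator keyed by
`SeedSequence((master_seed, cycle, replica))`, i.e. a collision-resistant
hash of the campaign seed and the run's coordinates in the campaign.
Campaigns are therefore bit-reproducible, and replica streams are
independent regardless of how many replicas or cycles run.

## Potential terms

Six term types cover the fixtures: harmonic bonds; short-range Gaussian
pair wells −ε·exp(−(r−r₀)²/2σ²) (shifted to zero at the cutoff, so designed
contact distances are exact stationary points); one-sided harmonic pair
walls (excluded volume at a designed contact distance); a quartic axis
double-well a(u−z₁)²(u−z₂)² with an optional localized Gaussian deepening
one basin; axis and positional harmonic tethers; and two analytic
single-particle landscapes (1D double well V = a(x²−b)², Müller–Brown)
whose closed-form energies, gradients and (1D) Boltzmann densities serve as
oracles for the sampling tests.

Force evaluation groups all terms of a type into index arrays and
accumulates forces with a single `bincount` scatter, so a step costs a
fixed, small number of vectorized operations (~0.1–0.2 ms for a 14-bead
system with a bias attached).

## The domain-docking fixture

The fixture emulates a mobile nuclease domain docking onto a scissile site:

* a pinned *scaffold* (7 beads: scissile site, four base beads, two labeled
  reporter posts), held by positional tethers;
* a rigid-ish *mobile domain* (6 beads: center, two catalytic sites at
  lateral offset w = 5.8 on either side, an apex reporter bead, two linker
  attachment beads) bonded as a stiff complete graph and tethered to the
  scaffold by two weak linkers;
* an optional *ion* bead tethered at the reaction interface (the centroid
  of the two catalytic sites and the scissile site in the docked pose),
  bridging all three through Gaussian contact wells whose minima sit
  exactly at the docked-pose distances.

The progress metric is the geometric mean of the two scissile–catalytic
distances.  The designed undocked pose scores exactly 9.0 length units and
the docked pose exactly 6.0, echoing the ~9 Å → ~6 Å transition the
protocol is meant to capture.  The docking coordinate is the domain
center's height; its double well has wells exactly at the two pose heights.

Three design points deserve a note because they were forced by early
numerical experiments with the fixture:

1. **Asymmetry lives in a localized pocket, not a tilt.**  A linear tilt
   would displace the quartic minima, so the designed poses would no longer
   be stationary points and campaigns would plateau away from the designed
   metric.  Instead the undocked basin is deepened by a narrow Gaussian
   (depth 4 kT, σ = 1.0), leaving both poses exact stationary points.
2. **Steric walls give the metric a floor.**  Reseeding from the
   best-scoring frame is a ratchet: any tail fluctuation that happens to
   lower the metric becomes the next seed.  With nothing to stop the
   catalytic beads from approaching the scissile bead, campaigns ratchet
   the metric far below the docked value.  One-sided harmonic walls
   (k = 25) placed 0.2 units below the designed contact distance bound the
   metric near 6 from below — the bead-model analog of excluded volume at a
   formed interface.  The walls sit below the contact, not at it, so the
   docked pose itself is wall-free.
3. **Orientation tethers.**  A rigid domain held only by linkers can spin
   and tilt freely; extreme tilts move one catalytic bead toward the
   scissile site and fool the metric.  Axis tethers on the apex bead
   suppress tilt while leaving the metric-invariant spin about the docking
   axis free.

Energy scale (reduced units, multiplied by `energy_scale`): quartic barrier
2.5 kT, undocked pocket 4 kT, ion contacts ε = 5 kT each (σ = 0.4, cutoff
r₀+3σ).  These were set once, by Kramers-rate reasoning during fixture
design, to realize the phenomenology the protocol needs — an
undocked→docked crossing that is rare on the single-replica run scale but
likely somewhere within a 10-replica cycle; a docked-with-ion state that
is the global minimum and stays put; and, without the ion, a docked pose
that is only marginally metastable, so removing the ion from a docked seed
drives the metric back up.  The test suite checks exactly these behaviors
(campaign convergence and plateau, docked-state stability, the
ion-removal direction); it asserts the direction of the ion effect, never
particular post-removal values.  The decorative scaffold beads are
jittered deterministically from the seed; all functional geometry is
exact.

In physical mode (`DockingGeometry.physical_defaults`) the same landscape
is expressed in kcal/mol via `energy_scale = k_B·310.15 K`, with bead
masses of 100 amu and softened stiffnesses so a 0.05 ps time step is stable
(stiffest mode ωΔt ≈ 0.4).

## Accelerated MD

Boost: ΔV = (E−V)²/(α+E−V) below the threshold E, zero above; the biased
force is the unbiased force times α²/(α+E−V)².  Two modes: boosting only
the designated internal-coordinate channel (the fixture's double-well
terms, playing the role of the dihedral channel), or dual boost with an
extra threshold on the full potential.  In dual mode the total-channel
boost is computed on the unbiased total potential and the two boosts add:
V* = V + ΔV_int(V_int) + ΔV_tot(V); the biased force follows by the chain
rule, f_tot·F + (f_int−1)·F_int.

Parameter estimation follows the shape of the standard recipe — threshold
offset and acceleration proportional to a size measure, estimated from a
short unbiased run: E = ⟨V⟩ + c_E·size, α = c_α·size per channel.  The
exact protein coefficients are not restated here; the coefficients are
configurable with defaults (internal channel: c_E = 3.5, c_α = 0.7 per
internal term; total channel: 0.2, 0.2 per particle) chosen so that on the
reference double well (barrier 4 kT) the boosted landscape retains ≈ 1 kT
of roughness — deep enough to reweight, flat enough to diffuse.

Reweighting: each frame carries its boost ΔV; the unbiased profile over an
observable is F(bin) = −kT·ln Σ_bin exp(ΔV/kT) (evaluated shift-stabilized,
re-zeroed at the minimum; empty bins are NaN, never zero).  A second-order
cumulant estimator is selectable for large boosts.  Exponential reweighting
is exact in expectation but noisy when ΔV spans many kT; on the reference
double well (ΔV ≤ ~5 kT) a 200 000-step dual-boost run recovers the 4 kT
barrier to within a few percent, which is what the acceptance check
exercises at a 15 % tolerance.

## Targeted MD

U = ½(k/N)(RMSD(t) − RMSD*(t))² with k the total spring constant scaled
down by the number N of targeted beads, RMSD(t) the instantaneous best-fit
(Kabsch, proper rotations only) weighted RMSD to the target, and RMSD*(t)
linear in time between the schedule endpoints, clamped outside (before the
start it holds the initial value; after the end it holds the final value,
matching a steering stage followed by unbiased relaxation).  Weights are
uniform or mass-based ("mass-weighted partial" steering); the fit selection
may differ from the targeted selection, e.g. fitting on the restrained
scaffold while steering the mobile domain.

The RMSD gradient keeps only the explicit coordinate dependence after
optimal superposition: ∂RMSD/∂x_i = w_i(x_i−y′_i)/(W·RMSD).  When the fit
set equals the targeted set the rotation-gradient terms vanish at the
optimum and this is the exact gradient (verified against central
differences to 1e-5).  When the fit set is a separate, restrained selection
the fit atoms receive no steering force by design — the guiding force acts
only on the targeted domain.  Non-targeted low-mobility beads can be held
by a weak positional restraint (default 0.1 kcal/mol/Å²) against solute
drift; the fluctuation threshold for choosing restrained atoms is not
hard-coded — the restrained selection is an explicit parameter.

The reference steering protocol (`make_tmd_docking_setup`) prepares the
physical-unit fixture with a start pose whose mass-weighted best-fit RMSD
from the docked target is exactly 10 Å over the mobile domain, a per-atom
spring of 0.25 kcal/mol/Å², and a 100 ns linear schedule to zero —
a scheduled decrease rate of 0.1 Å/ns.  Run at 310.15 K with a 0.05 ps
step (2×10⁶ steps, a few minutes on one core), the fitted slope of the
measured RMSD(t) comes out ≈ 0.09 Å/ns: the trajectory lags in the
undocked pocket early on, crosses, and ends ~1–1.5 Å above the (zero)
schedule endpoint — the generic shape of steering any system against its
own landscape, which always leaves a thermal residual gap.  The slope is fitted
over the whole schedule; short windows are dominated by the pocket
transient and do not measure the rate.

## Step-by-step adaptive ensembles

Each cycle seeds `n_replicas` unbiased runs from the current seed frame
(velocities redrawn from Maxwell–Boltzmann — copying one replica's momenta
to all would correlate the ensemble), scores every saved frame with the
progress metric, and takes the minimum as the next seed.  Two selection
scopes: `previous_cycle` (the literal protocol: "a snapshot from a previous
cycle") and `best_so_far` (global minimum over the history).  The per-cycle
minimum series is non-increasing by construction only for `best_so_far`;
that scope is what the convergence acceptance check uses.  Ties break
deterministically toward the earlier cycle, lower replica id, earlier time.

Convergence: the campaign stops when the relative change of the per-cycle
minimum stays below 5 % for 2 consecutive transitions.  There is no
canonical stopping rule for this kind of protocol — the observable is a
plateau over a few cycles — so 5 %/2 is this package's choice and both
knobs are parameters.  On the default fixture (10 replicas
× 3 000 steps, T = 1) campaigns started from the undocked pose converge to
a plateau at ≈ 5.6–5.7 — within 10 % of the designed docked metric, the
small deficit being the expected minimum-statistics bias of scoring the
*minimum* over ~10⁴ thermal frames near a floor at 5.8.

A failed replica (integration blow-up) is logged and dropped; the cycle
proceeds if at least one replica survives.  The manifest records one row
per cycle (group, method tag, seed note, production time per run, number of
surviving runs); `manifest_totals` sums production time over group/method
filters, and the built-in reference ledger reproduces the modeled
campaign's totals (11 µs conventional + 3.3 µs accelerated = 14.3 µs).

The package also ships the comparison the protocol's value rests on:
against an equal-budget ensemble always reseeded from the undocked pose
(same replicas, lengths and cycle count, only the reseeding rule differs),
adaptive reseeding reaches the docked-metric threshold in fewer cycles for
a majority of paired seeds on a stiffened fixture (deeper undocked pocket),
where a single run essentially never crosses unaided.  This is a stochastic,
seeded check: 8 fixed pairs, censored at the budget, majority of decided
pairs.

## Trajectory analysis

* **Fit-excluded PCA.**  Frames are rigid-fitted to a reference over a fit
  selection (the scaffold, excluding the mobile domain); the coordinate
  covariance is then computed over the analysis selection (the mobile
  domain) and eigendecomposed.  Cartesian PCA only.  Eigenvalue bookkeeping
  is exact: fractions sum to 1, per-mode projection variance of the fitted
  data equals its eigenvalue, full-rank reconstruction is lossless.  A
  variance-free trajectory yields all-zero eigenvalues with a warning.
* **Distance pairs.**  Labeled site-pair series (the FRET-analog pairs and
  the reaction-interface pair), exportable as pair-vs-pair scatters.
* **Groupwise RMSD.**  `global_fit` (fit on a designated selection, report
  per-group RMSD without refit — a displaced rigid domain shows its full
  displacement) vs `self_fit` (each group fitted on itself — isolates
  internal deformation).
* **Cluster representatives.**  Pairwise best-fit RMSD matrix,
  average-linkage clustering cut at a threshold, medoid of the largest
  cluster; ties to the earliest frame.  Average-linkage with a threshold
  cut and a medoid representative is this package's documented choice of
  cluster analysis, checked against exhaustive medoid computation.
* **Coordination geometry.**  Ligands = labeled candidates within a cutoff
  of a labeled center; all ligand–center–ligand angles are classified to
  the nearer of 90°/180°; octahedral requires exactly 6 ligands, 12 cis and
  3 trans angles within tolerance (default ±15°, a typical
  coordination-geometry screen).
* **Interaction decomposition.**  Cross-group sum of pairwise short-range
  terms with exact per-particle splitting (half to each endpoint) — a toy
  pairwise analog of an interface interaction energy, not a continuum-
  solvent calculation.

## What the toys show — and what they do not

The fixtures demonstrate that the *machinery* behaves as specified: the
boost obeys its analytic form and its reweighting recovers a known free
energy; the steering spring tracks a linear RMSD schedule at the scheduled
rate; adaptive reseeding converges a designed docking transition and beats
equal-budget naive seeding; the ion term controls docked-state stability in
the right direction.  None of this validates force fields, water models,
electrostatics, or any biological claim about the real enzyme: bead wells
stand in for interaction networks, one collective coordinate stands in for
a high-dimensional transition, and the thermal scales were chosen to make
rare events observable in seconds of CPU time.  Passing tests certify the
algorithms and their bookkeeping, not the chemistry.

## Problem sizes used by the checked runs

Equipartition and Boltzmann checks: 1 bead, 1.2–2×10⁵ steps.  PMF
recovery: 2×10⁴ estimation + 2×10⁵ boosted steps.  Campaign convergence:
up to 12 cycles × 10 replicas × 3 000 steps (14 beads).  Steering rate:
2×10⁶ steps (13 beads, physical units).  Paired seeding comparison:
8 pairs × 2 arms × ≤ 6 cycles × 5 replicas × 1 500 steps.
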