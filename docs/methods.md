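# Methods

This note documents the model equations' provenance, the assumptions behind
each module, the numerical choices, and what the shipped reference
parameter set was calibrated against.

## Model overview

The package implements a deterministic whole-cell model of the guinea-pig
ventricular myocyte with ~78 ODE states coupling four subsystems:

1. **Sarcolemmal electrophysiology** — fast Na⁺ current and inward
   rectifier of the Luo–Rudy lineage; delayed rectifier split into rapid
   and slow components (I_Kr, I_Ks), with two selectable I_Ks
   formulations: the default two-gate form with a fast activation gate and
   a four-fold slower second gate, and an older single-gate-squared variant
   with faster deactivation; plateau K⁺ current; ATP-sensitive K⁺ current
   whose open fraction falls steeply with ATP and rises with ADP; Na⁺/K⁺
   pump; Na⁺/Ca²⁺ exchanger with allosteric activation by cytosolic Ca²⁺;
   sarcolemmal Ca²⁺ pump; linear background Na⁺ and Ca²⁺ currents; and an
   optional fast transient outward K⁺ current (two Hodgkin–Huxley gates,
   reference conductance 0.2 mS/µF, off by default because the guinea pig
   lacks I_to).

2. **Local-control Ca²⁺ release (CaRU)** — each of the 339,000 release
   units pairs one L-type Ca²⁺ channel (LCC) with a cluster of five
   simultaneously gating ryanodine receptors (RyRs), represented by a
   single RyR whose unitary flux is five times the single-channel value.
   The LCC Markov model has 10 states: a four-step voltage-dependent
   activation chain plus an open state, duplicated in a "mode normal" and
   a non-conducting, Ca²⁺-inactivated "mode Ca"; switching into mode Ca is
   proportional to the dyadic subspace Ca²⁺ of the source configuration.
   Voltage-dependent inactivation is carried by a separate Hodgkin–Huxley
   availability gate, so availability = (1 − P(mode Ca)) · y.  The RyR has
   4 states (closed → primed → open → inactivated → closed) with steeply
   Ca²⁺-dependent activation (order ~3.5 in subspace Ca²⁺) so that the
   dyadic trigger, not resting cytosolic Ca²⁺, gates release.  The joint
   chain has 40 states indexed `lcc_state * 4 + ryr_state`; all 40
   occupancies are integrated as ODE states and the normalization drift is
   monitored (rather than eliminating one state by closure).

   Dyadic subspace Ca²⁺ equilibrates much faster than gating, so for each
   of the four open/closed configurations it is the closed-form root of
   the linear balance `0 = J_LCC + J_RyR + (Ca_i − Ca_ss)/τ_ss`, with a
   GHK-form LCC flux.  Because the trigger flux per open channel falls
   with depolarization (GHK driving force) while LCC open probability
   rises, excitation–contraction coupling gain falls monotonically with
   voltage, release is graded, and the Ca²⁺ transient peaks late in the
   plateau — the behaviors that motivate the local-control formulation.

3. **Ca²⁺ cycling and buffering** — SERCa pump with forward/reverse Hill
   terms, a single SR compartment (the junctional SR is merged with the
   network SR under the rapid-refilling assumption), and dynamic (not
   rapid-equilibrium) buffers: low- and high-affinity troponin (shared
   with the force model), calmodulin, and an SR buffer.  Total cell Ca²⁺
   is exactly conserved when sarcolemmal and mitochondrial pathways are
   silenced; a test asserts this.

4. **Mitochondrial energetics** — a Ca²⁺-regulated TCA cycle (citrate
   synthase with the aconitase step lumped in, Ca²⁺-activated isocitrate
   and α-ketoglutarate dehydrogenases, succinyl-CoA synthetase, succinate
   dehydrogenase, fumarase, malate dehydrogenase over a conserved
   intermediate pool), NADH-driven respiration with respiratory control by
   the membrane potential ΔΨ, F₁F₀ ATP synthase, an electrogenic adenine
   nucleotide translocator of the Magnus–Keizer form, a proton leak, the
   Ca²⁺ uniporter (Magnus–Keizer allosteric form, ΔΨ-driven), a
   3 Na⁺/1 Ca²⁺ matrix Na⁺/Ca²⁺ exchanger, and a matrix Na⁺/H⁺ exchanger
   that closes the Na⁺ loop (fixed cytosolic/matrix pH).  NADH + NAD⁺ and
   matrix ATP + ADP are conserved pools.  Matrix free Ca²⁺ uses a constant
   fractional-buffering coefficient, which is what makes the matrix a
   low-pass filter of the cytosolic transient.  Cytosolic nucleotides
   (ATP/ADP, phosphocreatine) connect the ATPases to the mitochondria
   through a creatine-kinase shuttle.

5. **Isometric force** — a six-state tropomyosin/crossbridge scheme of the
   Rice lineage (nonpermissive N0/N1, permissive P0–P3); the
   permissive/nonpermissive switch follows the fraction of Ca²⁺-loaded
   low-affinity troponin through a Hill function, and crossbridge
   detachment consumes ATP.  Normalized force is converted to stress with
   a lineage maximal-force constant over the printed cross-sectional area
   of 0.013 mm².

## Provenance of equations and parameters

The functional forms are taken from the published source models of this
lineage (Luo–Rudy/Zeng-type K⁺ currents, the two-gate slow delayed
rectifier, the allosterically regulated Na⁺/Ca²⁺ exchanger, the
nucleotide-gated K(ATP) channel, Magnus–Keizer-type uniporter and
translocator, Rice-type crossbridge scheme, and the coupled LCC–RyR
release-unit construction with algebraic subspace Ca²⁺).  Numeric
parameters fall into three provenance classes recorded per entry in
`src/gpmyo/data/reference_params.yaml`:

* `cited-source` — standard values of the lineage (cell geometry, external
  ion concentrations, buffer totals and rate constants, exchanger
  affinities, N_caru = 339,000, the 5× RyR cluster flux).
* `calibrated` — values fixed by fitting whole-model outputs (see below).
* `chosen` — free implementation choices (stimulus shape, pH values,
  subspace volume).

Where the source equations use different unit systems, everything is
converted to ms / mM / mV / µA/µF at load time; the conversion constant
between current density and concentration flux
(`Cm/(z·F·V_myo)`) is applied at exactly one point in the assembled model.

## Calibration

The reference parameter set was calibrated against the model's published
whole-cell outputs, treating them as a joint target surface: steady-state
APD₉₀ at 1 Hz, the delay of the Ca²⁺-transient peak after the AP peak,
peak RyR open probability, the open-open dyad subspace Ca²⁺ maximum, the
peak I_Ca,L I–V relation (−32 µA/µF at +10 mV), the leftward shift of the
release-flux peak (+5 mV), fractional SR release, the removal-pathway
shares (SERCa/NCX/sarcolemmal pump), the mitochondrial return bolus, and
the uniporter-block response.  Calibration minimized a weighted sum of
squared log-ratios with a derivative-free simplex search in log-parameter
space; the resulting values are versioned in the parameter file.  No
parameter is adjusted at run time.

## Numerical choices

* **Integrator.** LSODA (stiff/non-stiff switching multistep with an
  internally generated finite-difference Jacobian), relative tolerance
  1e-7 and absolute tolerance 1e-9 by default (both configurable).  The
  simulation is split into segments at stimulus and clamp edges so that
  every discontinuity coincides with a solver restart; output is sampled
  on a uniform 1-ms grid (finer for voltage-clamp steps).
* **Determinism.** For fixed inputs and tolerances all simulations are
  bit-reproducible; the only stochastic component is the Monte-Carlo
  release-unit oracle, which takes an explicit seed.
* **Voltage clamp.** V is integrated with `dV/dt` equal to the clamp-ramp
  slope (zero within a step); AP-clamp waveforms are applied piecewise
  linearly, one segment per waveform interval.
* **Steady-state pacing.** Beats are repeated until the maximum relative
  change of any end-diastolic state falls below 1e-4 (cap 1000 beats,
  smaller caps in the standard recipes).
* **APD₉₀** is measured from the time of maximum upstroke velocity to 90%
  repolarization of the peak-to-rest span (configurable to a
  stimulus-onset reference).  A trace with no AP returns NaN
  ("no capture") rather than raising.
* **Stimulus.** Rectangular current pulse, −80 µA/µF for 0.5 ms,
  configurable; stimulus charge is assigned to the K⁺ balance so that
  total charge and concentrations stay consistent (a test asserts the
  identity over a full beat).
* **Open-open subspace maximum.** The algebraic open-open concentration is
  reported as its maximum over the AP plateau (samples with V ≥ −20 mV).
  The GHK source term grows without bound at diastolic potentials, where
  open-open dyads do not occur; the plateau window reflects the release
  events the quantity describes.
* **End of diastole** is the instant of the next stimulus.
* **Gain monotonicity and graded-release continuity.** The ECC gain
  curve is checked as monotone non-increasing over 0…+60 mV with a 0.5%
  relative tolerance (the high-voltage gains are ratios of two
  near-zero fluxes and carry solver-level noise).  Graded release is
  checked as the absence of discontinuities in peak release flux across
  1-mV-spaced clamp steps, bounded through the second difference: the
  smooth release curve is locally steeper than 5% of its maximum per mV
  on its rising limb, so a first-difference bound would reject even an
  analytically smooth curve, whereas a genuine jump shows up as a kink.
* **Quadrature.** Trapezoidal on the output grid wherever integrals are
  needed (flux fractions, recirculation, force averages).
* **Degenerate inputs.** Non-positive concentrations raise domain errors
  at the operation surface; inside the RHS, tiny negative solver
  excursions of Ca²⁺ are floored at 1e-9 mM.

## Protocols

All experiment definitions are declarative and serializable: fixed-rate
pacing, 400-ms voltage-step families from a −40 mV pre-clamp, S1–S2
restitution (pace to steady state at 2000 ms BCL, save the end-of-AP
state, re-launch with one premature stimulus per diastolic interval;
an S2 that fails to capture is recorded as "no capture"), the
frequency staircase (3000 → 300 ms BCL, three simulated minutes per step,
APD/Ca²⁺/force recorded at each), workload transitions
(0.25 Hz → high frequency → 0.25 Hz over 100/200/200 s), and AP clamp
from two-column CSV waveforms.  Uniporter block is a `vmuni_scale`
parameter overlay applicable to any protocol.  A fixture generator
produces synthetic clamp waveforms (guinea-pig-like monotone plateau and
canine-like spike–notch–dome) for tests and demonstrations; these are
idealized shapes, not recordings.

The "accumulated force" recorded by the staircase is reported both as the
last-beat peak stress and as the cycle-averaged stress, since the two
readouts differ and either may be meant by that phrase.

## What the generated data do and do not show

All inputs are generated by the simulator itself; there is no external
data dependency.  Passing tests therefore demonstrate internal
consistency of the implementation (conservation laws, master-equation ↔
Monte-Carlo agreement, graded-release continuity, convergence in solver
tolerance) and agreement of the reference parameter set with the
published whole-cell outputs — not agreement with any new experimental
recording.  The synthetic AP-clamp waveforms capture gross morphology
(plateau height, notch) but none of the beat-to-beat variability or
noise of real recordings.

## Known limitations

* There is no junctional-SR compartment, hence no local SR depletion
  during release; termination of release relies on RyR inactivation.
  Load-dependent RyR regulation is absent.
* Under the rapid-equilibrium subspace assumption, a RyR that closes
  loses its elevated dyadic Ca²⁺ instantly (no diffusional memory), so
  the closed-intermediate deactivation rate must be small for release to
  persist; this is a structural property of the coarse-grained dyad.
* The mitochondrial module uses Michaelis–Menten reductions of the
  source oxidative-phosphorylation flux expressions (respiration,
  F₁F₀, proton balance) rather than the full carrier-cycle forms; it is
  calibrated at the output level (respiration span across pacing rates,
  NADH transient shape, uniporter-block response).
* ADP compartmentation is not represented; NADH under/overshoots during
  workload transitions are qualitatively correct but smaller than
  experimental recordings, as in the source energetics model.
* Sarcomere length is fixed (isometric); no length-dependent activation
  or mechano-electric feedback.
* β-adrenergic signaling, ROS, the permeability transition pore, and
  tissue-level coupling are out of scope.

## Problem sizes used in the shipped checks

The standard recipes pace at most 300 beats to steady state from a
versioned pre-paced initial state, use 21 voltage-clamp steps of 400 ms,
15 diastolic intervals for restitution, 120 beats for the uniporter-block
quasi-steady state, and three simulated minutes per staircase step.
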