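# Methods

This note documents the model equations, the parameter conventions, the
numerical choices, and the design decisions taken where the underlying
formulation left room for judgement.  It is the companion to the code in
`src/vasoreg/`; nothing here is an empirical claim beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Network representation

The microvascular bed is a *representative segment* network: thirteen
compartments in strict series (A, FA, 1A, 2A, 3A, TA, C, TV, 1V, 2V, 3V,
DV, V), each representing `n_i` identical vessel segments in parallel.
Segment counts are kept as real numbers (0.23, 4.33, …): they act purely as
parallel-conductance multipliers and nothing in the model requires them to
be integers.  FA, 1A, 2A, 3A and TA are vasoactive; A, C and the venous
compartments are fixed resistances.

### Derivation of the resting state

The resting network is determined by a deliberately small set of primary
quantities: arteriolar/capillary diameters, per-compartment wall shear
stresses and pressure drops, the artery segment length, and venous wall
shear (10 dyn/cm²).  Everything else follows from three identities —
Poiseuille wall shear `v = τD/8μ`, the axial force balance `L = ΔP·D/4τ`,
and flow conservation `n_i Q_i = const` with the feed artery as the unit
compartment.  The artery diameter comes from inverting the force balance;
venous compartments mirror the segment counts and lengths of their arterial
counterparts across the capillary bed and take their diameters from
`Q_seg = πτD³/32μ`.

Two conventions matter for reproducing the tabulated reference state to its
printed precision:

* **Viscosity.**  Arterial/capillary viscosities left unspecified in the
  network config are evaluated from the empirical *in-vivo* viscosity law
  of Pries et al. (1994) at discharge hematocrit 0.4; the tabulated per-compartment
  values are those numbers rounded to three digits, and using the unrounded
  law is what makes the derived velocities and segment counts land on the
  tabulated figures.  Venous viscosities are taken as explicit inputs (the
  tabulated values): the small venules are *not* consistent with the same
  law, and treating them as inputs reproduces the tabulated venous
  geometry.  During simulation all viscosities are frozen at their
  reference values (no update law is applied as diameters change).
* **Pressure units.**  1 mmHg = 1333 dyn/cm² throughout.  The reference
  tables were computed with the rounded constant, and consistency with them
  was judged more valuable than the fourth significant digit of the
  physical value (1333.22).

Tissue volume is total capillary length divided by the areal capillary
density (500 mm⁻²), giving 4.73×10⁻³ cm³; vascular volume fractions are
luminal volumes relative to it.

### Calibration

For each vasoactive compartment the reference activation is the value that
balances the imposed tension at the tabulated diameter,
`A_ref = (P_mid·D/2 − T_pass)/T_act_max` (midpoint pressure = arithmetic
mean of the compartment's inlet and outlet pressures).  The stimulus that
targets exactly this activation is `logit(A_ref)`, and the tone offset
`C''_tone` absorbs the difference between it and the resting myogenic,
shear and conducted-signal contributions at `C_symp = 0`, resting demand.
By construction the resting network is then an exact fixed point: a 60-s
unperturbed simulation holds every diameter to <10⁻⁶ μm (this is asserted
in the tests).  Calibration fails loudly if `A_ref` leaves (0, 1) — the
wall parameters would then be inconsistent with the reference geometry.

## Wall mechanics

Passive tension is exponential in distension, active tension a Gaussian in
`D/D₀` scaled by the activation, and the target activation a sigmoid of the
net stimulus (see README for the equations).  The active-tension curve is
used without any geometric prefactor: the tabulated `C_act` values carry
tension units (dyn/cm) directly.  An optional `πr²` prefactor variant is
retained behind a parameter flag for sensitivity analysis only.  Activation
is clamped to [0, 1] after each integration step; the dynamics drive it
toward a target strictly inside (0, 1), so the clamp only guards numerical
overshoot.

## Hemodynamics

Flow is quasi-steady: at every time step the series network is re-solved
for the current diameters (per-segment resistance `128μL/πD⁴`, compartment
resistance divided by `n`, fixed boundary pressures 100/13.06 mmHg).  There
is no inertance or compliance — the wall time constants (τ_d = 1 s,
τ_a = 20 s) dominate all dynamics of interest.  The series solve is tested
against a generic resistor-chain nodal solve at 10⁻¹² relative tolerance.

## Oxygen and ATP transport

Oxygen demand `M0` is volumetric tissue demand in
**cm³ O₂ (100 cm³)⁻¹ min⁻¹**, the conventional physiological unit; the
protocol presets 1, 1.91, 4.64 and 8.28 correspond to rest and 2.5/10/20 %
duty-cycle contraction.  Each exchanging compartment (FA…C; the artery and
the venous side exchange no oxygen) supplies an annular tissue sleeve of
width 18.8 μm with zero-order kinetics, so saturation falls linearly with
distance at rate `M0·A_sleeve/(Q_seg·C0_eff)` and is floored at zero once
depleted.  The sleeve annulus uses the current (time-varying) diameter; the
difference from freezing it at the reference geometry was checked and is
negligible (<0.3 % in the headline responses).  The convective capacity is
normalized as `C0_eff = C0·H_D/0.45` — the carrying capacity 0.5 cm³O₂/cm³
refers to blood at a normal hematocrit of 0.45, scaled to the discharge
hematocrit actually flowing.

ATP obeys `v·dC/dx = H_T·R0(1 − R1·S) − (4k_d/D)·C` in *every* compartment
(metabolic signal sources exist in all segments, venules included), with
`4/D` the surface-to-volume ratio that converts the wall degradation
velocity `k_d` (cm/s) into a volumetric sink.  Because saturation is
piecewise linear, this ODE is solved exactly piece by piece (splitting at
the oxygen depletion point where needed); compartment means are computed
analytically from the same pieces.  No numerical integration error enters
the metabolic signal.

## Conducted response

The local signal density is piecewise constant per compartment,
`S_loc = C_meta·⟨C_ATP⟩`, and the upstream-conducted signal is the
exponentially damped integral of all *downstream* sources, terminating at
the distal end of the venous outflow.  For piecewise-constant sources the
integral has a closed form, precomputed as a weight matrix over the fixed
geometry, so each evaluation is a single mat-vec; it is verified against
adaptive quadrature at 10⁻⁸.  Each vasoactive compartment reads the signal
at its midpoint (an `upstream_end` variant is available by configuration).
Only upstream conduction is modeled.  For sympatholysis control
experiments the conducted field can be locked: the solver then returns the
snapshot taken immediately before the lock time regardless of the current
metabolic state.

A note on the resting profile: at physiological resting demand the
capillary and venous saturations remain well above zero, ATP decays from
its inlet value toward the low release-degradation equilibrium of the small
vessels, and the resting conducted signal is therefore somewhat *larger* in
the proximal than in the distal arterioles.  The signal *changes* during
sympathetic stimulation — the quantity that drives sympatholysis — are
nevertheless always largest distally, because constriction-induced
desaturation generates sources closest to the terminal arterioles.

## Integration and protocols

Explicit fixed-step Euler with dt = 10 ms, output every 100 ms.  The
stiffest local rate constants are O(1 s⁻¹), so this step is comfortably
stable, and a fixed step makes every run bit-reproducible; a
Richardson-style halving test in the suite confirms first-order
convergence, and halving dt changes the headline responses by far less
than any tolerance used.  Protocols are piecewise-constant in `C_symp` and
`M0` (step changes), matching the square stimulation/contraction epochs of
the experimental protocols the model emulates.  Metabolic fields are
recomputed every step (signal generation and conduction are treated as
instantaneous).

Steady state is declared when max |dD/dt| < 10⁻⁶ μm/s *and*
max |dA/dt| < 10⁻⁷ s⁻¹ — the diameter criterion alone is blind to states
whose tensions balance momentarily while the activation is still moving.
Equilibration to the steady tolerance takes ~100–400 s of model time
depending on demand; the acceptance script and tests equilibrate with a
600-s cap and assert that the tolerance was reached.

## Randomized scenarios

`generate_scenario(seed)` perturbs the wall and signaling parameters
multiplicatively within ±20 % (±10 % for the passive diameters, whose
exponents amplify geometric jitter) and draws random piecewise-constant
protocols (2–4 epochs, `C_symp` ∈ [0, 4], `M0` ∈ [1, 8.28], 10–40 s each).
`R1` is capped below 1 so ATP release can never go negative.  Scenarios
whose jittered walls cannot be calibrated against the fixed reference
geometry are rejected and redrawn deterministically.  These scenarios
exercise the *invariants* (flow conservation, closed-form/oracle
equivalences, component-sum identity, positivity); they emulate parameter
uncertainty, not biological variability — they share one network topology
and reference geometry, so passing them says nothing about heterogeneous
networks or remodeled beds.

## Problem sizes

The packaged tests and the acceptance script run the model at its native
size (13 compartments, 5 vasoactive): equilibrations of a few hundred
seconds of model time, 30-s stimulation pulses at dt = 10 ms, a 100-seed
scenario campaign for the oracle equivalences, and 25-point
multiprecision sweeps for the tension curves.

## Known limitations

* Strictly serial, homogeneous topology: no flow-pathway heterogeneity,
  bifurcation phase separation, plasma skimming or capillary recruitment.
* Oxygen: no radial gradients, no diffusive exchange between neighboring
  vessels, zero-order uptake with a hard depletion floor.
* The metabolic mechanism is the erythrocyte-ATP pathway only; adenosine,
  potassium, calcium or NO dynamics are not represented, and signal
  generation/conduction is instantaneous.
* Viscosities are frozen at reference values during constriction; the
  in-vivo law is used only to populate the reference state.
* The tabulated venous geometry is reproduced to <0.1 % but not always to
  the last printed digit; the exact venous viscosity convention behind the
  published table could not be reconstructed (the large venules match the
  in-vivo law, the small ones do not).
* Sympathetic drive is a single additive constant applied equally to all
  arteriolar orders; receptor-subtype heterogeneity is deliberately absent
  (testing whether size-dependent responses emerge without it is the point
  of the model).
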