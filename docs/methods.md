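# Methods

This note documents the model, its parameterisation, the numerical choices
and the known limitations of `ionrep`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## The model

A uterine (myometrial) smooth muscle cell is described as a single
electrical compartment. Each electrogenic species *i* — ion channel, pump
or exchanger — carries a unit current

ψᵢ = Gᵢ · gᵢ(x) · (V − Eᵢ)

with unitary conductance Gᵢ (pS), conducting fraction gᵢ(x) ∈ [0, 1]
derived from the species' gating state x, and reversal potential Eᵢ
(single-ion Nernst, fixed, or a Goldman–Hodgkin–Katz potential solved from
zero net flux for multi-ion pores). The pumps and exchangers (PMCA, NaK,
NCX) are phrased directly as current densities (pA/pF) scaled by
dimensionless density factors. Currents are **outward-positive** and the
membrane equation is integrated in per-capacitance form,

dV/dt = i_inj(t) − Σᵢ κᵢ ψᵢ(t),   1 pA/pF ≡ 1 mV/ms,

where κᵢ ≥ 0 is the surface density of species *i* per unit membrane
capacitance (channels/pF). Intracellular calcium follows a minimal
one-variable balance driven by the two voltage-gated calcium currents:

d[Ca²⁺]ᵢ/dt = γ_L·J_L + γ_T·J_T − λ·[Ca²⁺]ᵢ

with J = −I the inward current magnitude; sarcoplasmic-reticulum release
and buffering are intentionally not modelled.

Internal units: ms, mV, pS, pA, pA/pF, nM for global [Ca²⁺]ᵢ (local spark
calcium is specified in µM and converted), µM for [ATP]ₒ, mM for all other
ion concentrations. Temperature is fixed at 310.15 K; no Q10 corrections
are applied.

### Density estimation (the method's core)

Given a paired recording of V(t) and [Ca²⁺]ᵢ(t) (or an f/f0 fluorescence
trace converted through the indicator relation), every species' gating is
driven open-loop by the observed waveforms from its steady state at the
first sample. Integrating each unit current gives cumulative charge
integrals qᵢ(t_k); with W_hi = −qᵢ(t_h) and Y_h = V(t_h) − V(0) − V₀(t_h)
(V₀ the injected-charge term), the observed voltage is *exactly linear* in
the densities: Y = W·κ. The estimation suite computes

* **κ⁺** — the SVD pseudo-inverse (minimum-norm least-squares) solution,
* **null space** — the final n−r right singular vectors (rank r counted at
  a relative threshold `rank_tol`, default 1e-8); this kernel is the space
  of density changes invisible to the recording — the cell's functional
  redundancy with respect to that behaviour,
* **κ_p** — a non-negative least-squares (NNLS) particular solution,
* **κ̂** — the ℓ1-minimal non-negative solution: linear programming over
  the kernel coefficients γ minimising Σ(κ_p + Bγ) subject to
  κ_p + Bγ ≥ 0. Kernel moves are fit-neutral, so κ̂ achieves κ_p's
  residual with the least total channel count (a parsimony criterion).
* **redundancy maps** — the kernel basis row-reduced to echelon form with
  a chosen leading species and each pivot rescaled to +1: a unit change in
  the leading density is compensated, to first order, by the trailing
  coefficients. A leading species with no kernel component is *pinned*
  (non-compensatable); rows whose coefficients exceed the physiological
  density bounds are flagged implausible. The published echelon algorithm
  for such maps is not specified anywhere we could find; greedy
  largest-pivot Gaussian elimination starting at the requested species is
  our choice, and it reproduces the expected single-row reading when the
  kernel is one-dimensional.
* **density upper bounds** — from a steady-state whole-cell I–V curve,
  each species' bound is max_V |Ī(V)| / |Gᵢ gᵢ(x̄(V)) (V − Eᵢ)| at a
  baseline calcium of 100 nM — the density the species would need to carry
  the whole observed current alone. Voltages within 1 mV of Eᵢ or with
  conducting fraction below 1e-12 are skipped; a species with no valid
  sample gets an undefined bound.

LP tie-breaking: the HiGHS vertex solution is reported as-is; degeneracy
only moves mass within the kernel and is fit-neutral. Sub-sampling: if a
recording exceeds 20 000 samples, rows of (W, Y) are decimated uniformly
after integration (a conditioning knob, configurable).

## The species library

All gating parameters printed in the primary biophysical literature for
these channels are used verbatim: Boltzmann half-activations and slopes
(e.g. Kv9.3 3.2/21.8 mV, Kv6.1 −9.4/11.8 mV, Kv3.4 19.1/11.3 mV, Kv4.1
−49/22.3 mV, L-type −18.9/8.8 mV, T-type −28.6/8.9 mV, Kv7.4 −16.7/10.7 mV
at 28 °C), calcium Hill curves (SK2 740 nM/2.2, SK3 300 nM/5, SK4
95 nM/3.2, ATP-gated P2RX4 32 µM/1.6), the printed unitary conductances
(Kv6.1 12.5 pS, T-type 7.5 pS, SK4 11 pS, BK 260 pS, P2RX4 36 pS, Kir7.1
50 fS, gap junctions 85/30 pS), the gap-junction steady-conductance
Gaussians (baselines 0.35 and 0.25), the voltage-dependent CaCC Hill
parameters (K_d 360→73 nM and n 1.2→2.3 between −66 and +74 mV,
interpolated exponentially/linearly), and the pump/exchanger current laws
with their printed constants.

Where the source models' rate constants were not printed, the schemes were
constructed to satisfy the printed *apparent* curves exactly and obey
microscopic reversibility identically:

* **Kv2.1 / Kv4.3 ladders** — four voltage sensors (per-step rates
  r·exp(±(V−V_s)/2k_s)), a concerted opening step, and an allosterically
  coupled inactivated row. Each column m carries a free inactivation
  equilibrium K_I(m); the inactivated-row forward rates carry the ratio
  K_I(m+1)/K_I(m) so every square loop balances identically. A K_I profile
  peaked at partial activation yields the U-shaped (closed-state)
  inactivation of Kv2.1, weakest at strong depolarisation, with the
  seconds-scale time constants reported for this channel; for Kv4.3 the
  profile is largest at rest (A-type closed-state inactivation) and a
  deep inactivated state hangs off the chain. Sensor parameters (V_s, k_s)
  are solved numerically so the scheme's stationary open probability
  reproduces the printed apparent activation Boltzmann (+20/19.6 mV for
  Kv2.1, −7.9/12.34 mV for Kv4.3) including the shift contributed by the
  concerted step.
* **hERG** — the five-state chain (three closed states with a
  voltage-insensitive middle step, open, inactivated) with the published
  exponential rate constants for activation. The open↔inactivated
  equilibrium was moderated (recovery prefactor 0.2 ms⁻¹) and the
  open↔closed backward prefactor set to 0.0689 ms⁻¹ so that the channel's
  activation midpoint and its simulated validation current (below) are
  physiologically consistent; with the literal small-prefactor reading the
  reproduced validation current would require an effective unitary
  conductance near 600 pS, which we rejected.
* **hERG, PIP2-sensitive variant** — same topology plus a direct
  C3↔inactivated transition whose forward rate is *computed* from the loop
  (detailed balance holds by construction at every voltage, in both PIP2
  conditions). PIP2 depletion scales all activation rates by 0.35 and all
  deactivation rates by 2.5 — two parameterisations differing only in
  those two documented factors. Kir7.1's PIP2-off state scales its open
  probability by 0.15 (run-down).
* **BK α, α+β1, α+β4** — a ten-state (5 closed + 5 open) allosteric
  scheme: horizontal transitions move the four voltage sensors, vertical
  transitions open the pore with equilibrium L·Dⁱ, and fast-equilibrated
  calcium binding multiplies the opening equilibrium by
  ((1+K·C)/(1+K))⁴ with K = [Ca]/K_d. Variant parameters are set so that
  the β1 variant activates ~40 mV left of α (voltage-sensor effect, with
  higher calcium affinity) and β4 suppresses opening ~11-fold at rest and
  slows activation.
* **BK α+β3** — fifteen states (five calcium-binding levels × closed/open/
  inactivated), binding affinity increased h-fold in the conducting rows;
  all loops balance via the corresponding off-rate scaling. The conducting
  fraction counts open *and* inactivated states, following the published
  current expression for this variant literally; note this makes the
  "inactivation" of the scheme invisible in the conducted current, an
  acknowledged oddity of that expression.
* **Kv7.1** — a five-state chain with two open states and a
  voltage-independent inactivating step (no loops).
* **A-type and accessory-subunit Kv4.3 complexes, Kv9.3, Kv6.1, Kv7.4** —
  independent HH gates with the printed steady states; time-constant
  profiles (Gaussian bells in V, or constants) were chosen at the time
  scales reported for each complex (fast ~ms activation for A-types,
  0.63/3.1 s double-exponential inactivation for Kv9.3, 32 s for Kv6.1,
  slow m1·m2·m3 gating for the KCNE3 complexes).
* **L-type calcium channel** — printed activation/inactivation Boltzmanns;
  activation time constant in the cardiac-model form
  d∞·(1−e^{−(V+10)/6.24})/(0.035(V+10)); voltage-dependent inactivation
  time constant from the classical cardiac rate pair (hundreds of ms at
  depolarised potentials — an early implementation used a much faster
  profile, which suppressed regenerative firing and was corrected);
  calcium-dependent inactivation f_Ca as the standard algebraic saturating
  form. The reversal potential is the calcium Nernst potential tracking
  instantaneous [Ca²⁺]ᵢ.

### Calibrated scalars

A handful of scalars are not printed anywhere and were fixed, once, by
calibration; they are declared here and frozen in the catalogue:

* **G_Kv2.1 = 2.0 pS, G_Kv9.3 = 2.53 pS** (effective unitary
  conductances): anchored so the delayed-rectifier family (densities
  15.7 / 6 / 0.74 per pF) reproduces the reported simulated peak of
  3.77 pA/pF for a −60→+40 mV step. **G_hERG = 29.67 pS**: anchored so
  2.4 channels/pF reproduce 1.544 pA/pF at 450 ms after the same step.
* **G_CaL = 7 pS**: chosen so the cell supports regenerative plateau-type
  action potentials from slow near-threshold depolarisations (rheobase
  ≈ 0.5–0.8 pA/pF for 300-ms pulses), within the single-channel range
  reported for this channel under physiological calcium.
* **G_CaCC = 8 pS** (single-channel range reported for this chloride
  channel), activation time constant 80 ms.
* **Background conductances and pump scale** (G_bgK = 10 pS with κ = 0.5,
  G_bgCl = 60.9 pS with κ = 0.46, I_NaK,max = 2.25 pA/pF): the chloride
  leak is the free parameter balancing the tonic pump currents so the
  unforced closed loop rests at −49.5 mV with [Ca²⁺]ᵢ ≈ 85 nM (the
  experimental resting range), quiescent but excitable.
* **Free-running calcium coefficients** γ_L = 0.313, γ_T = 1.92e-4
  nM·ms⁻¹ per pA/pF, λ = 6.3e-4 ms⁻¹, consistent with the same resting
  state. Reported fits of this calcium model to myometrial recordings
  (γ_L ≈ 2251, γ_T ≈ 1.38, λ ≈ 6.3e-4) carry no printed units; read as
  nM per *second* per pA/pF they are compatible with these defaults,
  whereas nM per ms would produce 10⁵-nM transients.

### Ionic environment

Na⁺ 10/140, K⁺ 140/5.4, Ca²⁺ 100 nM/2.5 mM, Cl⁻ 140/142.7 mM (in/out).
The chloride pair follows the KCl-based internal solutions used in the
whole-cell recordings this model targets, putting E_Cl ≈ −0.5 mV; this is
why chloride currents are strongly depolarising from rest. E_K = −87.0 mV,
E_Na = +70.5 mV.

## Free-running simulation

The closed loop (V, [Ca²⁺]ᵢ, 118 gating states) is integrated with LSODA
(rtol 1e-6, atol 1e-8, max step 20 ms). The initial condition is the
whole-system equilibrium found by damped integration (100 s, no forcing)
followed by a root polish; direct root-finding from arbitrary guesses is
unreliable for the stiff Markov schemes. Forcing programs implement:

* **ATP step** — [ATP]ₒ constant over a finite window (default 10 s),
  driving the purinergic channel (default density 90 channels/pF in the
  free-running repertoire);
* **PIP2 switch** — instantaneous swap of hERG and Kir7.1 to their
  PIP2-depleted parameterisations for the switch window (default 30 s);
* **calcium sparks** — a stochastic train of logistic pulses
  A·sech²((t−T)/2w). The peak equals the drawn amplitude A exactly and the
  full width at half maximum is 3.525·w, solved from the drawn duration.
  Amplitudes are log-normal (median 30 µM, σ_log 0.4) resampled into
  [10, 80] µM, durations log-normal (median 300 ms, σ_log 0.15) in
  [200, 500] ms, and inter-event intervals log-normal (median 1 s,
  σ_log 0.3), giving ≈1 spark/s. The driven subpopulation (default 5% of
  the CaCC density) sees global-plus-local calcium; the log-normal
  parameters themselves are not published and are config-exposed.

An action potential is an upward crossing of −20 mV with a 200-ms
refractory separation (no formal AP criterion exists for these cells; this
is our operational definition). Membrane capacitance enters only to convert
per-cell channel counts to densities (50 pF).

### State-variable audit

The assembled free-running system carries 118 gating states: Kv2.1 12,
Kv9.3 3, Kv6.1 2, BK/BKβ1/BKβ4 10 each, BKβ3 15, SK2/SK3/SK4 1 each, hERG
5, CaL 2, CaT 2, CaCC 1, Kv3.4 2, Kv4.1 4, Kv4.3 13, the four Kv4.3
accessory complexes 3 each, Kv7.1 5, Kv7.4 2, Kir7.1 1, gap junctions 1+1,
P2RX4 2, and none for the ohmic backgrounds and the three pumps (+V and
[Ca²⁺]ᵢ in the closed loop). The model family we follow was originally
described with a 123-dimensional gating state, but no species-by-species
enumeration consistent with that number exists in the available
description: single-state bookkeeping for the three non-inactivating BK
variants gives 91, ten-state allosteric BK variants give 118. We document
118 and treat the difference as an unresolved bookkeeping discrepancy, not
silently absorbed.

## Calcium model fitting

The fluorescence residual is minimised in fluorescence space: candidate
parameters forward-simulate [Ca²⁺]ᵢ from the voltage trace (driving
currents evaluated at a reference calcium of 100 nM — the feedback of the
fitted transient on the driving currents is second-order) and map through
the indicator relation f = f_max·Ca/(K_d+Ca), compared at the fluorescence
sample times.

**Structural non-identifiability of K_d.** The fluorescence depends on
calcium only through Ca/K_d, and the balance equation is linear in
calcium, so the data are exactly invariant under joint scaling of
(K_d, γ_L, γ_T, Ca_init). K_d is therefore fixed by default at the
indicator's calibrated affinity (1050 nM for the high-affinity green
indicator modelled here); `fit_kd=True` profiles over a K_d grid and
returns a point on the flat valley. The remaining five parameters are
fitted by a trust-region solver seeded with a variable-projection stage
(at fixed λ the transient is linear in Ca_init, γ_L, γ_T; at fixed f_max
the fluorescence inverts to concentration), with random log-uniform
restarts. Finite-difference steps are set to 1e-4 in log-parameters so the
Jacobian rises above the ODE solver's noise floor. γ_T is only
identifiable when the recording visits hyperpolarised potentials that
de-inactivate the T-type channel; the recovery harness uses such a
waveform and still only expects γ_T within 25%.

## The synthetic generator

`synthetic.generate_waveforms` emulates a paired current-clamp/fluorescence
experiment: the free-running model itself produces the recording from a
known density vector, sampled at 1 kHz (voltage) and 30 Hz (calcium), with
optional additive Gaussian noise, reproducible from one integer seed. It
does **not** emulate electrode drift, seal leak, photobleaching,
motion artefacts, indicator buffering, or spatial calcium gradients —
passing the recovery tests therefore demonstrates correctness of the
estimation machinery (the linear algebra and the open-loop/closed-loop
consistency), not robustness to every pathology of real recordings. The
reference density vector (`table2_repertoire`) is the ℓ1-minimal estimate
reported for this cell type and is used as the generator default.

## Problem sizes

Test fixtures use 4–6 s recordings at 1 kHz (m ≈ 4000–6000, n = 31) —
large enough that m ≫ n and the rank structure matches longer recordings.
The generative-recovery check runs 10 seeded 4-s experiments. The
spark-threshold experiments bracket the minimal CaCC count by bisection
with majority voting over seeded free-running simulations (3 seeds × 15 s
per level in the test suite; 5 seeds × 20 s, bracket refined to 12%, in
`scripts/acceptance.py`). These sizes are the package's choice of a
representative experiment; the search is seed-reproducible.

## Known limitations

* Markov rate constants reconstructed from apparent curves are not unique;
  only their stationary behaviour, time scales and loop consistency are
  constrained. Kinetic details far from the fitted regimes are
  extrapolations.
* With the large chloride leak required to balance the tonic pump
  currents, spark-driven excitation in this implementation manifests as a
  depolarising staircase that reaches the AP threshold, rather than a
  crisply regenerative spike per spark; the bracketed minimal CaCC count
  (~1.5–2.5 thousand per cell at default parameters) is accordingly higher
  than the few-hundred scale suggested by the single-channel literature,
  and is sensitive to the unprinted background-conductance split.
* Spark amplitudes anywhere above ~2 µM saturate the chloride channel's
  calcium sensor (its published K_d is sub-micromolar), so the model
  cannot distinguish amplitude effects within the 10–80 µM range.
* The kernel, and hence every redundancy statement, is local to the
  driving waveform; richer behavioural repertoires generically shrink it.
* Single cell only: no gap-junctional network load (junctional currents
  are disabled by default via a zero transjunctional delay), no
  excitation–contraction coupling, no stretch feedback.
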