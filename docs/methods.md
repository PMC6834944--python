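# Methods

## The channel model

`navmex` models the cardiac sodium channel NaV1.5 as a continuous-time
Markov chain whose states resolve the position of the domain-III
voltage-sensing domain (DIII-VSD) alongside the activation/inactivation
machinery of the pore. The drug-free chain has 16 states in three DIII
regimes:

* a rested row `RC1..RC4` (DIII down),
* a first-activated row `A1C1..A1C4` (DIII partially up, fluorescence
  partially quenched),
* a fully activated A2 regime containing the canonical 8-state gating core
  `C3-C2-C1-O` with fast inactivation `IF`, closed-inactivated `IC3/IC2`
  and slow inactivation `IS`.

Only the A2 regime conducts (through `O`) or inactivates; the DIII sensor
therefore both enables opening and *guards* the local-anesthetic receptor.
Mexiletine binds exclusively from A2 states into a mirrored row of eight
non-conducting drug-bound states (the guarded-receptor picture), with the
intrinsic dissociation constant fixed at Kd = 156 uM for every construct.
Bound inactivated states are additionally stabilized by a factor `phi`
(modulated-receptor behaviour); detailed balance then fixes their unbinding
rate at `kon*Kd/phi`.

Every elementary rate follows `k(V) = A*exp(V/B)` with a numerical guard
`k <= 1e3 /ms` on [-200, +100] mV. Rates fixed by microscopic
reversibility (one per independent cycle: the pre-open step of the R/A1
rows, the IF->O recovery in each core, and the state-dependent unbinding
rates) are monomials of the elementary laws, so cycle closure is exact at
every voltage and concentration, not merely to solver tolerance.

Simulated fluorescence ("DIII-VSD activation") is
`(w1*sum(A1) + w2*(sum(A2) + sum(bound)))/total` with `w2 = 1` fixed and
`w1` fitted; only the ratio of the A1/A2 contributions is identifiable.
Drug-bound states are counted in the A2 fluorescent class, consistent with
mexiletine stabilizing the activated DIII conformation.

## Protocol dialects

All clamp protocols hold at -120 mV with ENa = +65 mV fixed in clamp mode:

* availability (SSA): 500-ms prepulses -140..-30 mV, 25-ms test to 0 mV;
* activation (GV): test pulses -80..+40 mV from holding;
* recovery from inactivation: 1-s conditioning at -20 mV, recovery at
  -100 mV over 1..10^4 ms, paired 25-ms test pulses;
* tonic block: a 10-s drug wash-in at holding starting from the drug-free
  resting state, then a single test pulse; the finite wash-in matters,
  because rested-state association is slow and part of what tonic block
  measures;
* use-dependent block: the same wash-in, then eight 400-ms pulses to
  -10 mV at 2 Hz; block read on the peak of pulse 8;
* fluorometry activation: 200-ms prepulses -200..0 mV read at the prepulse
  end (a finite acquisition window, as in the experiments - closed-state
  inactivation contributes only as far as it develops in 200 ms);
* fluorescence recovery: 20-ms pulse to +20 mV, decay at -160 mV (the
  deactivating potential of fluorometry protocols), single-exponential fit
  with free offset over a 60-ms window; mexiletine at 75 uM, the same
  concentration as the late-block protocol (the source protocol does not
  state this concentration);
* late current: |I| at the end of a 400-ms step to 0 mV; late block at
  75 uM.

Summary reductions are two-parameter Boltzmann fits (V1/2, k), Hill fits
(IC50, free Hill coefficient) and exponential fits with free offset, all
with deterministic initial guesses.

## Calibration

Calibration minimizes tolerance-normalized residuals against the registry
in `navmex/data/targets.json`, which records each experimental summary
statistic with its source quote. The procedure is staged
(`scripts/calibrate.py`):

1. **Drug-free gating per construct** - DIII step equilibria and kinetics,
   closed-inactivation position/slope, fluorescence weight and the
   late-current scale are fitted to the availability shifts, the DIII
   activation anchors, the fluorometry half-activation voltages and the
   late/peak current ratios (0.1 / 0.67 / 1.0 % for WT / M1652R / R1626P).
   Two structural guards keep the model usable in a myocyte: the resting
   window open probability at -85 mV is capped, and the equilibrium open
   probability near the plateau take-off (-35 mV) must not exceed the 0-mV
   persistent level (no re-excitation hump).
2. **Shared drug interaction** - state-class binding rates (open and
   A2-closed; inactivated-state binding is a small fitted rate),
   the modulated-receptor factor `phi` and the bound-gating kinetic
   modifiers are fitted jointly to the tonic and use-dependent IC50s of
   both mutants, the drug-induced fluorescence shifts, the fluorescence
   recovery time constants and the late-block fractions, plus the
   boosted-model block targets evaluated on a DIII-saturated variant.

The construct differences in apparent mexiletine affinity emerge from
DIII-VSD occupancy and kinetics alone: the mexiletine-sensitive R1626P
holds its DIII-VSD up at rest (high A2 occupancy, fast rested-state
association, strong interpulse retention), while the resistant M1652R sits
DIII-down at rest and sheds block between pulses through its unstable
fast-inactivated state (the IF->O escape route is ~an order of magnitude
faster than in R1626P at the holding potential).

## Booster design

The in silico "booster" retunes only the six DIII-VSD movement rates
(ax, bx, ay, by, a3, b3) of the fitted M1652R model - drug-bound
parameters and all other gating rates stay bit-identical - to produce a
15-mV hyperpolarizing shift of drug-free availability and at least a
doubling of tonic and use-dependent block at 50 uM mexiletine. The
boosted model's IC50s are reported as post-hoc outcomes, and recovery from
inactivation, fluorescence activation and late block are untargeted
predictions.

## Myocyte and fiber

The host ventricular myocyte follows the ten Tusscher-Panfilov (2006)
epicardial formulation (L-type Ca current with subspace Ca-dependent
inactivation, IKr, IKs, IK1, Ito, INaK, NCX, SERCA/leak/CICR release,
analytic Ca buffering), with the Hodgkin-Huxley sodium current replaced by
the Markov channel; ENa tracks the dynamic intracellular Na. Repolarization
reserve is calibrated with three exposed scalars - a background chloride
conductance and scales on IKr and IKs - so that the WT cell repolarizes
monotonically at BCL 2000 ms while the mutant phenotypes (marked APD
prolongation for R1626P; progressive failure of repolarization for M1652R)
are reproduced; the construct conductance gNa is chosen per construct to
give a common peak-current scale.

Numerics: fixed-rule adaptive explicit stepping (5 us during upstrokes,
20 us default, 250 us in diastole), Rush-Larsen for host gates, forward
Euler for concentrations, and backward Euler for the Markov block (solved
as a 24x24 linear system per step), which is unconditionally stable and
conserves occupancy exactly. Runs are bit-reproducible; there is no
randomness anywhere in the simulation path.

The 1D fiber couples identical myocytes through a monodomain cable term
solved by operator splitting with Crank-Nicolson diffusion (no-flux ends),
dx = 100 um and D = 1.54e-3 cm^2/ms by default. Conduction velocity is
measured between interior cells (stimulated edge excluded) from -40 mV
threshold-crossing activation times, which remain robust for slow
electrotonic fronts; conduction block is declared when the distal 20% of
the cable fails to activate.

APD90 is measured from the maximum-dV/dt instant to 90% repolarization
toward the pre-stimulus diastolic potential; failed repolarization yields
NaN and is excluded from steady-beat medians (median over the last 10
beats). An EAD is a negative-to-positive dV/dt reversal above the 90%
level followed by >= 2 mV of depolarization, with the first 120 ms after
the upstroke blanked so the epicardial notch-dome is not miscounted.

## Synthetic clamp data

`generate_synthetic_clamp_data` produces availability, activation and
fluorescence curves from known parameters with additive Gaussian noise of
configurable sd (default 0.02) on the normalized responses,
bit-reproducible for a fixed seed. It emulates sweep-averaged normalized
protocol outputs only - no capacitance/leak artifacts, no series
resistance, no cell-to-cell expression variability - so parameter-recovery
results bound identifiability under idealized acquisition, not raw-trace
fitting.

## Problem sizes

Channel-level quantities are desk-scale (seconds). Cell-level results use
40-100 beats at BCL 2000 ms; dose-response scans use reduced beat counts
once APD90 is quasi-steady. Fiber demonstrations default to 100 cells and
50 beats; the test suite exercises reduced cables (8-12 cells, 1-2 beats),
which preserve the propagation and block phenomenology.

## Known limitations

* The rate-cap guard (1e3/ms over [-200, +100] mV) bounds how steep a
  single exponential rate pair can be; equilibrium slopes much below
  ~8 mV/e-fold are not representable, which limits how compressed some
  fitted curves can be.  For R1626P the open-column DIII step (a3/b3) is
  tied to the generic step (ay/by), because free fits drove the
  reversibility-derived pre-open rate far past the cap.
* The fluorometry-derived M1652R anchors (25% activation at -120 mV, 50%
  at -80 mV, half-activation at -100 mV) are mutually tense for any
  two-step Boltzmann-like activation curve; the calibrated model
  compromises within a few percentage points of the anchors.
* Several experimental statistics could not be reproduced simultaneously
  with the ones the calibration prioritizes, because they share a single
  rested-state binding machinery:
  - with the R1626P tonic IC50 and the 4-mM M1652R fluorescence shift in
    band, the M1652R tonic IC50 is far too weak (the model's M1652R simply
    has too little resting A2 occupancy to bind), and use-dependent block
    saturates near the tonic level for both mutants once the open-state
    trapping flux is reduced enough for the cellular drug response;
  - R1626P fluorescence recovery is rate-limited by closed-inactivation
    exit; making it fast enough for the printed ~19-ms time constant
    breaks the availability curve measured with 500-ms prepulses;
  - any booster that hyperpolarizes M1652R availability by 15 mV becomes
    nearly R1626P-like in its binding, so its predicted tonic IC50 is
    several-fold stronger than the published design outcome.
* The host is an epicardial formulation with a calibrated repolarization
  reserve, not a patient-specific model; absolute APD values inherit
  host-model uncertainty.  Drug-free R1626P action potentials near one
  second sit close to a repolarization cliff in this host, where even
  modest late-current block collapses the APD: the simulated 10-uM
  mexiletine effect on R1626P (and, more weakly, M1652R) is therefore
  substantially larger than the published percentages.
* Fiber conduction velocities (19-30 cm/s) are below the physiological
  40-60 cm/s because the single-cell APD calibration pins the sodium
  conductance low; cable activation is defined by a -40 mV crossing, and
  the edge stimulus defaults to -150 A/F over five cells so that the
  proximal end fires against the cable sink.  No conduction block occurs
  for any construct at therapeutic concentrations and slow pacing.
* EAD counts near regime boundaries (long-AP alternans, failure of
  repolarization) are sensitive to the integration rules; the rules are
  fixed and deterministic, and regime-boundary beat indices are treated as
  qualitative.
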