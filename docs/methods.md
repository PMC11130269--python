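# Methods

## The mechanistic model

`naloxsim` simulates opioid-induced respiratory depression and its reversal
by intranasal naloxone for one virtual subject under one dosing scenario.
Five coupled components are integrated on a common seconds time axis:

**Opioid pharmacokinetics.** An IV bolus enters the central compartment of a
linear three-compartment model in amounts (mg):

    dP_F/dt  = K21·P_F2 + K31·P_F3 − (K12 + K13 + K_out)·P_F
    dP_F2/dt = K12·P_F − K21·P_F2
    dP_F3/dt = K13·P_F − K31·P_F3

with `P_F(0)` equal to the opioid dose.

**Naloxone pharmacokinetics.** Intranasal absorption is delayed through two
transit compartments feeding a central concentration `P` (mg/L):

    dT1/dt = K_tr·D·F·exp(−K_tr(t − t_d)) − K_tr·T1
    dT2/dt = K_tr·T1 − K_in·T2
    dP/dt  = (K_in/V)·T2 − (C_L/V)·P

`D` is the dose per administration and `F` the intranasal bioavailability.
Multiple administrations superpose the forcing term with shifted time
origins, which is exact because the chain is linear in its input.  The
integration is split at each administration time so the forcing
discontinuity always lands on a segment boundary.

**Biophase transition.** Each drug's effect-site concentration `L` (pM)
equilibrates with its central compartment at a first-order rate `k1`:

    dL/dt = k1·(C_plasma·1e9/M − L)

where `C_plasma` is `P_F/V_c` (mg/L) for the opioid and `P` directly for
naloxone, and `M` is the drug's molar mass; `1 mg/(L·g/mol) = 1e9 pM`
motivates the scaling.  Each drug uses its own molar mass and `k1`.

**Competitive receptor binding.** Both ligands compete for the mu opioid
receptor through Hill-type kinetics sharing the free fraction
`R = 1 − r_op − r_nx`:

    dr_op/dt = k_on·L_op^n·R − k_off·r_op      (and symmetrically for naloxone)

**Pharmacodynamics.** Fractional minute ventilation is
`V_F = 1 − α·r_op`, with agonism coefficient `α = 1` for a full agonist.

**Rescue event.** The first naloxone administration is placed at the first
downward crossing of `V_F` through the scenario threshold.  The crossing is
found by the integrator's event root-finder on the dense solution, so its
localization error is far below the 1 s `event_tol` contract.  Dose `k` of
`n` lands at `t_cross + (k−1)·delay`.  If the threshold is never reached,
no naloxone is given and the scenario is still valid.

Integration uses LSODA (stiff-capable, adaptive) with defaults
`rtol 1e−8 / atol 1e−10` on a 1 h horizon sampled every 10 s.  Occupancies
are clipped to `[0,1]` at output (integrator noise is below 1e−8).
Verified invariants: occupancy conservation, non-negativity, agreement with
the matrix-exponential closed form of the opioid block (1e−8 relative),
with the algebraic competitive equilibrium under clamped concentrations
(1e−4), with the single-ligand relaxation exponential (1e−6), and transit
chain mass balance `∫K_in·T2 dt → D·F` (1e−4 relative).

## Default parameters

Published estimates for this model family are cited rather than printed in
the sources this package draws on, so the shipped defaults
(`naloxsim/data/default_parameters.yaml`) are explicit stand-ins: a
fentanyl-like three-compartment PK block (V_c 12.7 L, minute-scale
distribution rates), an intranasal naloxone block shaped like labeled
NARCAN concentration profiles (V 200 L, CL 2.5 L/min, F 0.5, transit rates
giving a ~20 min absorption peak), and pM-scale binding (opioid Kd 100 pM,
naloxone Kd 150 pM, Hill slopes 1).  They were chosen once for clinical
plausibility — a 0.11 mg carfentanil-like bolus collapses ventilation
within ~2 min, and 4 mg intranasal naloxone produces a nadir shortly after
administration followed by clear reversal within the hour — and are treated
as configuration everywhere.  No number in that file is a fitted or
published estimate; conclusions drawn from these simulations are about the
model's structure and the emulation methodology, not about real drugs.

## Virtual populations

A virtual subject is one draw of all kinetic parameters.  The original
joint bootstrap/literature distributions are not available, so the sampler
uses independent log-normal draws per parameter with the median at the
default value and a shared coefficient of variation (default 20%, a typical
inter-individual PK variability scale).  Structural constants (molar
masses, α) are fixed; bioavailability is clipped to (0, 1].  One master
seed spawns an independent stream per subject (`numpy.random.SeedSequence`),
so populations are reproducible, order-stable, and extensible.  What this
generator does not emulate: correlation between parameters (a real
bootstrap joint distribution has it), multimodality, and covariate
structure — so passing tests demonstrate the machinery, not population
realism.

## Study design and feature encoding

The dosing grid crosses opioid dose (12 levels evenly spaced over
0.013–0.157 mg, spacing our choice), naloxone dose count (0–4), rescue
threshold (40/25/10% of baseline), and inter-dose delay (2/3/5 min):
540 cells; with 2000 subjects, 1 080 000 records.  Degenerate cells
(count 0, or count 1 where delay is inert) are retained as distinct grid
cells.  The naloxone dose per administration defaults to 4 mg.

Each record's input is min–max normalized per feature into three blocks:
opioid (7 PK parameters + dose), naloxone (6 PK parameters + the four
scenario factors), binding (6 parameters).  Scenario factors are fed as raw
design factors, not realized administration times, which depend on the
subject.  Features outside the normalization bounds (e.g. a test population
normalized with training bounds) are clipped with a logged warning.
Targets are occupancy trajectories, the quantity the PD map converts to
ventilation.

## Emulators

Both architectures are built on a compact numpy neural-network engine
(dense and LSTM layers with exact backpropagation through time, Adam,
global-norm gradient clipping at 5).  Static inputs drive the recurrent
layers by repetition at every unrolled step — the standard way to decode a
sequence from a static conditioning vector.  Occupancy outputs pass through
a logistic squashing so predictions live in [0, 1].  Initialization is
Glorot-uniform with forget-gate bias 1, seed-deterministic.

* Black-box: all features concatenated → tanh dense layer (default 128
  units) → LSTM (default 64) → per-step logistic scalar.
* Semi-mechanistic: opioid block → LSTM track; naloxone block → LSTM
  track; per-step track outputs concatenated with the binding block →
  final LSTM → per-step logistic scalar.  No dense hidden layer.  The two
  tracks are the learned analogs of the drugs' effect-site trajectories and
  are exposed via `track_activations`; by construction there is no
  parameter path from naloxone inputs to the opioid track (verified
  bitwise under perturbation).

Training minimizes mean squared occupancy error.  Every epoch withholds a
fresh random 10% of the records and reports its error; reported errors are
squared error summed over time points, averaged over records (an error
*scale* choice — only orderings between models are meaningful).  The
learning rate follows a cosine schedule from 3e−3 down to 5% of that over
the epoch budget, so the final-epoch error reflects converged performance
rather than step noise.  Per-epoch randomness is derived from
(seed, global epoch index), which makes training resumable and exactly
reproducible.

## Baseline and evaluation

The PLSR baseline maps the concatenated feature vector to the flattened
trajectory; the component count (1..max, default 10) is chosen by k-fold
cross-validated MSE (default 15 folds) and predictions are clipped to
[0, 1].  Populations are summarized by pointwise median and 2.5/97.5
percentiles of ventilation (the "95% band"); models are scored by the RMSE
of each summary curve against the mechanistic one, per scenario and pooled
over all time points of all scenarios before the root.

## The reduced head-to-head experiment

The full-scale study (2000×540, multi-day training) is summarized at desk
scale with its structure intact: 100-subject train and test populations
(disjoint seeds, test features normalized with training bounds), a 36-cell
sub-grid (4 doses × 3 counts × 3 thresholds × 1 delay) spanning the factor
ranges, a 61-point output grid (60 s steps), integrator tolerances
1e−6/1e−9 (occupancy targets accurate to ~1e−5, far below emulator error),
widths 16 recurrent / 32 dense, 80 epochs, batch 64, three seeds.  Both
architectures get identical budgets and matched seeds; the 80-epoch budget
lies past the point where both holdout curves have flattened under the
cosine schedule, so the final error is a plateau value rather than a
mid-descent snapshot.  BLAS is pinned to one thread during these runs so
results reproduce bit-for-bit on any host.  The experiment asserts
orderings only — semi-mechanistic final holdout error below black-box in
every seed, and both emulators' median-trajectory RMSE below PLSR's —
never absolute error values, which are scale- and hardware-bound.  A
caveat the full-scale study does not face: at 3 600 training records the
black-box network can eventually close most of the gap, so per-seed final
margins at the plateau are modest (tens of percent down to a few percent),
and the ordering should be read as the expected direction, not a large
guaranteed separation.

## Known limitations

* Stand-in parameters: all kinetic values are plausible placeholders, not
  estimates; absolute simulated times/levels have no clinical standing.
* Independent log-normal population sampling ignores parameter
  correlations.
* The emulator engine is deliberately small (single-layer LSTMs, CPU
  numpy); it is not a general deep-learning framework.
* The PD map is the single-equation ventilation model; the fuller
  translational physiology (CO₂ dynamics, additional opioids and
  formulations) is out of scope.
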