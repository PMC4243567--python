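# Methods

## Scope and model tiers

`striatnet` reconstructs a striatal microcircuit — medium spiny neurons
(MSNs) receiving lateral (MSN→MSN) and feedforward (FSI→MSN) GABAergic
inhibition — at two levels of fidelity:

1. **Exact structural tier.** Cell morphologies (compartment counts and
   branch-order structure), spatial placement, distance-gated stochastic
   connectivity, contact-count distributions, synapse placement zones,
   conduction delays, and the jitter-and-shift input generator follow
   the published anatomical and statistical rules exactly, and the
   package's quantitative claims live here.
2. **Reduced dynamics tier.** Membrane dynamics are passive
   multicompartment cables with a leaky-integrate-and-fire (LIF) soma
   surrogate and two-state conductance synapses. The detailed
   single-cell models this replaces carry over a dozen voltage- and
   calcium-gated currents; we deliberately do not reproduce them.
   Consequences of network inhibition are therefore asserted
   *directionally* (signs of effects in paired simulations), never as
   numeric matches to full-biophysics results.

## Morphology

The MSN scaffold has 189 compartments: 1 soma, 4 primary dendrites (1
compartment each), 8 secondary dendrites (1 each), and 16 tertiary
dendrites of 11 compartments each. The FSI scaffold has 148
compartments: 1 soma, 3 primary dendrites of 3 compartments, 6
secondary of 5, and 12 tertiary of 9. The branching multiplicities
follow the binary-branching pattern of the underlying single-cell
lineages (each primary bifurcates into two secondaries, each secondary
into two tertiaries); for the FSI this is also the unique pattern of
the form (P, 2P, 4P) satisfying 1 + 49·P = 148. Both are configurable.

Compartment dimensions are generic defaults (MSN: 16 µm soma, ~190 µm
soma-to-tip dendritic path; FSI slightly smaller and thinner), because
the source morphologies defer dimensions to earlier single-cell work.
They only affect the reduced dynamics tier. Spines are not modeled;
their membrane-area contribution enters as a ×2 area multiplier on
secondary/tertiary compartments (`spine_scale`).

Synapse placement zones: lateral contacts target secondary+tertiary
compartments; feedforward contacts target soma+primary; cortical drive
covers the whole FSI but only the dendrites (non-soma) of the MSN.

## Network construction

MSN somata sit on an `n³` cubic lattice with 20 µm spacing (default
n = 14, i.e. 2744 cells; desk-scale experiments use n = 8, 512 cells).
The 20 µm spacing is taken as binding; the nominal 280 µm tissue-cube
edge is read as the extent including margins. FSIs number
⌊n_MSN·4/90⌋ (121 at full scale) and are placed uniformly at random in
the lattice bounding cube.

Wiring (one independent Bernoulli draw per ordered pair):

| pathway | gate | probability | contacts | placement | delay |
|---|---|---|---|---|---|
| lateral MSN→MSN | ≤ 380 µm | 0.155 | 1–3 with pmf (0.83, 0.13, 0.04) | uniform over secondary+tertiary | 2.4 ms |
| feedforward FSI→MSN | ≤ 250 µm | 0.25 | uniform on {7,…,12} | uniform over soma+primary | 2.4 ms |

Self-connections are forbidden; reciprocal pairs are allowed;
projections never wrap across the cube boundary, so peripheral cells
receive fewer afferents — a property the tests assert on a cube wider
than the 380 µm radius. Contacts are sampled per-compartment with
replacement (uniform over compartments, not membrane length); nothing
in the source rules forbids two contacts of one connection sharing a
compartment. Cortical input synapses are assigned uniformly at random:
84 glutamatergic (AMPA/NMDA pairs) + 84 GABAergic per FSI, 84
glutamatergic per MSN (configurable).

All randomness descends from a single master seed through named
sub-streams (placement, lateral, feedforward, cortical, inputs), so
each construction stage is independently reproducible and a run
manifest suffices to rebuild a network bit-exactly (verified via a
SHA-256 digest of the canonical JSON serialization).

## Input generation

Each synapse receives an independent spike train built as: constant-ISI
scaffold at the desired frequency → per-spike Gaussian re-draw (sd
`jitter_sd`) → single uniform global shift on [0, `shift_max`].
Uncorrelated input uses `jitter_sd = ISI/4` and `shift_max = ISI`.
This family, unlike a Poisson process, can realize partially
synchronized but still randomized drive.

Boundary conventions (the source algorithm is silent on them; all are
tested): without a shift the scaffold starts at t = ISI; with a shift
the scaffold additionally covers the shift margin and includes the
i = 0 spike, which the shift slides into (0, shift] — this keeps the
windowed rate stationary at the nominal frequency (otherwise every
train would systematically lose about one spike per window). Jittered
spikes are re-sorted; spikes landing outside [0, duration] are dropped,
never wrapped. The re-draw replaces spikes and cannot thin them except
at the window edges.

Per-synapse frequencies are the configured per-cell summed
glutamatergic rate divided by the synapse count (84), so "1000 Hz
input" means 1000 summed glutamatergic events per second per cell,
matching the glutamatergic-only accounting used for the rate-sweep
experiments.

Structured conditions:

* **Ensemble drive**: the first ⌈fraction·n⌉ MSNs (default half) each
  receive, on 6 of their cortical synapses, one shared, precisely timed
  8 Hz train at twice the noise-synapse weight, AMPA-only (a brief kick
  rather than a sustained NMDA tail). Calibrated once so ensemble cells
  respond with ~1–2 spikes per cycle at ~5 ms pooled timing SD.
* **Synchronized FSIs**: every FSI receives the bit-identical input
  set — a deterministic burst schedule (default: a burst every 125 ms,
  8 spikes at 2 ms spacing) on 8 synapses, the rest silent — so all
  FSIs fire lockstep bursts at ~60 Hz mean. **Desynchronized FSIs**
  receive distinct uncorrelated trains summing to 600 Hz, yielding a
  comparable ~60–100 Hz mean rate.

## Reduced simulator

Passive cable parameters: Cm = 1 µF/cm², Rm = 20 kΩ·cm² (τm = 20 ms),
Ra = 100 Ω·cm. LIF surrogate at the soma: MSN rest −80 mV, threshold
−45 mV, reset −55 mV, refractory 2 ms; FSI rest −70 mV, threshold
−50 mV, reset −62 mV, refractory 1.2 ms. These place the MSN in a
hyperpolarized down-state-like rest and make the FSI the more excitable
cell, without claiming biophysical detail.

Synapses are peak-normalized differences of exponentials
g(t) = g_max·N·(e^(−t/τ_d) − e^(−t/τ_r)) with linear summation per
compartment: AMPA (0.5/2.5 ms, E = 0), NMDA (2/80 ms, E = 0, no
magnesium block by default), GABA-A (0.5/7.5 ms, E = −60 mV). The
−60 mV GABA reversal sits above the MSN resting potential, so GABAergic
events depolarize hyperpolarized cells and hyperpolarize depolarized
ones — the voltage-dependent IPSP sign the analysis relies on.

Per-contact conductances are the reduced tier's calibration, chosen
once: g_AMPA = 0.58 nS, g_NMDA = 0.03 nS, g_GABA-A = 0.45 nS (one
shared value for lateral and feedforward contacts), with FSI
glutamatergic weights scaled ×0.7. The calibration targets three
operating points: ~6.5 Hz MSN firing at 1000 Hz summed drive, ~60 Hz
FSI firing at 600 Hz drive, and single lateral IPSPs within roughly
±0.2 mV at the soma (feedforward IPSPs then land near ±1–2 mV).

Integration is backward Euler with a Hines-style O(n) tree solve per
cell, vectorized across cells and JIT-compiled (numba, with a pure
NumPy fallback). Conductances are held constant across a step; events
are quantized to the step grid (delays applied before quantization).
Default dt = 0.1 ms for network runs and 0.025 ms for IPSP studies;
a self-convergence test bounds the dt = 0.1 → 0.05 trace change.
Presynaptic spikes enter target conductance states after the 2.4 ms
delay via a ring buffer; the `lateral_on` / `feedforward_on` toggles
gate only this recurrent event delivery, so paired ON/OFF runs are
otherwise bit-identical — the subtraction of their traces isolates one
inhibition kind exactly.

## IPSP protocol and analysis

The paired-subtraction protocol drives exactly one presynaptic cell (a
central MSN for lateral, a central FSI for feedforward) above threshold
with a soma current while every other MSN is held at a distinct
subthreshold potential spanning −75…−50 mV. Holding is realized as
per-cell constant soma currents with each cell initialized at its exact
steady-state profile (the cable is linear, so the profile is
EL + bias·unit-response); literal subthreshold noise trains would
cancel identically in the ON−OFF subtraction, so holding currents give
the same baselines deterministically. IPSPs are extracted from the
first presynaptic spike only: the ON−OFF somatic difference over a
window after the spike (capped at the presynaptic inter-spike
interval), signed amplitude = whichever of max/min has the larger
absolute value; identically zero differences are flagged excluded, not
reported as zero-amplitude IPSPs.

IPSP time courses are fitted with V = scale·(e^(−t/T1) − e^(−t/T2)) by
least squares. R² = 1 − SS_res/SS_tot on the fitted window (the
convention is stated because the source leaves it open); fits with
R² < 80 % are discarded. The form is symmetric under
(T1,T2,scale) → (T2,T1,−scale); results are canonicalized to T1 ≥ T2.
Amplitude is a free scale parameter — no pre-normalization. The
one-sample z-test uses z = (mean − µ0)/(sd/√n) with the open
equivalence band (−1.96, 1.96); |z| = 1.96 exactly is not equivalent.

Peri-event histograms count every (spike, event) pair whose offset
falls in the window; edge events keep truncated windows rather than
being dropped. Suppression fractions count subset spikes in
(event+5, event+30] ms by default, ON over OFF. Ensemble spike-timing
SD pools offsets to the rhythm event over all events, population
(n-denominator) convention, over a (0, 25] ms response window.

## Experiment designs and what passing shows

All three runners default to the 512-MSN network and complete on one
CPU in minutes; problem sizes in the test suite are chosen so the whole
suite stays well under typical CI budgets (216–512 MSNs, 1–1.5 s of
simulated time).

* **rate_curves**: unstructured drive swept over frequencies including
  the 800–1100 Hz band, paired toggled runs. Expected directions:
  lateral ON lowers the mean MSN rate and raises the across-cell rate
  SD at high input.
* **lateral_ensemble**: half the MSNs entrained by the shared 8 Hz
  rhythm, lateral toggled. Expected: non-ensemble spiking within
  5–30 ms of the rhythm event is deeply suppressed with lateral ON, and
  the ensemble's pooled spike-timing SD does not increase.
* **feedforward** (synchronized vs desynchronized FSIs, feedforward
  toggled): non-ensemble MSNs are suppressed more than ensemble MSNs,
  and desynchronized FSIs suppress total MSN spiking at least as much
  as synchronized FSIs at comparable mean FSI rates.

Two design choices keep these contrasts measurable in the reduced
tier. First, each paired contrast toggles one inhibition kind with the
*other* kind inactive in both arms: under passive/LIF dynamics the full
feedforward load (≈116 proximal contacts per MSN at ~60 Hz FSI rates)
silences MSNs outright — the detailed models' intrinsic currents, which
sustain firing under that load, are exactly what this tier omits — and
a silenced baseline leaves nothing to measure. Second, the rate sweep
drives FSIs at 300 Hz (their rate-sweep operating point), where the
reduced FSI is nearly silent.

What passing does **not** show: the synthetic conditions have no
D1/D2 subtypes, no FSI–FSI gap junctions, no dopamine or plasticity,
stationary input statistics, and reduced membrane dynamics; numeric
network outcomes of the full-biophysics model (e.g. exact percentage
rate reductions or remaining-spike fractions) are out of reach here and
are not asserted.

## Numerical and degenerate-input conventions

* Backward Euler is unconditionally stable for the stiff axial
  couplings (g_ax/C up to ~50 ms⁻¹ in thin tertiary branches).
* Non-finite membrane state aborts a run with a diagnostic.
* The double-exponential fitter seeds T1, T2 from the trace's peak
  time, bounds both in (10⁻³, 10⁴) ms, and reports optimizer failure as
  a rejected fit (R² = −∞) rather than raising.
* Zero sample variance or n < 2 are errors for the z-test; an empty
  event list is an error for peri-event statistics; a zero OFF-count is
  an error for suppression fractions.
* Refractory cells are clamped to the reset potential; threshold
  crossings during the refractory period are ignored.
* Fit acceptance threshold (R² ≥ 0.80), suppression window (5–30 ms),
  and the (−1.96, 1.96) equivalence band are fixed study constants.

## Known limitations

* The per-MSN afferent means printed for the full network (~425 source
  cells / ~513 lateral contacts per MSN) follow from the stated
  probability rules; the source's own printed means (430 cells / 636
  contacts) are not exactly reconcilable with those rules, and the
  package reports rather than asserts them.
* The FSI count follows the ⌊n·4/90⌋ ratio rule (121 at full scale);
  an alternative printed figure of 144 is inconsistent with that rule
  and is not used.
* The stated tissue density (88,900 cells/mm³) conflicts with the 20 µm
  spacing (~125,000/mm³); spacing is binding.
* LIF spike initiation makes the reduced F–I curve much steeper than a
  real MSN's; absolute rates are calibration artifacts, only paired
  contrasts are meaningful.
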