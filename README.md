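# striatnet

A desk-scale model of the striatal microcircuit for studying **lateral**
(medium spiny neuron → medium spiny neuron) and **feedforward**
(fast-spiking interneuron → medium spiny neuron) GABAergic inhibition.

The striatum's principal projection neurons (MSNs) inhibit one another
through sparse, weak, distal contacts, while parvalbumin-expressing
fast-spiking interneurons (FSIs) inhibit MSNs through strong clusters
of proximal contacts. How these two inhibition systems shape which MSN
ensembles fire — and when — is hard to probe experimentally. This
package builds the circuit's anatomy exactly as the quantitative
literature describes it, replaces the heavy single-cell biophysics with
a reduced passive-cable + integrate-and-fire tier, and packages the
measurement procedures (IPSP extraction and fitting, peri-event
suppression statistics) so the functional claims about both inhibition
systems can be exercised as testable properties.

## The model in brief

* **Cells.** MSN: 189 compartments (1 soma, 4 primary, 8 secondary, 16
  tertiary dendrites of 11 compartments). FSI: 148 compartments
  (1 soma, 3×3 primary, 6×5 secondary, 12×9 tertiary).
* **Space.** MSNs on a cubic lattice, 20 µm spacing (14³ = 2744 cells
  at full scale, 8³ = 512 at desk scale); FSIs uniform at random,
  4 FSIs per 90 MSNs.
* **Wiring.** Lateral: ordered MSN pairs within 380 µm connect with
  p = 0.155, making 1–3 contacts (83 / 13 / 4 %) on secondary/tertiary
  dendrites. Feedforward: FSI→MSN pairs within 250 µm connect with
  p = 0.25, making 7–12 contacts (uniform) on soma/primary. Delays
  2.4 ms; no self-connections; no wrap-around at the boundary.
* **Inputs.** Jitter-and-shift trains: a constant-ISI scaffold, a
  Gaussian re-draw of each spike (sd = ISI/4 for uncorrelated drive),
  then a uniform global shift (up to one ISI). Structured variants add
  a shared, precisely timed 8 Hz rhythm to an MSN ensemble, or drive
  all FSIs with bit-identical burst schedules.
* **Dynamics.** Passive cable (backward-Euler Hines solve, numba-JIT)
  with a spiking-soma surrogate; two-state AMPA/NMDA/GABA-A
  conductance synapses, GABA-A reversal −60 mV, one shared per-contact
  GABA-A conductance for lateral and feedforward contacts.
* **Measurements.** Paired simulations with one inhibition kind toggled
  isolate its effect exactly. IPSPs are the extrema of ON−OFF somatic
  differences after the first presynaptic spike; time courses are
  fitted with V = scale·(e^(−t/T1) − e^(−t/T2)), fits with R² < 80 %
  discarded; a one-sample z-test with the (−1.96, 1.96) band tests
  equivalence; peri-event histograms and 5–30 ms suppression fractions
  quantify population effects.

See `docs/methods.md` for assumptions, calibration, numerics, and
limitations.

## Worked example

```python
import numpy as np
from striatnet import build_network, PlacementParams
from striatnet.netbuild import network_summary
from striatnet.experiments import ipsp_experiment

# 512-MSN desk-scale network
net = build_network(PlacementParams(n_per_side=8, seed=3), seed=3)
s = network_summary(net)
print(f"{s['n_msn']} MSNs, {s['n_fsi']} FSIs")
print(f"lateral realized p = {s['lateral']['realized_p']:.4f}")

# paired-subtraction IPSP protocol, one spiking MSN then one spiking FSI
lat = ipsp_experiment("msn", n_per_side=8, seed=3, duration=200.0, dt=0.05)
ff = ipsp_experiment("fsi", n_per_side=8, seed=3, duration=200.0, dt=0.05)
print(f"lateral IPSPs: n={len(lat.amplitudes)}, "
      f"median |A| = {np.median(np.abs(lat.amplitudes)):.3f} mV")
print(f"feedforward IPSPs: n={len(ff.amplitudes)}, "
      f"median |A| = {np.median(np.abs(ff.amplitudes)):.3f} mV")
print(f"feedforward/lateral ratio = "
      f"{np.median(np.abs(ff.amplitudes)) / np.median(np.abs(lat.amplitudes)):.1f}x")
```

Output:

```
512 MSNs, 22 FSIs
lateral realized p = 0.1551
lateral IPSPs: n=76, median |A| = 0.061 mV
feedforward IPSPs: n=125, median |A| = 0.724 mV
feedforward/lateral ratio = 11.8x
```

The lateral IPSPs are small (±0.2 mV scale, sign depending on whether
the postsynaptic cell is held above or below the −60 mV GABA reversal);
the feedforward IPSPs from a single FSI are roughly an order of
magnitude larger despite the identical per-contact conductance, because
an FSI makes 7–12 proximal contacts where an MSN makes 1–3 distal ones.

A command-line interface mirrors the library:

```bash
striatnet build --n-per-side 8 --seed 3 --out net.json
striatnet gen-inputs --network net.json --msn-hz 1000 --out inputs.tsv
striatnet simulate --network net.json --inputs inputs.tsv --duration 1000 --record all
striatnet experiment --experiment lateral_ensemble --seed 5 --out-dir out/
```

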