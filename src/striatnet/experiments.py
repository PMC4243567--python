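"""Experiment runners at desk scale.

Wires network construction, input generation, the reduced simulator and
the analysis procedures into the three study designs:

* ``rate_curves`` — paired inhibition ON/OFF runs across a sweep of
  unstructured input frequencies; reports mean rate and across-cell
  rate SD per condition.
* ``lateral_ensemble`` — half the MSNs form a partially synchronized
  ensemble (shared precisely timed 8 Hz rhythm on top of distinct
  noise), lateral inhibition toggled; reports peri-event histograms,
  suppression fractions and the pooled ensemble spike-timing SD.
* ``feedforward`` — feedforward inhibition toggled under synchronized
  (bit-identical burst input; all FSIs in lockstep) or desynchronized
  (distinct 600 Hz noise) FSI drive; reports ensemble vs non-ensemble
  suppression fractions.

The desk default is the 512-MSN network (n_per_side = 8); full
2744-cell runs work but take correspondingly longer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import analysis
from .inputs import (
    EnsembleInputPlan,
    FsiInputPlan,
    ensemble_inputs,
    generate_train,
    synchronized_fsi_inputs,
    uncorrelated_spec,
)
from .netbuild import (
    KIND_CORTICAL_GABA,
    KIND_CORTICAL_GLUT,
    Network,
    PlacementParams,
    build_network,
    stage_seed,
)
from .simulator import (
    CellDynamics,
    PairedRun,
    SimConfig,
    StimSet,
    SynapseParams,
    default_synapses,
    paired_ipsp_run,
    run_network,
)

__all__ = [
    "ExperimentConfig",
    "cortical_stim",
    "steady_soma_response",
    "input_resistance",
    "ipsp_experiment",
    "run_rate_curves",
    "run_lateral_ensemble",
    "run_feedforward",
]

#: number of cortical synapses per cell (glutamatergic; FSIs also get
#: an equal count of GABAergic synapses, the 1:1 ratio)
N_GLUT_MSN = 84
N_GLUT_FSI = 84
N_GABA_FSI = 84

#: gain of the shared-rhythm synapses relative to a noise synapse
RHYTHM_GAIN = 2.0

#: FSI glutamatergic weight scale relative to MSN synapses (calibration
#: of the reduced tier: FSIs are far more excitable than MSNs)
FSI_GLUT_SCALE = 0.7


@dataclass
class ExperimentConfig:
    experiment: str = "rate_curves"
    n_per_side: int = 8
    duration: float = 2000.0  # ms
    dt: float = 0.1  # ms
    msn_input_hz: float = 1000.0  # summed glutamatergic drive per MSN
    fsi_input_hz: float = 600.0  # summed glutamatergic drive per FSI
    fsi_gaba_hz: float = 600.0  # summed GABAergic drive per FSI
    rhythm_freq: float = 8.0  # Hz
    ensemble_fraction: float = 0.5
    n_rhythm_syn: int = 6  # synapses per ensemble cell carrying the rhythm
    fsi_burst_period: float = 125.0  # ms
    fsi_spikes_per_burst: int = 8
    input_freqs: tuple = (400.0, 600.0, 800.0, 1000.0, 1100.0)
    toggle: str = "lateral"  # which inhibition kind the paired runs flip
    suppression_window: tuple[float, float] = (5.0, 30.0)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for f in (self.msn_input_hz, self.fsi_input_hz, self.rhythm_freq):
            if f <= 0:
                raise ValueError("input frequencies must be positive")


# ---------------------------------------------------------------------------
# stimulation assembly
# ---------------------------------------------------------------------------

def cortical_stim(
    network: Network,
    duration: float,
    seed: int,
    msn_glut_hz: float,
    fsi_glut_hz: float = 600.0,
    fsi_gaba_hz: float = 600.0,
    ensemble_plan: EnsembleInputPlan | None = None,
    n_rhythm_syn: int = 6,
    rhythm_gain: float = RHYTHM_GAIN,
    fsi_plan: FsiInputPlan | None = None,
    synapses: dict[str, SynapseParams] | None = None,
    fsi_glut_scale: float = FSI_GLUT_SCALE,
) -> StimSet:
    """Attach jitter-and-shift input trains to every cortical synapse.

    Per-synapse train frequencies are the per-cell summed rate divided
    by the synapse count, so the configured total is the summed
    glutamatergic rate per cell.  Glutamatergic synapses are AMPA/NMDA
    pairs driven by the same train.  Ensemble members additionally
    receive the plan's shared rhythm train on ``n_rhythm_syn`` of their
    synapses at ``rhythm_gain`` times the noise-synapse weight.
    """
    syn = synapses or default_synapses()
    g_ampa = syn["AMPA"].g_max
    g_nmda = syn["NMDA"].g_max
    g_gaba = syn["GABA_A"].g_max
    stim = StimSet()
    n_msn = network.n_msn
    rng_root = stage_seed(seed, "inputs")
    children = iter(rng_root.spawn(
        n_msn * N_GLUT_MSN + network.n_fsi * (N_GLUT_FSI + N_GABA_FSI)
    ))

    cort = network.connections.select(KIND_CORTICAL_GLUT)
    gaba = network.connections.select(KIND_CORTICAL_GABA)
    if len(cort) == 0:
        raise ValueError("network was built without cortical input synapses")

    # group synapse compartments by target cell
    def comps_by_target(table):
        comps: dict[int, list[int]] = {}
        for i in range(len(table)):
            lo, hi = table.contact_offsets[i], table.contact_offsets[i + 1]
            comps.setdefault(int(table.target[i]), []).extend(
                int(c) for c in table.contact_comp[lo:hi]
            )
        return comps

    glut_comps = comps_by_target(cort)
    gaba_comps = comps_by_target(gaba)

    per_syn_msn = msn_glut_hz / N_GLUT_MSN
    per_syn_fsi = fsi_glut_hz / N_GLUT_FSI
    per_syn_fsi_gaba = fsi_gaba_hz / N_GABA_FSI

    # "identical" FSI drive means the complete input set — trains AND
    # synapse locations — is duplicated bit-exactly on every FSI, so
    # lockstep somatic trajectories follow; use the first FSI's synapse
    # compartments and one shared GABA train set for all of them
    identical_fsi = fsi_plan is not None and fsi_plan.mode == "identical"
    fsi_targets = sorted(t for t in glut_comps if t >= n_msn)
    if identical_fsi and fsi_targets:
        ref_glut = glut_comps[fsi_targets[0]]
        ref_gaba = gaba_comps[fsi_targets[0]]
        shared_gaba_seeds = stage_seed(seed, "inputs").spawn(len(ref_gaba))
        shared_gaba_trains = [
            generate_train(uncorrelated_spec(per_syn_fsi_gaba, duration, seed=c))
            for c in shared_gaba_seeds
        ]
        for tgt in fsi_targets:
            glut_comps[tgt] = ref_glut
            gaba_comps[tgt] = ref_gaba

    for tgt, comps in glut_comps.items():
        if tgt < n_msn:  # MSN
            for j, comp in enumerate(comps):
                spec = uncorrelated_spec(per_syn_msn, duration, seed=next(children))
                train = generate_train(spec)
                stim.add_train("msn", tgt, comp, "AMPA", train, g_ampa)
                stim.add_train("msn", tgt, comp, "NMDA", train, g_nmda)
            if ensemble_plan is not None and ensemble_plan.is_ensemble(tgt):
                # rhythm synapses are AMPA-only: a brief, precisely timed
                # kick rather than a sustained NMDA tail
                for comp in comps[:n_rhythm_syn]:
                    stim.add_train("msn", tgt, comp, "AMPA",
                                   ensemble_plan.shared_rhythm, g_ampa * rhythm_gain)
        else:  # FSI
            fsi_id = tgt - n_msn
            for j, comp in enumerate(comps):
                if fsi_plan is not None:
                    train = fsi_plan.trains[fsi_id][j % len(fsi_plan.trains[fsi_id])]
                    next(children)  # keep the seed stream aligned across modes
                else:
                    train = generate_train(
                        uncorrelated_spec(per_syn_fsi, duration, seed=next(children)))
                stim.add_train("fsi", fsi_id, comp, "AMPA", train, g_ampa * fsi_glut_scale)
                stim.add_train("fsi", fsi_id, comp, "NMDA", train, g_nmda * fsi_glut_scale)

    for tgt, comps in gaba_comps.items():
        fsi_id = tgt - n_msn
        for j, comp in enumerate(comps):
            if identical_fsi:
                train = shared_gaba_trains[j]
                next(children)  # keep the seed stream aligned across modes
            else:
                train = generate_train(
                    uncorrelated_spec(per_syn_fsi_gaba, duration, seed=next(children)))
            stim.add_train("fsi", fsi_id, comp, "GABA_A", train, g_gaba)

    return stim


# ---------------------------------------------------------------------------
# paired-subtraction IPSP protocol
# ---------------------------------------------------------------------------

def steady_state_profile(dyn: CellDynamics, bias_pA: float) -> np.ndarray:
    """Per-compartment steady-state voltages under a constant soma current
    (exact linear solve of the passive cable)."""
    n = dyn.n_comp
    G = np.diag(dyn.gL.astype(float))
    for i in range(1, n):
        p = dyn.parent[i]
        G[i, i] += dyn.g_ax[i]
        G[p, p] += dyn.g_ax[i]
        G[i, p] -= dyn.g_ax[i]
        G[p, i] -= dyn.g_ax[i]
    rhs = dyn.gL.astype(float) * dyn.e_leak
    rhs[0] += bias_pA
    return np.linalg.solve(G, rhs)


def steady_soma_response(dyn: CellDynamics, bias_pA: float) -> float:
    """Steady-state somatic voltage under a constant soma current."""
    return float(steady_state_profile(dyn, bias_pA)[0])


def input_resistance(dyn: CellDynamics) -> float:
    """Somatic input resistance in mV/pA (= GOhm)."""
    return (steady_soma_response(dyn, 100.0) - dyn.e_leak) / 100.0


@dataclass
class IpspExperimentResult:
    paired: PairedRun
    records: list  # analysis.IPSPRecord per connected postsynaptic MSN
    amplitudes: np.ndarray  # signed mV, excluded records dropped
    baselines: np.ndarray


def ipsp_experiment(
    presyn_pop: str,
    n_per_side: int = 8,
    seed: int = 0,
    duration: float = 250.0,
    dt: float = 0.025,
    baseline_range: tuple[float, float] = (-75.0, -50.0),
    window: float = 80.0,
    synapses: dict[str, SynapseParams] | None = None,
    network: Network | None = None,
) -> IpspExperimentResult:
    """Paired-subtraction single-source IPSP measurement.

    One designated presynaptic cell (a central MSN for lateral, a
    central FSI for feedforward) is driven above threshold by a soma
    current; every other MSN is held at a distinct subthreshold
    potential spanning ``baseline_range``.  The matching inhibition kind
    is toggled between the two runs and IPSPs are extracted from the
    ON - OFF somatic difference of each connected MSN at the first
    presynaptic spike.
    """
    syn = synapses or default_synapses()
    if network is None:
        network = build_network(
            PlacementParams(n_per_side=n_per_side, seed=seed), seed=seed,
            lateral=True, feedforward=True, cortical=False,
        )
    msn_dyn = CellDynamics.msn_default(network.msn_scaffold)
    fsi_dyn = CellDynamics.fsi_default(network.fsi_scaffold)
    r_msn = input_resistance(msn_dyn)
    r_fsi = input_resistance(fsi_dyn)

    # presynaptic cell: closest to the cube center so it has many targets
    if presyn_pop == "msn":
        pos = network.msn_positions
    elif presyn_pop == "fsi":
        pos = network.fsi_positions
        if len(pos) == 0:
            raise ValueError("network has no FSIs")
    else:
        raise ValueError("presyn_pop must be 'msn' or 'fsi'")
    center = network.msn_positions.mean(axis=0)
    presyn = int(np.argmin(np.linalg.norm(pos - center, axis=1)))

    stim = StimSet()
    lo, hi = baseline_range
    # evenly cover the range, order shuffled so connected subsets span it
    targets = np.linspace(lo, hi, network.n_msn)
    targets = targets[np.random.default_rng(seed).permutation(network.n_msn)]
    for cell in range(network.n_msn):
        if presyn_pop == "msn" and cell == presyn:
            continue
        stim.add_bias("msn", cell, (targets[cell] - msn_dyn.e_leak) / r_msn)
    if presyn_pop == "msn":
        stim.add_bias("msn", presyn, (-25.0 - msn_dyn.e_leak) / r_msn)
    else:
        stim.add_bias("fsi", presyn, (-30.0 - fsi_dyn.e_leak) / r_fsi)

    # start every held MSN at its steady holding profile (the cable is
    # linear, so V = EL + bias * unit-response); the presynaptic cell
    # starts at rest and charges toward its first spike
    unit = (steady_state_profile(msn_dyn, 1.0) - msn_dyn.e_leak)
    bias_vec = stim.bias_vector("msn", network.n_msn)
    v0_msn = msn_dyn.e_leak + bias_vec[:, None] * unit[None, :]
    if presyn_pop == "msn":
        v0_msn[presyn, :] = msn_dyn.e_leak
    v0 = {"msn": v0_msn}

    config = SimConfig(
        duration=duration, dt=dt, lateral_on=False, feedforward_on=False,
        record_msn="all", seed=seed,
    )
    paired = paired_ipsp_run(
        network, stim, config, presyn_pop, presyn,
        msn_dyn=msn_dyn, fsi_dyn=fsi_dyn, synapses=syn, initial_v=v0,
    )

    # postsynaptic MSNs contacted by the presynaptic cell
    kind = "lateral" if presyn_pop == "msn" else "feedforward"
    sub = network.connections.select(kind)
    post = np.unique(sub.target[sub.source == presyn])
    if presyn_pop == "msn":
        post = post[post != presyn]

    # keep the analysis window clear of the second presynaptic spike
    cells_on, times_on = paired.result_on.raster.cells_times(presyn_pop)
    own = times_on[cells_on == presyn]
    if len(own) > 1:
        window = min(window, float(own[1] - own[0]))

    records = []
    for cell in post:
        rec = analysis.extract_ipsp(
            paired.result_on.traces.trace("msn", int(cell)),
            paired.result_off.traces.trace("msn", int(cell)),
            dt, paired.t_first_spike, window=window, cell=int(cell),
        )
        records.append(rec)
    kept = [r for r in records if not r.excluded]
    return IpspExperimentResult(
        paired=paired,
        records=records,
        amplitudes=np.array([r.amplitude for r in kept]),
        baselines=np.array([r.baseline for r in kept]),
    )


# ---------------------------------------------------------------------------
# experiment runners
# ---------------------------------------------------------------------------

def _build_for(config: ExperimentConfig) -> Network:
    return build_network(
        PlacementParams(n_per_side=config.n_per_side, seed=config.seed),
        seed=config.seed, lateral=True, feedforward=True, cortical=True,
        n_msn_glut=N_GLUT_MSN,
    )


def _paired_results(network, stim, config: ExperimentConfig, toggle: str):
    base = SimConfig(duration=config.duration, dt=config.dt, seed=config.seed)
    if toggle == "lateral":
        # feedforward stays inactive in BOTH arms: in the reduced tier the
        # full feedforward load overwhelms MSN spiking, so lateral effects
        # are isolated against a feedforward-free background
        cfg_on = replace(base, lateral_on=True, feedforward_on=False)
        cfg_off = replace(base, lateral_on=False, feedforward_on=False)
    elif toggle == "feedforward":
        # lateral stays inactive in both arms, mirroring the lateral case:
        # the paired contrast then isolates the feedforward effect
        cfg_on = replace(base, lateral_on=False, feedforward_on=True)
        cfg_off = replace(base, lateral_on=False, feedforward_on=False)
    else:
        raise ValueError("toggle must be 'lateral' or 'feedforward'")
    res_on = run_network(network, stim, cfg_on)
    res_off = run_network(network, stim, cfg_off)
    return res_on, res_off


def run_rate_curves(config: ExperimentConfig) -> dict:
    """Firing-rate sweep: paired toggled runs at each input frequency.

    Returns one row per swept frequency with mean rate and across-cell
    rate SD for both conditions.
    """
    network = _build_for(config)
    rows = []
    for f in config.input_freqs:
        stim = cortical_stim(
            network, config.duration, config.seed + int(f),
            msn_glut_hz=f, fsi_glut_hz=config.fsi_input_hz,
            fsi_gaba_hz=config.fsi_gaba_hz,
        )
        res_on, res_off = _paired_results(network, stim, config, config.toggle)
        stats_on = analysis.rate_stats(res_on.raster, config.duration)
        stats_off = analysis.rate_stats(res_off.raster, config.duration)
        rows.append({
            "input_hz": f,
            "mean_rate_on": stats_on["mean_hz"],
            "mean_rate_off": stats_off["mean_hz"],
            "rate_sd_on": stats_on["sd_hz"],
            "rate_sd_off": stats_off["sd_hz"],
        })
    return {"toggle": config.toggle, "rows": rows, "network": network}


def _ensemble_events(plan: EnsembleInputPlan) -> np.ndarray:
    return plan.shared_rhythm.times


def run_lateral_ensemble(config: ExperimentConfig) -> dict:
    """Ensemble-vs-noise design with lateral inhibition toggled."""
    network = _build_for(config)
    plan = ensemble_inputs(
        network.n_msn, config.ensemble_fraction, config.rhythm_freq,
        uncorrelated_spec(config.msn_input_hz / N_GLUT_MSN, config.duration),
        seed=config.seed,
    )
    stim = cortical_stim(
        network, config.duration, config.seed,
        msn_glut_hz=config.msn_input_hz, fsi_glut_hz=config.fsi_input_hz,
        fsi_gaba_hz=config.fsi_gaba_hz,
        ensemble_plan=plan, n_rhythm_syn=config.n_rhythm_syn,
    )
    res_on, res_off = _paired_results(network, stim, config, "lateral")
    events = _ensemble_events(plan)
    ens = np.nonzero(plan.membership)[0]
    non = np.nonzero(~plan.membership)[0]
    # 5C-style alignment: every ensemble-cell spike is a reference event
    ens_cells_off, ens_times_off = res_off.raster.cells_times("msn")
    ens_spike_events = ens_times_off[np.isin(ens_cells_off, ens)]
    out = {
        "network": network,
        "plan": plan,
        "result_on": res_on,
        "result_off": res_off,
        "rhythm_events": events,
        "suppression_non_ensemble": analysis.suppression_fraction(
            res_on.raster, res_off.raster, events,
            window=config.suppression_window, cells=non),
        "suppression_ensemble": analysis.suppression_fraction(
            res_on.raster, res_off.raster, events,
            window=config.suppression_window, cells=ens),
        "ensemble_sd_on": analysis.ensemble_spike_sd(
            res_on.raster, events, window=(0.0, 25.0), cells=ens),
        "ensemble_sd_off": analysis.ensemble_spike_sd(
            res_off.raster, events, window=(0.0, 25.0), cells=ens),
        "peh_non_ensemble_on": analysis.perievent_histogram(
            res_on.raster, ens_spike_events, window=(-50.0, 50.0),
            binsize=2.0, cells=non),
        "peh_non_ensemble_off": analysis.perievent_histogram(
            res_off.raster, ens_spike_events, window=(-50.0, 50.0),
            binsize=2.0, cells=non),
    }
    return out


def run_feedforward(config: ExperimentConfig, fsi_mode: str) -> dict:
    """Feedforward toggled under synchronized or desynchronized FSIs."""
    network = _build_for(config)
    plan = ensemble_inputs(
        network.n_msn, config.ensemble_fraction, config.rhythm_freq,
        uncorrelated_spec(config.msn_input_hz / N_GLUT_MSN, config.duration),
        seed=config.seed,
    )
    fsi_plan = synchronized_fsi_inputs(
        max(network.n_fsi, 1), fsi_mode, config.duration,
        burst_period=config.fsi_burst_period,
        spikes_per_burst=config.fsi_spikes_per_burst,
        noise_freq=config.fsi_input_hz,
        n_synapses_per_fsi=N_GLUT_FSI,
        seed=config.seed + 7,
    )
    stim = cortical_stim(
        network, config.duration, config.seed,
        msn_glut_hz=config.msn_input_hz, fsi_glut_hz=config.fsi_input_hz,
        fsi_gaba_hz=config.fsi_gaba_hz,
        ensemble_plan=plan, n_rhythm_syn=config.n_rhythm_syn,
        fsi_plan=fsi_plan,
    )
    res_on, res_off = _paired_results(network, stim, config, "feedforward")
    events = _ensemble_events(plan)
    ens = np.nonzero(plan.membership)[0]
    non = np.nonzero(~plan.membership)[0]
    fsi_rate = analysis.rate_stats(res_on.raster, config.duration, pop="fsi")["mean_hz"]
    return {
        "network": network,
        "mode": fsi_mode,
        "plan": plan,
        "result_on": res_on,
        "result_off": res_off,
        "rhythm_events": events,
        "fsi_mean_rate_on": fsi_rate,
        "suppression_non_ensemble": analysis.suppression_fraction(
            res_on.raster, res_off.raster, events,
            window=config.suppression_window, cells=non),
        "suppression_ensemble": analysis.suppression_fraction(
            res_on.raster, res_off.raster, events,
            window=config.suppression_window, cells=ens),
        "total_msn_on": res_on.raster.total("msn"),
        "total_msn_off": res_off.raster.total("msn"),
    }
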