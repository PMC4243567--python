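"""Synthetic presynaptic spike-train generation.

Trains are built by a jitter-and-shift algorithm rather than a Poisson
process, so partially synchronized but still randomized inputs can be
produced: a constant interspike-interval (ISI) scaffold at the desired
frequency, a Gaussian re-draw of every spike time around its scaffold
position, then a single uniform random shift of the whole train.
Uncorrelated input uses a large shift (one ISI) and a large jitter
standard deviation (ISI/4); a shared zero-jitter train realizes
precisely timed rhythmic drive for cell ensembles.

Conventions (tested): the scaffold starts at t = ISI, extends past the
window by ``shift_max`` so the global shift does not deplete the tail,
jittered spikes are re-sorted, and spikes outside [0, duration] are
dropped (no wrap-around).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "InputTrainSpec",
    "SpikeTrain",
    "EnsembleInputPlan",
    "FsiInputPlan",
    "generate_train",
    "uncorrelated_spec",
    "rhythm_train",
    "burst_train",
    "ensemble_inputs",
    "synchronized_fsi_inputs",
]


@dataclass(frozen=True)
class InputTrainSpec:
    frequency: float  # Hz
    duration: float  # ms
    jitter_sd: float  # ms, sigma of the Gaussian re-draw
    shift_max: float  # ms, bound of the uniform global shift
    seed: object = 0  # int or SeedSequence

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.duration <= 0:
            raise ValueError("frequency and duration must be positive")
        if self.jitter_sd < 0 or self.shift_max < 0:
            raise ValueError("jitter_sd and shift_max must be non-negative")

    @property
    def isi(self) -> float:
        return 1000.0 / self.frequency


class SpikeTrain:
    """Sorted spike times (ms) within [0, duration]."""

    __slots__ = ("times", "duration")

    def __init__(self, times: np.ndarray, duration: float) -> None:
        times = np.asarray(times, dtype=float)
        if times.size and (times.min() < 0 or times.max() > duration):
            raise ValueError("spike times must lie within [0, duration]")
        if times.size > 1 and np.any(np.diff(times) < 0):
            raise ValueError("spike times must be sorted")
        self.times = times
        self.duration = float(duration)

    def __len__(self) -> int:
        return len(self.times)

    def rate(self) -> float:
        """Mean firing rate in Hz."""
        return len(self.times) / self.duration * 1000.0

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SpikeTrain)
            and self.duration == other.duration
            and np.array_equal(self.times, other.times)
        )


def generate_train(spec: InputTrainSpec) -> SpikeTrain:
    """Constant-ISI scaffold -> Gaussian re-draw -> uniform global shift.

    The scaffold covers the window plus ``shift_max`` of margin so the
    stationary rate stays at the nominal frequency after shifting; the
    shift moves every spike by the same draw from U[0, shift_max];
    spikes outside [0, duration] are then dropped and the result sorted.
    """
    rng = np.random.default_rng(spec.seed)
    isi = spec.isi
    n = int(np.floor((spec.duration + spec.shift_max) / isi))
    # without a shift the scaffold starts at t = ISI; with one, the global
    # shift slides the periodic train so the i = 0 spike enters (0, shift],
    # keeping the windowed rate stationary at the nominal frequency
    i0 = 1 if spec.shift_max == 0 else 0
    base = isi * np.arange(i0, n + 1)
    if spec.jitter_sd > 0:
        base = rng.normal(base, spec.jitter_sd)
    shift = rng.uniform(0.0, spec.shift_max) if spec.shift_max > 0 else 0.0
    t = np.sort(base + shift)
    t = t[(t >= 0.0) & (t <= spec.duration)]
    return SpikeTrain(t, spec.duration)


def uncorrelated_spec(frequency: float, duration: float, seed=0) -> InputTrainSpec:
    """Fully randomized train parameters: jitter sd = ISI/4, shift = ISI."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    isi = 1000.0 / frequency
    return InputTrainSpec(
        frequency=frequency, duration=duration,
        jitter_sd=isi / 4.0, shift_max=isi, seed=seed,
    )


def rhythm_train(frequency: float, duration: float) -> SpikeTrain:
    """Precisely timed periodic train (zero jitter, zero shift)."""
    spec = InputTrainSpec(frequency, duration, 0.0, 0.0, seed=0)
    return generate_train(spec)


def burst_train(
    duration: float,
    period: float,
    spikes_per_burst: int,
    intra_burst_isi: float,
) -> SpikeTrain:
    """Deterministic burst schedule: a burst every ``period`` ms.

    Each burst is ``spikes_per_burst`` spikes spaced ``intra_burst_isi``
    ms apart, the first burst starting at t = period.
    """
    onsets = np.arange(period, duration + 1e-9, period)
    offs = intra_burst_isi * np.arange(spikes_per_burst)
    t = (onsets[:, None] + offs[None, :]).ravel()
    t = t[t <= duration]
    return SpikeTrain(np.sort(t), duration)


@dataclass
class EnsembleInputPlan:
    """Noise trains for every cell plus a shared rhythm for ensemble members.

    ``noise_specs[i]`` holds the per-synapse train specs of cell ``i``
    (independent seeds); ``shared_rhythm`` is bit-identical across all
    ensemble members.
    """

    n_cells: int
    membership: np.ndarray  # bool, True = ensemble member
    shared_rhythm: SpikeTrain
    noise_specs: list[list[InputTrainSpec]]

    def is_ensemble(self, cell: int) -> bool:
        return bool(self.membership[cell])


def ensemble_inputs(
    n_cells: int,
    ensemble_fraction: float,
    rhythm_freq: float,
    noise_spec: InputTrainSpec,
    seed=0,
    n_synapses_per_cell: int = 1,
) -> EnsembleInputPlan:
    """Mark the first ceil(fraction*n) cells as the ensemble.

    All cells get independent noise trains (one spec per synapse,
    seed-streamed); ensemble cells additionally share one precisely
    timed rhythm train at ``rhythm_freq``.
    """
    if not 0 < ensemble_fraction <= 1:
        raise ValueError("ensemble_fraction must be in (0, 1]")
    n_ens = int(np.ceil(ensemble_fraction * n_cells))
    membership = np.zeros(n_cells, dtype=bool)
    membership[:n_ens] = True
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_cells * n_synapses_per_cell)
    noise_specs = [
        [
            replace(noise_spec, seed=children[i * n_synapses_per_cell + j])
            for j in range(n_synapses_per_cell)
        ]
        for i in range(n_cells)
    ]
    rhythm = rhythm_train(rhythm_freq, noise_spec.duration)
    return EnsembleInputPlan(n_cells, membership, rhythm, noise_specs)


@dataclass
class FsiInputPlan:
    """Per-FSI glutamatergic drive trains.

    ``trains[i][j]`` is the spike train of synapse ``j`` on FSI ``i``.
    In ``identical`` mode every FSI holds references to the same train
    objects (bit-identical input); in ``independent`` mode each FSI has
    its own seed stream.
    """

    mode: str
    trains: list[list[SpikeTrain]]


def synchronized_fsi_inputs(
    n_fsi: int,
    mode: str,
    duration: float,
    burst_period: float = 125.0,
    spikes_per_burst: int = 8,
    intra_burst_isi: float = 2.0,
    noise_freq: float = 600.0,
    n_synapses_per_fsi: int = 84,
    n_burst_syn: int = 8,
    seed=0,
) -> FsiInputPlan:
    """FSI drive for the synchronized vs desynchronized contrast.

    ``identical``: one deterministic burst schedule (a burst of
    ``spikes_per_burst`` spikes every ``burst_period`` ms) carried by
    ``n_burst_syn`` synapses, the remaining synapses silent; the whole
    set is duplicated bit-exactly on every FSI so all FSIs fire in
    lockstep bursts.  ``independent``: each FSI's synapses get distinct
    uncorrelated trains whose summed rate is ``noise_freq``.
    """
    if n_fsi < 1:
        raise ValueError("n_fsi must be >= 1")
    if mode == "identical":
        t = burst_train(duration, burst_period, spikes_per_burst, intra_burst_isi)
        silent = SpikeTrain(np.empty(0), duration)
        shared = [t] * n_burst_syn + [silent] * (n_synapses_per_fsi - n_burst_syn)
        return FsiInputPlan(mode, [shared for _ in range(n_fsi)])
    if mode == "independent":
        per_syn_freq = noise_freq / n_synapses_per_fsi
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(n_fsi * n_synapses_per_fsi)
        trains = [
            [
                generate_train(uncorrelated_spec(
                    per_syn_freq, duration,
                    seed=children[i * n_synapses_per_fsi + j],
                ))
                for j in range(n_synapses_per_fsi)
            ]
            for i in range(n_fsi)
        ]
        return FsiInputPlan(mode, trains)
    raise ValueError(f"unknown FSI input mode {mode!r}")
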