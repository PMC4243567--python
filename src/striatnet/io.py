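"""File formats and run manifests.

Networks are JSON documents; rasters and input plans are tab-separated
text; traces go to HDF5 with dt and units as attributes.  A run
manifest (JSON) snapshots the configuration and per-stage seeds so a
network can be rebuilt bit-exactly from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .netbuild import Network, PlacementParams, TopologyParams, build_network
from .simulator import RasterSet, StimSet, TraceSet

__all__ = [
    "save_network",
    "load_network",
    "network_digest",
    "write_raster_tsv",
    "read_raster_tsv",
    "write_inputs_tsv",
    "write_traces_h5",
    "read_traces_h5",
    "RunManifest",
    "write_manifest",
    "read_manifest",
    "rebuild_from_manifest",
]


def save_network(network: Network, path) -> None:
    Path(path).write_text(network.to_json())


def load_network(path) -> Network:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"network file not found: {p}")
    return Network.from_json(p.read_text())


def network_digest(network: Network) -> str:
    """SHA-256 of the canonical JSON serialization."""
    return hashlib.sha256(network.to_json().encode()).hexdigest()


def write_raster_tsv(raster: RasterSet, path) -> None:
    """Tab-separated spikes: population, cell_id, spike_time_ms."""
    with open(path, "w") as fh:
        fh.write("population\tcell_id\tspike_time_ms\n")
        for pop, (cells, times) in raster.spikes.items():
            for c, t in zip(cells, times):
                fh.write(f"{pop}\t{c}\t{t:.6f}\n")


def read_raster_tsv(path, duration: float, n_cells: dict[str, int]) -> RasterSet:
    pops: dict[str, list] = {p: ([], []) for p in n_cells}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("population"):
            raise ValueError("not a raster TSV (missing header)")
        for line in fh:
            pop, cell, t = line.rstrip("\n").split("\t")
            pops.setdefault(pop, ([], []))
            pops[pop][0].append(int(cell))
            pops[pop][1].append(float(t))
    spikes = {
        p: (np.array(cs, np.int64), np.array(ts, float))
        for p, (cs, ts) in pops.items()
    }
    return RasterSet(spikes, duration, n_cells)


def write_inputs_tsv(stim: StimSet, path, sidecar_path=None, meta: dict | None = None) -> None:
    """Input raster: synapse_id, population, cell_id, comp_id, kind, time_ms.

    An optional JSON sidecar stores arbitrary generation metadata
    (specs, seeds).
    """
    with open(path, "w") as fh:
        fh.write("synapse_id\tpopulation\tcell_id\tcomp_id\tkind\ttime_ms\n")
        syn_id = 0
        for pop, events in stim._events.items():
            for cell, comp, kind, times, w in events:
                for t in times:
                    fh.write(f"{syn_id}\t{pop}\t{cell}\t{comp}\t{kind}\t{t:.6f}\n")
                syn_id += 1
    if sidecar_path is not None:
        Path(sidecar_path).write_text(json.dumps(meta or {}, indent=2))


def write_traces_h5(traces: TraceSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["units"] = "mV"
        f.attrs["time_units"] = "ms"
        f.create_dataset("times", data=traces.times)
        for pop, (ids, arr) in traces.data.items():
            grp = f.create_group(pop)
            grp.create_dataset("cell_ids", data=ids)
            grp.create_dataset("soma_mV", data=arr)
            if len(traces.times) > 1:
                grp.attrs["dt_ms"] = float(traces.times[1] - traces.times[0])


def read_traces_h5(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        times = f["times"][:]
        data = {}
        for pop in f:
            if pop == "times":
                continue
            data[pop] = (f[pop]["cell_ids"][:], f[pop]["soma_mV"][:])
    return TraceSet(times, data)


@dataclass
class RunManifest:
    """Everything needed to rebuild a network/run bit-exactly."""

    version: str
    master_seed: int
    placement: dict
    topology: dict
    build_flags: dict  # lateral / feedforward / cortical / n_msn_glut
    artifacts: dict  # logical name -> file path
    network_sha256: str | None = None
    extra: dict | None = None


def manifest_for(network: Network, master_seed: int, artifacts: dict | None = None,
                 build_flags: dict | None = None, extra: dict | None = None) -> RunManifest:
    flags = {"lateral": True, "feedforward": True, "cortical": False, "n_msn_glut": 84}
    if build_flags:
        flags.update(build_flags)
    return RunManifest(
        version=__version__,
        master_seed=master_seed,
        # JSON-normalized (tuples become lists) so written and re-read
        # manifests compare equal
        placement=json.loads(json.dumps(asdict(network.placement))),
        topology=json.loads(json.dumps(asdict(network.topology))),
        build_flags=flags,
        artifacts=artifacts or {},
        network_sha256=network_digest(network),
    )


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2))


def read_manifest(path) -> RunManifest:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"manifest not found: {p}")
    doc = json.loads(p.read_text())
    m = RunManifest(**doc)
    if m.version != __version__:
        import warnings

        warnings.warn(
            f"manifest written by version {m.version}, running {__version__}",
            stacklevel=2,
        )
    return m


def rebuild_from_manifest(manifest: RunManifest) -> Network:
    """Reconstruct the network from a manifest; verifies the digest."""
    pl = dict(manifest.placement)
    pl["fsi_ratio"] = tuple(pl["fsi_ratio"])
    tp = dict(manifest.topology)
    tp["lateral_contact_pmf"] = tuple(tp["lateral_contact_pmf"])
    tp["ff_contact_range"] = tuple(tp["ff_contact_range"])
    flags = manifest.build_flags
    net = build_network(
        PlacementParams(**pl), TopologyParams(**tp), seed=manifest.master_seed,
        lateral=flags["lateral"], feedforward=flags["feedforward"],
        cortical=flags["cortical"], n_msn_glut=flags["n_msn_glut"],
    )
    if manifest.network_sha256 and network_digest(net) != manifest.network_sha256:
        raise ValueError("rebuilt network does not match the manifest digest")
    return net
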