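"""Spike-train and result I/O.

The interchange format for spike trains is a two-column tab-separated table,
``cell_id<TAB>time_s``, one spike per row, sorted by cell then time, with a
JSON sidecar (same stem, ``.json``) carrying the provenance: simulation or
generator settings, seed, and a hash of the network realization where one
exists.  Feature tables and KL grids travel as CSV via pandas.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .cell import MSNCellParams
from .network import NetworkConfig, NetworkRealization, SimulationResult
from .segments import SpikeTrain

__all__ = [
    "write_spikes_tsv",
    "read_spikes_tsv",
    "write_result",
    "read_session",
    "realization_hash",
    "config_dict",
]


def realization_hash(realization: NetworkRealization) -> str:
    """Stable short hash of wiring + conductance draws."""
    h = hashlib.sha256()
    for arr in (realization.indptr, realization.indices,
                realization.g_syn, realization.b_decay, realization.g_ex):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def config_dict(config: NetworkConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cell_params"] = dataclasses.asdict(config.cell_params)
    return d


def write_spikes_tsv(path, spikes: list[np.ndarray], sidecar: dict | None = None):
    """Write per-cell spike-time arrays as ``cell_id<TAB>time_s`` rows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id\ttime_s\n")
        for cid, times in enumerate(spikes):
            for t in np.asarray(times):
                fh.write(f"{cid}\t{t:.6f}\n")
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_spikes_tsv(path, n_cells: int | None = None) -> list[np.ndarray]:
    """Read a spike TSV back into per-cell time arrays."""
    cells, times = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cell_id"):
            raise ValueError(f"{path}: not a spike TSV (missing header)")
        for line in fh:
            c, t = line.split("\t")
            cells.append(int(c))
            times.append(float(t))
    cells = np.asarray(cells, int)
    times = np.asarray(times, float)
    n = (int(cells.max()) + 1 if cells.size else 0) if n_cells is None else n_cells
    return [np.sort(times[cells == i]) for i in range(n)]


def write_result(path, result: SimulationResult,
                 realization: NetworkRealization | None = None):
    """Write a simulation result with its provenance sidecar."""
    sidecar = {
        "config": config_dict(result.config),
        "seed": result.realization_seed,
    }
    if realization is not None:
        sidecar["realization_hash"] = realization_hash(realization)
    write_spikes_tsv(path, result.spike_times, sidecar)


def write_voltage_h5(path, result: SimulationResult):
    """Dump recorded membrane-potential traces (cells x samples) to HDF5."""
    import h5py

    if result.voltage is None:
        raise ValueError("simulation was run without voltage recording")
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("voltage_mV", data=result.voltage,
                               compression="gzip")
        ds.attrs["stride_ms"] = result.voltage_stride_ms
        fh.create_dataset("cells", data=np.asarray(result.voltage_cells))


def read_session(path, duration: float, group: str = "", age: float = float("nan"),
                 source: str = "") -> list[SpikeTrain]:
    """Read a spike TSV as a list of session-level :class:`SpikeTrain`."""
    spikes = read_spikes_tsv(path)
    return [
        SpikeTrain(spike_times=t, duration=duration, cell_id=i,
                   group=group, age=age, source=source or str(path))
        for i, t in enumerate(spikes)
    ]
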