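"""File input/output for runs.

Spike streams go to two-column whitespace text (neuron_id, time_s);
connectivity snapshots to Matrix Market sparse integer files with a CSV
sidecar assigning each neuron to its partition group; every run directory
carries a config echo so the analysis can be re-run without the simulator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from . import __version__
from .config import RunConfig

__all__ = [
    "write_spikes", "read_spikes", "write_matrix", "read_matrix",
    "write_partition", "read_partition", "write_rewiring_events",
    "write_run_dir",
]


def write_spikes(path, ids, times):
    with open(path, "w") as fh:
        for i, t in zip(ids, times):
            fh.write(f"{int(i)} {t:.6f}\n")


def read_spikes(path):
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return np.empty(0, np.int32), np.empty(0)
    return data[:, 0].astype(np.int32), data[:, 1]


def write_matrix(path, A):
    mmwrite(str(path), sparse.coo_matrix(A), field="integer")


def read_matrix(path) -> np.ndarray:
    return np.asarray(mmread(str(path)).todense(), dtype=np.int32)


def write_partition(path, groups: dict, n_total: int, n_E: int):
    """CSV sidecar: neuron_id, group label."""
    labels = np.array(["background_E"] * n_E + ["I"] * (n_total - n_E),
                      dtype=object)
    for name in ("engram_overlap", "engram_rest", "dc_only"):
        ids = groups.get(name)
        if ids is not None and len(ids):
            labels[np.asarray(ids)] = name
    pd.DataFrame({"neuron_id": np.arange(n_total), "group": labels}) \
        .to_csv(path, index=False)


def read_partition(path) -> dict:
    df = pd.read_csv(path)
    return {g: df.loc[df.group == g, "neuron_id"].to_numpy()
            for g in df.group.unique()}


def write_rewiring_events(path, events):
    """CSV log of structural events: time_s, event in {form, delete}, pre, post.

    ``events`` as collected by a :class:`hspsim.plasticity.StructuralEngine`
    built with ``log_events=True``.
    """
    pd.DataFrame(events, columns=["time_s", "event", "pre_id", "post_id"]) \
        .to_csv(path, index=False)


def write_run_dir(out_dir, cfg: RunConfig, result=None) -> Path:
    """Create a run directory with config echo, seed, and all outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.dump(out / "config.yaml")
    (out / "meta.json").write_text(json.dumps(
        {"seed": cfg.seed, "version": __version__}, indent=2))
    if result is None:
        return out
    write_matrix(out / "A_final.mtx", result.final_A)
    for t, A in result.snapshots.items():
        write_matrix(out / f"A_{t:.0f}s.mtx", A)
    write_partition(out / "partition.csv", result.groups,
                    cfg.n_total, cfg.n_E)
    tidy = []
    for name, series in result.rate.items():
        for (t0, t1), v in zip(result.window_edges, series):
            tidy.append({"group": name, "metric": "rate_hz",
                         "window_start_s": t0, "value": v})
    for (pre, post), series in result.gamma.items():
        for t, v in zip(result.gamma_times, series):
            tidy.append({"group": f"{pre}->{post}", "metric": "gamma",
                         "window_start_s": t, "value": v})
    pd.DataFrame(tidy).to_csv(out / "measurements.csv", index=False)
    spikes = getattr(result, "spikes", None)
    if spikes is not None and len(spikes):
        write_spikes(out / "spikes.txt", spikes.ids, spikes.times)
    return out
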