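"""Experiment protocols: montages, phase scheduling, runs, and sweeps.

A run always starts from a network grown to its structural equilibrium under
background input.  Motor learning is Poisson input (default 1.5 kHz, 0.1 mV)
to the engram subpopulation (10 % of E neurons); tDCS is a constant somatic
polarization ``delta_Vm`` applied to a montage-defined subpopulation
immediately before, during, or immediately after learning ("immediately"
meaning zero gap).  The simulation then relaxes with plasticity active and
the final engram connectivity is the main readout.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .network import (Simulator, SpikeRecord, StimSchedule, grow_network,
                      make_dc_drive, make_poisson_drive)
from .plasticity import StructuralEngine

log = logging.getLogger("hspsim.protocols")

__all__ = [
    "MontageSpec", "ExperimentPlan", "build_montage", "schedule",
    "Recorder", "ExperimentResult", "run_experiment", "sweep", "clone_sim",
]


# ---------------------------------------------------------------------------
# montage

@dataclass(frozen=True)
class MontageSpec:
    """Electrode-montage scenario resolved to explicit neuron id sets."""
    kind: str
    engram_ids: np.ndarray
    dc_ids: np.ndarray


def build_montage(kind: str, engram_ids: np.ndarray, n_E: int,
                  rng: np.random.Generator) -> MontageSpec:
    """Resolve a montage name into the stimulated id set.

    uniform   — DC covers all excitatory neurons;
    targeted  — DC covers exactly the engram;
    unfocused — DC covers half the engram plus an equal number of non-engram
                excitatory neurons drawn uniformly at random.
    """
    engram_ids = np.asarray(engram_ids)
    if np.any(engram_ids >= n_E) or np.any(engram_ids < 0):
        raise ValueError("engram ids out of range")
    if kind == "uniform":
        dc = np.arange(n_E)
    elif kind == "targeted":
        dc = engram_ids.copy()
    elif kind == "unfocused":
        if engram_ids.size % 2:
            raise ValueError("unfocused montage needs an even engram size")
        half = engram_ids.size // 2
        overlap = engram_ids[:half]
        outside = np.setdiff1d(np.arange(n_E), engram_ids)
        extra = rng.choice(outside, size=half, replace=False)
        dc = np.sort(np.concatenate([overlap, extra]))
    else:
        raise ValueError(f"unknown montage kind {kind!r}")
    return MontageSpec(kind, np.sort(engram_ids), dc)


# ---------------------------------------------------------------------------
# plan and schedule

@dataclass(frozen=True)
class ExperimentPlan:
    """Timing and drive parameters of one experiment."""
    growth_s: float = 750.0
    learn_s: float = 150.0
    dc_s: float = 150.0
    relax_s: float = 150.0
    timing: str = "none"
    delta_Vm_mV: float = 0.0
    learn_rate_hz: float = 1500.0
    learn_J_mV: float = 0.1
    engram_fraction: float = 0.10
    snapshot_times_s: tuple = ()
    seed: int = 1

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "ExperimentPlan":
        return cls(growth_s=cfg.growth_s, learn_s=cfg.learn_s, dc_s=cfg.dc_s,
                   relax_s=cfg.relax_s, timing=cfg.timing,
                   delta_Vm_mV=cfg.delta_Vm_mV, learn_rate_hz=cfg.learn_rate_hz,
                   learn_J_mV=cfg.learn_J_mV, engram_fraction=cfg.engram_fraction,
                   snapshot_times_s=tuple(cfg.snapshot_times_s), seed=cfg.seed)


def schedule(plan: ExperimentPlan, montage: MontageSpec, n_total: int,
             n_E: int):
    """Build the stimulation schedule for one run.

    Returns ``(StimSchedule, t_end)`` with absolute times in seconds.  Every
    run ends at the same fixed horizon ``growth + learn_s + dc_s + relax_s``
    regardless of timing (mirroring the fixed 1200 s measurement point of the
    full-scale timeline), so conditions are compared at equal elapsed time.
    """
    g = plan.growth_s
    learn_on = plan.learn_s > 0 and plan.learn_rate_hz > 0
    dc_on = plan.dc_s > 0 and plan.delta_Vm_mV != 0 and plan.timing != "none"
    if plan.timing == "before":
        dc_t, learn_t = g, g + plan.dc_s
    elif plan.timing == "after":
        learn_t, dc_t = g, g + (plan.learn_s if learn_on else 0.0)
    else:  # during / none
        dc_t = learn_t = g
    segs = StimSchedule()
    if learn_on:
        mask = np.zeros(n_total, bool)
        mask[montage.engram_ids] = True
        segs.add(make_poisson_drive(plan.learn_rate_hz, plan.learn_J_mV,
                                    mask, learn_t, plan.learn_s))
    if dc_on:
        mask = np.zeros(n_total, bool)
        mask[montage.dc_ids] = True
        segs.add(make_dc_drive(plan.delta_Vm_mV, mask, dc_t, dc_t + plan.dc_s))
    t_end = g + plan.learn_s + plan.dc_s + plan.relax_s
    for t in plan.snapshot_times_s:
        if t < g:
            raise ValueError(f"snapshot time {t} s lies before the end of growth")
        t_end = max(t_end, t)
    return segs, t_end


# ---------------------------------------------------------------------------
# recording

class Recorder:
    """Collects rate windows, block-connectivity series, and snapshots."""

    def __init__(self, cfg: RunConfig, groups: dict[str, np.ndarray],
                 gamma_pairs, snapshot_times=()):
        self.cfg = cfg
        self.groups = {k: np.asarray(v) for k, v in groups.items() if len(v)}
        self.gamma_pairs = [p for p in gamma_pairs
                            if p[0] in self.groups and p[1] in self.groups]
        self.window_chunks = max(1, int(round(
            cfg.rate_window_s / (cfg.dt_struct_ms * 1e-3))))
        self.stride_chunks = max(1, int(round(
            cfg.gamma_stride_s / (cfg.dt_struct_ms * 1e-3))))
        self.snapshot_times = sorted(snapshot_times)
        self._acc = None
        self._i_chunk = 0
        self.rate: dict[str, list] = {k: [] for k in self.groups}
        self.window_edges: list = []
        self.gamma: dict[tuple, list] = {p: [] for p in self.gamma_pairs}
        self.gamma_times: list = []
        self.snapshots: dict[float, np.ndarray] = {}
        # indicator matrix over E neurons: all requested block sums come from
        # one small matmul against the E-E weight block per readout
        names = sorted({n for pair in self.gamma_pairs for n in pair})
        self._gnames = {n: k for k, n in enumerate(names)}
        self._indicator = np.zeros((len(names), cfg.n_E))
        for name, k in self._gnames.items():
            self._indicator[k, self.groups[name]] = 1.0

    def chunk(self, sim, counts):
        cfg = self.cfg
        if self._acc is None:
            self._acc = np.zeros_like(counts, dtype=np.float64)
            self._win_t0 = sim.state.t - cfg.dt_struct_ms * 1e-3
        self._acc += counts
        self._i_chunk += 1
        if self._i_chunk % self.window_chunks == 0:
            w = self.window_chunks * cfg.dt_struct_ms * 1e-3
            for name, ids in self.groups.items():
                self.rate[name].append(self._acc[ids].mean() / w)
            self.window_edges.append((self._win_t0, sim.state.t))
            self._acc[:] = 0.0
            self._win_t0 = sim.state.t
        if self._i_chunk % self.stride_chunks == 0 and self.gamma_pairs:
            # raw block sums S[pre, post] over the E-E weight block (= J * A)
            n_E = sim.conn.n_E
            wt_ee = sim.conn.WT[:n_E, :n_E]
            S = (self._indicator @ wt_ee @ self._indicator.T) / sim.conn.J
            for pre, post in self.gamma_pairs:
                raw = S[self._gnames[pre], self._gnames[post]]
                size = self.groups[pre].size * self.groups[post].size
                self.gamma[(pre, post)].append(raw / size)
            self.gamma_times.append(sim.state.t)
        while self.snapshot_times and sim.state.t >= self.snapshot_times[0] - 1e-9:
            self.snapshots[self.snapshot_times.pop(0)] = sim.conn.A.copy()

    def as_arrays(self):
        return ({k: np.asarray(v) for k, v in self.rate.items()},
                {k: np.asarray(v) for k, v in self.gamma.items()})


@dataclass
class ExperimentResult:
    """Time series of population rates and block connectivities for one run."""
    cfg: RunConfig
    montage: MontageSpec
    groups: dict
    rate: dict                 # group -> Hz per rate window
    window_edges: np.ndarray
    gamma: dict                # (pre, post) -> series
    gamma_times: np.ndarray
    snapshots: dict            # time -> A copy
    final_A: np.ndarray
    growth_rate_hz: float = float("nan")

    #: number of trailing connectivity readouts averaged for the final value
    FINAL_WINDOWS = 10

    def final_gamma(self, pre="engram", post=None) -> float:
        """Mean of the last few recorded Γ values for one block pair."""
        series = self.gamma[(pre, post or pre)]
        return float(np.mean(series[-self.FINAL_WINDOWS:]))

    def final_rate(self, group="engram") -> float:
        return float(np.mean(self.rate[group][-2:]))


def partition_groups(montage: MontageSpec, n_E: int) -> dict[str, np.ndarray]:
    """Disjoint E-population partition induced by engram and DC id sets."""
    eng = set(montage.engram_ids.tolist())
    dc = set(montage.dc_ids.tolist())
    overlap = np.array(sorted(eng & dc), dtype=np.int64)
    eng_rest = np.array(sorted(eng - dc), dtype=np.int64)
    dc_only = np.array(sorted(dc - eng), dtype=np.int64)
    rest = np.array(sorted(set(range(n_E)) - eng - dc), dtype=np.int64)
    return {"engram_overlap": overlap, "engram_rest": eng_rest,
            "dc_only": dc_only, "background_E": rest}


# ---------------------------------------------------------------------------
# running

def clone_sim(sim: Simulator) -> Simulator:
    """Deep copy of a simulator (used to fork one grown network into many runs)."""
    return copy.deepcopy(sim)


def run_experiment(cfg: RunConfig, sim: Simulator | None = None,
                   montage: MontageSpec | None = None,
                   record_spikes: bool | None = None) -> ExperimentResult:
    """Execute one full protocol and return its measurements.

    When ``sim`` is given it must be a freshly grown (equilibrated) network;
    it is cloned, so the same grown network can seed many conditions.
    """
    cfg.validate()
    plan = ExperimentPlan.from_config(cfg)
    seed_seq = np.random.SeedSequence(cfg.seed)
    if sim is None:
        sim = grow_network(cfg, seed_seq=seed_seq)
    else:
        sim = clone_sim(sim)
    if sim.plasticity is None:
        sim.plasticity = StructuralEngine(cfg, sim.struct_rng)
    n_eng = cfg.n_engram
    if montage is None:
        montage_rng = np.random.default_rng(seed_seq.spawn(1)[0])
        montage = build_montage(cfg.montage, np.arange(n_eng), cfg.n_E,
                                montage_rng)
    segs, t_end = schedule(plan, montage, cfg.n_total, cfg.n_E)

    groups = partition_groups(montage, cfg.n_E)
    groups["engram"] = montage.engram_ids
    groups["non_engram"] = np.setdiff1d(np.arange(cfg.n_E), montage.engram_ids)
    groups["all_E"] = np.arange(cfg.n_E)
    groups["I"] = np.arange(cfg.n_E, cfg.n_total)
    part_names = [k for k in ("engram_overlap", "engram_rest", "dc_only",
                              "background_E") if len(groups.get(k, ()))]
    pairs = [(a, b) for a in part_names for b in part_names]
    pairs += [("engram", "engram"), ("non_engram", "non_engram"),
              ("engram", "non_engram"), ("non_engram", "engram"),
              ("all_E", "all_E")]
    rec = Recorder(cfg, groups, pairs,
                   snapshot_times=list(plan.snapshot_times_s) or [t_end])
    spikes = SpikeRecord() if (record_spikes if record_spikes is not None
                               else cfg.record_spikes) else None
    log.info("run: montage=%s timing=%s dVm=%+.2f mV seed=%d, %.0f s of "
             "protocol after %.0f s growth", montage.kind, plan.timing,
             plan.delta_Vm_mV, cfg.seed, t_end - sim.state.t, sim.state.t)
    sim.advance(t_end - sim.state.t, schedule=segs, recorder=rec,
                spikes_out=spikes)
    rate, gamma = rec.as_arrays()
    result = ExperimentResult(
        cfg=cfg, montage=montage, groups=rec.groups, rate=rate,
        window_edges=np.asarray(rec.window_edges), gamma=gamma,
        gamma_times=np.asarray(rec.gamma_times), snapshots=rec.snapshots,
        final_A=sim.conn.A.copy(),
        growth_rate_hz=getattr(sim, "growth_rate_hz", float("nan")))
    result.spikes = spikes
    return result


# ---------------------------------------------------------------------------
# sweep

def sweep(base_cfg: RunConfig, montages, timings, delta_Vms, seeds,
          grown: dict | None = None) -> pd.DataFrame:
    """Run a montage x timing x intensity x seed grid.

    ``grown`` optionally maps seed -> equilibrated :class:`Simulator` so the
    growth phase is shared across grid points.  Returns one row per run with
    the final engram connectivity and, for unfocused runs, the overlapped /
    non-overlapped half readouts.
    """
    rows = []
    grown = grown if grown is not None else {}
    for seed in seeds:
        cfg0 = base_cfg.replace(seed=seed)
        if seed not in grown:
            grown[seed] = grow_network(cfg0,
                                       seed_seq=np.random.SeedSequence(seed))
        for montage in montages:
            for timing in timings:
                for dvm in delta_Vms:
                    cfg = cfg0.replace(montage=montage, timing=timing,
                                       delta_Vm_mV=float(dvm))
                    if timing == "none" or dvm == 0:
                        cfg = cfg.replace(timing="none", delta_Vm_mV=0.0)
                    res = run_experiment(cfg, sim=grown[seed])
                    row = {
                        "montage": montage, "timing": cfg.timing,
                        "delta_Vm_mV": cfg.delta_Vm_mV, "seed": seed,
                        "gamma_engram": res.final_gamma("engram"),
                        "gamma_network": res.final_gamma("all_E"),
                        "rate_engram_final_Hz": res.final_rate("engram"),
                        "gamma_overlap": np.nan, "gamma_nonoverlap": np.nan,
                    }
                    if montage == "unfocused":
                        row["gamma_overlap"] = res.final_gamma("engram_overlap")
                        row["gamma_nonoverlap"] = res.final_gamma("engram_rest")
                    rows.append(row)
    return pd.DataFrame(rows)
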