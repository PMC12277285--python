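"""Clock-driven LIF network core.

The model is an inhibition-dominated random recurrent network of excitatory
(E) and inhibitory (I) leaky integrate-and-fire neurons with delta-pulse
synapses (each presynaptic spike deflects the postsynaptic membrane by a
fixed amount one transmission delay later).  All connections involving
inhibitory neurons are static; E-E connections are an integer synapse-count
matrix grown and rewired by the homeostatic structural plasticity engine in
:mod:`hspsim.plasticity`.

Membrane dynamics between events are integrated exactly (exponential Euler
of the linear leak equation) on a fixed grid of ``dt_ms``.  Direct-current
stimulation enters as an additive term calibrated so that the threshold-free
stationary membrane deflection equals the configured ``delta_Vm`` exactly.

Implementation notes.  Simulation advances in chunks of one structural
interval.  Poisson input uses inverse-CDF sampling: uniforms are drawn in
bulk per chunk from a PCG64 generator and converted to event counts inside
a Numba kernel through a cumulative table with a guide index (input rates
are piecewise constant, so tables are built once per drive segment).  The
weight matrix is stored presynaptic-major so spike delivery streams one
contiguous row.  The calcium trace is updated once per chunk from the spike
counts (the decay misordering within one 100 ms chunk is < 1 % of a single
spike increment for the 10 s calcium time constant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .config import RunConfig

log = logging.getLogger("hspsim.network")

__all__ = [
    "NeuronParams", "CouplingParams", "NetworkState", "ConnectivityMatrix",
    "SpikeRecord", "Segment", "StimSchedule", "make_poisson_drive",
    "make_dc_drive", "Simulator", "grow_network", "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the integration blows up (non-finite membrane potentials)."""


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class NeuronParams:
    """LIF single-neuron parameters (all in ms / mV)."""
    tau_m_ms: float = 10.0
    V_theta_mV: float = 20.0
    V_reset_mV: float = 10.0
    t_ref_ms: float = 2.0
    delay_ms: float = 1.0

    def __post_init__(self):
        if self.tau_m_ms <= 0:
            raise ValueError("tau_m must be positive")
        if not self.V_theta_mV > self.V_reset_mV >= 0:
            raise ValueError("require V_theta > V_reset >= 0")
        if self.t_ref_ms < 0:
            raise ValueError("t_ref must be non-negative")


@dataclass(frozen=True)
class CouplingParams:
    """Synaptic couplings: EPSP amplitude J, relative inhibition g, background rate."""
    J_mV: float = 0.1
    g: float = 8.0
    nu_ext_hz: float = 19500.0

    def __post_init__(self):
        if self.J_mV <= 0 or self.g <= 0 or self.nu_ext_hz < 0:
            raise ValueError("require J > 0, g > 0, nu_ext >= 0")


@dataclass
class NetworkState:
    """Mutable per-neuron state at one point in simulated time.

    ``Ca`` is the calcium trace of the excitatory population, refreshed at
    structural-interval resolution.
    """
    V: np.ndarray              # membrane potential (mV), length n_total
    ref_remaining: np.ndarray  # refractory countdown in steps, int32
    Ca: np.ndarray             # calcium trace of E neurons (units of Hz)
    t: float = 0.0             # simulated time (s)


@dataclass
class SpikeRecord:
    """Flat stream of (neuron id, spike time) pairs, time-ordered."""
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int32))
    times: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))

    def extend(self, ids, times):
        self.ids = np.concatenate([self.ids, np.asarray(ids, np.int32)])
        self.times = np.concatenate([self.times, np.asarray(times, np.float64)])

    def __len__(self):
        return self.ids.size


class ConnectivityMatrix:
    """Plastic E-E synapse counts plus static couplings with inhibitory neurons.

    ``A[i, j]`` is the number of synapses from excitatory neuron ``j`` onto
    excitatory neuron ``i`` (multapses allowed, no autapses).  ``WT`` is the
    dense weight matrix used by the integrator, stored transposed
    (``WT[pre, post]``) so that delivering one spike reads a contiguous row;
    its E-E block always equals ``J * A.T`` and is updated incrementally as
    synapses form and die.  All blocks involving inhibitory neurons are
    frozen at construction (Erdos-Renyi at ``p_static``, weight ``+J`` out
    of E, ``-g J`` out of I).
    """

    def __init__(self, n_E: int, n_I: int, J: float, g: float,
                 p_static: float, rng: np.random.Generator):
        self.n_E = n_E
        self.n_I = n_I
        self.J = J
        n = n_E + n_I
        self.A = np.zeros((n_E, n_E), dtype=np.int32)
        WT = np.zeros((n, n), dtype=np.float64)
        ei = rng.random((n_E, n_I)) < p_static          # WT[E, I]: E -> I
        ie = rng.random((n_I, n_E)) < p_static          # WT[I, E]: I -> E
        ii = rng.random((n_I, n_I)) < p_static          # I -> I
        np.fill_diagonal(ii, False)
        WT[:n_E, n_E:] = J * ei
        WT[n_E:, :n_E] = -g * J * ie
        WT[n_E:, n_E:] = -g * J * ii
        self.WT = WT

    def apply_rewiring(self, formed, deleted):
        """Mirror synapse formation/deletion events into the weight matrix.

        Events are (post, pre) pairs as stored in ``A``.
        """
        if len(formed):
            i, j = np.asarray(formed, np.int64).T.reshape(2, -1)
            np.add.at(self.WT, (j, i), self.J)
        if len(deleted):
            i, j = np.asarray(deleted, np.int64).T.reshape(2, -1)
            np.add.at(self.WT, (j, i), -self.J)

    def check_consistency(self, atol=1e-9):
        """Verify that the E-E weight block equals J * A (hard error otherwise)."""
        if not np.allclose(self.WT[: self.n_E, : self.n_E].T,
                           self.J * self.A, atol=atol):
            raise SimulationError("E-E weight block diverged from J * A")

    @property
    def ee_probability(self) -> float:
        """Mean E-E connectivity Gamma = (1/n_E^2) * sum(A)."""
        return float(self.A.sum()) / self.n_E**2


# ---------------------------------------------------------------------------
# stimulation schedule

@dataclass
class Segment:
    """One time-stamped drive segment of a :class:`StimSchedule`."""
    kind: str                  # "poisson" or "dc"
    mask: np.ndarray           # boolean, length n_total
    t_start_s: float
    t_stop_s: float
    rate_hz: float = 0.0       # poisson only
    weight_mV: float = 0.0     # poisson only
    delta_Vm_mV: float = 0.0   # dc only

    def active(self, t0: float, t1: float) -> bool:
        """Whether this segment overlaps the half-open interval [t0, t1)."""
        eps = 1e-9
        return self.t_start_s < t1 - eps and self.t_stop_s > t0 + eps


class StimSchedule:
    """Ordered collection of drive segments."""

    def __init__(self, segments=()):
        self.segments = list(segments)

    def add(self, seg: Segment):
        self.segments.append(seg)
        return self

    def active(self, t0: float, t1: float):
        return [s for s in self.segments if s.active(t0, t1)]

    def boundaries(self):
        out = set()
        for s in self.segments:
            out.update((s.t_start_s, s.t_stop_s))
        return sorted(out)


def make_poisson_drive(rate_hz: float, weight_mV: float, mask: np.ndarray,
                       t_start_s: float, duration_s: float) -> Segment:
    """Independent Poisson spike input at ``rate_hz`` to every masked neuron."""
    if rate_hz < 0:
        raise ValueError("Poisson rate must be non-negative")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return Segment("poisson", np.asarray(mask, bool), t_start_s,
                   t_start_s + duration_s, rate_hz=rate_hz, weight_mV=weight_mV)


def make_dc_drive(delta_Vm_mV: float, mask: np.ndarray,
                  t_start_s: float, t_stop_s: float) -> Segment:
    """Constant drive whose threshold-free stationary effect on V is delta_Vm.

    Positive values depolarize (anodal), negative hyperpolarize (cathodal).
    """
    if t_stop_s <= t_start_s:
        raise ValueError("require t_stop > t_start")
    mask = np.asarray(mask, bool)
    if not mask.any():
        log.warning("DC segment with empty target mask is a no-op")
    return Segment("dc", mask, t_start_s, t_stop_s, delta_Vm_mV=delta_Vm_mV)


# ---------------------------------------------------------------------------
# Poisson sampling tables

_GUIDE_SIZE = 1024


def _poisson_tables(lam: float, tail: float = 1e-14):
    """(cumulative pmf with sentinel, guide index) for inverse-CDF sampling."""
    if lam <= 0:
        cum = np.array([1.1])
    else:
        kmax = int(stats.poisson.isf(tail, lam)) + 3
        cum = np.cumsum(stats.poisson.pmf(np.arange(kmax), lam))
        cum[-1] = 1.1
    guide = np.searchsorted(cum, np.arange(_GUIDE_SIZE) / _GUIDE_SIZE,
                            side="left").astype(np.int32)
    return cum, guide


# ---------------------------------------------------------------------------
# the integration kernel

@njit(cache=True)
def _run_chunk(V, ref, WT, buf, head, u_bg, cum, guide, bg_w,
               ex_pulse, has_ex, dc_add, decay, theta, v_reset,
               ref_steps, delay_steps, counts, record, sp_id, sp_t, t0, dt_s):
    """Advance the whole network by ``u_bg.shape[0]`` grid steps.

    The ring buffer ``buf`` has ``delay_steps + 1`` rows; pulses emitted in
    a step land in the row that is consumed exactly one delay later.
    Returns (number of recorded spikes, new buffer head).
    """
    n_steps = u_bg.shape[0]
    n = V.shape[0]
    D = buf.shape[0]
    G = guide.shape[0]
    cap = sp_id.shape[0]
    nsp = 0
    for step in range(n_steps):
        slot = (head + delay_steps) % D
        t_now = t0 + (step + 1) * dt_s
        for i in range(n):
            u = u_bg[step, i]
            k = guide[int(u * G)]
            while u > cum[k]:
                k += 1
            pulse = bg_w * k + buf[head, i]
            buf[head, i] = 0.0
            if has_ex:
                pulse += ex_pulse[step, i]
            if ref[i] > 0:
                # refractory: clamp to reset, discard inputs
                ref[i] -= 1
                V[i] = v_reset
            else:
                V[i] = V[i] * decay + dc_add[i] + pulse
                if V[i] >= theta:
                    V[i] = v_reset
                    ref[i] = ref_steps
                    counts[i] += 1
                    if record and nsp < cap:
                        sp_id[nsp] = i
                        sp_t[nsp] = t_now
                        nsp += 1
                    for q in range(n):
                        buf[slot, q] += WT[i, q]
        head = (head + 1) % D
    return nsp, head


# ---------------------------------------------------------------------------
# simulator

class Simulator:
    """Chunked clock-driven simulation with optional structural plasticity.

    Time advances in chunks of ``dt_struct_ms``; drive segments are constant
    within a chunk (segment boundaries must lie on the chunk grid, which all
    protocol phases satisfy).  After each chunk the calcium trace absorbs the
    chunk's spikes and the structural engine — when attached — updates
    synaptic elements and rewires the E-E matrix.
    """

    def __init__(self, cfg: RunConfig, conn: ConnectivityMatrix | None = None,
                 seed_seq: np.random.SeedSequence | None = None):
        cfg.validate()
        self.cfg = cfg
        n = cfg.n_total
        if seed_seq is None:
            seed_seq = np.random.SeedSequence(cfg.seed)
        kernel_ss, wiring_ss, struct_ss = seed_seq.spawn(3)
        self.kernel_rng = np.random.Generator(np.random.PCG64(kernel_ss))
        self.struct_rng = np.random.default_rng(struct_ss)
        if conn is None:
            conn = ConnectivityMatrix(cfg.n_E, cfg.n_I, cfg.J_mV, cfg.g,
                                      cfg.p_static, np.random.default_rng(wiring_ss))
        self.conn = conn
        self.state = NetworkState(
            V=np.zeros(n), ref_remaining=np.zeros(n, np.int32),
            Ca=np.zeros(cfg.n_E), t=0.0)
        self.plasticity = None          # attached by protocols / grow_network
        self.threshold_enabled = True
        self._delay_steps = max(1, int(round(cfg.delay_ms / cfg.dt_ms)))
        self._buf = np.zeros((self._delay_steps + 1, n))
        self._head = 0
        self._decay = math.exp(-cfg.dt_ms / cfg.tau_m_ms)
        self._ca_decay = math.exp(-cfg.dt_struct_ms / (cfg.tau_ca_s * 1000.0))
        self._ref_steps = int(round(cfg.t_ref_ms / cfg.dt_ms))
        self._chunk_steps = int(round(cfg.dt_struct_ms / cfg.dt_ms))
        self._u_bg = np.empty((self._chunk_steps, n))
        self._no_ex = np.zeros((0, 0))
        # spike buffers sized for the refractory-limited maximum
        cap = n * (self._chunk_steps // max(1, self._ref_steps) + 2)
        self._sp_id = np.zeros(cap, np.int32)
        self._sp_t = np.zeros(cap, np.float64)
        self._table_cache: dict[float, tuple] = {}
        self._bg_lam = cfg.nu_ext_hz * cfg.dt_ms * 1e-3

    # -- helpers -----------------------------------------------------------
    def _tables(self, lam: float):
        if lam not in self._table_cache:
            self._table_cache[lam] = _poisson_tables(lam)
        return self._table_cache[lam]

    def _compile_drives(self, segments):
        """Split active segments into a DC vector and Poisson source specs."""
        cfg = self.cfg
        n = cfg.n_total
        dvm = np.zeros(n)
        pois = []
        for seg in segments:
            if seg.kind == "dc":
                dvm[seg.mask] += seg.delta_Vm_mV
            elif seg.kind == "poisson":
                lam = seg.rate_hz * cfg.dt_ms * 1e-3
                if lam > 0:
                    ids = np.flatnonzero(seg.mask)
                    cum, _ = self._tables(lam)
                    pois.append((cum, seg.weight_mV, ids))
            else:
                raise ValueError(f"unknown segment kind {seg.kind!r}")
        dc_add = (1.0 - self._decay) * dvm
        return dc_add, pois

    def _extra_pulses(self, pois):
        """Pre-sample masked Poisson sources into a dense (steps, n) array.

        Event counts depend only on the drawn uniforms, never on network
        state, so they can be materialized ahead of the kernel.
        """
        if not pois:
            return self._no_ex, False
        ex = np.zeros((self._chunk_steps, self.cfg.n_total))
        for cum, w, ids in pois:
            u = self.kernel_rng.random((self._chunk_steps, ids.size))
            ex[:, ids] += w * np.searchsorted(cum, u, side="left")
        return ex, True

    # -- main entry --------------------------------------------------------
    def advance(self, duration_s: float, schedule: StimSchedule | None = None,
                recorder=None, spikes_out: SpikeRecord | None = None):
        """Run for ``duration_s`` (a multiple of the structural interval).

        ``recorder`` (see :class:`hspsim.protocols.Recorder`) receives
        per-chunk spike counts and connectivity readouts; ``spikes_out``
        accumulates the full spike stream when given.
        """
        from .plasticity import CalciumParams, update_calcium

        cfg = self.cfg
        schedule = schedule or StimSchedule()
        dt_struct_s = cfg.dt_struct_ms * 1e-3
        n_chunks = int(round(duration_s / dt_struct_s))
        theta = cfg.V_theta_mV if self.threshold_enabled else np.inf
        record = spikes_out is not None
        bg_cum, bg_guide = self._tables(self._bg_lam)
        ca_par = CalciumParams(cfg.tau_ca_s, cfg.beta_ca)
        counts = np.zeros(cfg.n_total, np.int64)
        compiled = None
        active_key = None
        for _ in range(n_chunks):
            t0 = self.state.t
            t1 = t0 + dt_struct_s
            segs = schedule.active(t0, t1)
            key = tuple(id(s) for s in segs)
            if key != active_key:
                compiled = self._compile_drives(segs)
                active_key = key
            dc_add, pois = compiled
            self.kernel_rng.random(out=self._u_bg)
            ex, has_ex = self._extra_pulses(pois)
            counts[:] = 0
            nsp, self._head = _run_chunk(
                self.state.V, self.state.ref_remaining, self.conn.WT,
                self._buf, self._head, self._u_bg, bg_cum, bg_guide, cfg.J_mV,
                ex, has_ex, dc_add, self._decay, theta, cfg.V_reset_mV,
                self._ref_steps, self._delay_steps, counts, record,
                self._sp_id, self._sp_t, t0, cfg.dt_ms * 1e-3)
            self.state.t = t1
            if not np.isfinite(self.state.V).all():
                raise SimulationError(
                    f"non-finite membrane potential at t={t1:.3f} s "
                    "(parameter blow-up?)")
            self.state.Ca = update_calcium(self.state.Ca, counts[: cfg.n_E],
                                           dt_struct_s, ca_par)
            if record:
                spikes_out.extend(self._sp_id[:nsp].copy(), self._sp_t[:nsp].copy())
            if self.plasticity is not None:
                self.plasticity.step(self, dt_struct_s)
            if recorder is not None:
                recorder.chunk(self, counts)
        return self


# ---------------------------------------------------------------------------
# growth phase

def grow_network(cfg: RunConfig, seed_seq: np.random.SeedSequence | None = None,
                 recorder=None):
    """Grow the E-E network from scratch under background input.

    Starts from an empty E-E matrix with homeostatic structural plasticity
    active and runs for ``cfg.growth_s``.  Returns the simulator holding the
    equilibrated network; ``sim.growth_converged`` flags whether the final
    population rate lies within 10 % of the homeostatic setpoint.
    """
    from .plasticity import StructuralEngine

    sim = Simulator(cfg, seed_seq=seed_seq)
    sim.plasticity = StructuralEngine(cfg, sim.struct_rng)
    window_chunks = max(1, int(round(cfg.rate_window_s / (cfg.dt_struct_ms * 1e-3))))

    class _Tail:
        """Accumulates the last rate window to judge setpoint convergence."""
        def __init__(self):
            self.buf = []

        def chunk(self, sim_, counts):
            self.buf.append(counts[: cfg.n_E].sum())
            if len(self.buf) > window_chunks:
                self.buf.pop(0)
            if recorder is not None:
                recorder.chunk(sim_, counts)

    tail = _Tail()
    sim.advance(cfg.growth_s, recorder=tail)
    rate = (sum(tail.buf) / cfg.n_E) / (len(tail.buf) * cfg.dt_struct_ms * 1e-3) \
        if tail.buf else 0.0
    sim.growth_rate_hz = rate
    target = cfg.epsilon_hz / (cfg.beta_ca * cfg.tau_ca_s)
    sim.growth_converged = abs(rate - target) <= 0.1 * target
    if not sim.growth_converged:
        log.warning("growth ended at %.2f Hz, more than 10%% from the %.2f Hz "
                    "setpoint — growth parameters may be mis-calibrated",
                    rate, target)
    log.info("growth finished: rate %.2f Hz, E-E connectivity %.4f",
             rate, sim.conn.ee_probability)
    return sim
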