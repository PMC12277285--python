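"""Homeostatic structural plasticity on E-E connections.

Each excitatory neuron senses its own activity through a calcium trace
(exponential decay with time constant ``tau_ca``, increment ``beta`` per
spike; with ``beta = 1/tau_ca`` the stationary trace equals the firing rate
in Hz).  A linear growth rule drives continuous counts of axonal boutons
(``z_axon``) and dendritic spines (``z_dend``) toward the calcium setpoint
``epsilon``::

    dz/dt = nu_g * (1 - Ca / epsilon)        (z clipped at 0 from below)

The same rule governs both element types.  Every structural interval the
integer parts of the element counts are reconciled with the synapse-count
matrix A: neurons whose integer element count fell below their number of
bound synapses delete the deficit (victims drawn uniformly over the synapse
multiset; the partner's element returns to its free pool), and all free
axons and free spines are then paired uniformly at random to form new
synapses until one pool is exhausted.  Multapses are allowed, autapses are
not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "CalciumParams", "GrowthRule", "ElementLedger", "update_calcium",
    "grow_elements", "rewire", "StructuralEngine", "LedgerError",
]


class LedgerError(RuntimeError):
    """Element ledger and connectivity matrix disagree — internal corruption."""


def sample_without_replacement(m: int, d: int, rng: np.random.Generator):
    """Indices of ``d`` items drawn uniformly without replacement from ``m``."""
    if d > m:
        raise LedgerError("cannot draw more items than the pool holds")
    return rng.permutation(m)[:d]


@dataclass(frozen=True)
class CalciumParams:
    tau_ca_s: float = 10.0
    beta: float = 0.1

    def __post_init__(self):
        if self.tau_ca_s <= 0 or self.beta <= 0:
            raise ValueError("calcium parameters must be positive")


@dataclass(frozen=True)
class GrowthRule:
    """Linear homeostatic growth rule, identical for boutons and spines."""
    nu_g: float = 2.0          # maximal growth rate (elements / s)
    epsilon: float = 8.0       # calcium setpoint (Hz units when beta = 1/tau_ca)

    def __post_init__(self):
        if self.nu_g <= 0 or self.epsilon <= 0:
            raise ValueError("growth-rule parameters must be positive")


@dataclass
class ElementLedger:
    """Continuous per-neuron element counts; bound counts derive from A."""
    z_axon: np.ndarray
    z_dend: np.ndarray

    @classmethod
    def zeros(cls, n_E: int) -> "ElementLedger":
        return cls(np.zeros(n_E), np.zeros(n_E))

    @staticmethod
    def bound_counts(A: np.ndarray):
        """(bound_axon, bound_dend): column sums and row sums of A."""
        return A.sum(axis=0, dtype=np.int64), A.sum(axis=1, dtype=np.int64)

    def free_counts(self, A: np.ndarray):
        """Integer free elements (may be negative before rewiring)."""
        ba, bd = self.bound_counts(A)
        return (np.floor(self.z_axon).astype(np.int64) - ba,
                np.floor(self.z_dend).astype(np.int64) - bd)


def update_calcium(Ca: np.ndarray, n_spikes, dt_s: float,
                   params: CalciumParams) -> np.ndarray:
    """Batch calcium update over an interval of ``dt_s`` seconds.

    Decays the trace by ``exp(-dt/tau)`` and adds ``beta`` per spike
    (spike-time resolution within the interval is ignored; the integrator
    kernel applies the same rule step-by-step).
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    return Ca * np.exp(-dt_s / params.tau_ca_s) + params.beta * np.asarray(n_spikes)


def grow_elements(ledger: ElementLedger, Ca: np.ndarray, dt_struct_s: float,
                  rule: GrowthRule) -> ElementLedger:
    """Advance both element types by the linear rule; clip at zero."""
    if dt_struct_s <= 0:
        raise ValueError("dt_struct must be positive")
    dz = rule.nu_g * (1.0 - Ca / rule.epsilon) * dt_struct_s
    ledger.z_axon = np.maximum(ledger.z_axon + dz, 0.0)
    ledger.z_dend = np.maximum(ledger.z_dend + dz, 0.0)
    return ledger


# ---------------------------------------------------------------------------
# rewiring

@njit(cache=True)
def _victims_from_positions(mat, owners, pos_flat, offsets, out):
    """Map multiset positions to partner ids by scanning contiguous rows.

    ``mat[owner, partner]`` holds synapse counts; position ``p`` addresses
    the p-th synapse of the owner's ascending partner expansion.
    """
    for k in range(owners.size):
        row = mat[owners[k]]
        for q in range(offsets[k], offsets[k + 1]):
            p = pos_flat[q]
            acc = 0
            for i in range(row.size):
                acc += row[i]
                if acc > p:
                    out[q] = i
                    break


def _delete_deficits(A, AT, deficits, axis, rng, deleted, ba, bd):
    """Remove |deficit| randomly chosen synapses per neuron along one axis.

    ``axis=0``: neuron j deletes among its outgoing synapses (column j of A);
    ``axis=1``: neuron i deletes among its incoming synapses (row i).
    Neurons are visited in random order, each drawing victim *positions*
    uniformly without replacement over its bound-synapse multiset (one
    uniform per single-deficit neuron, drawn as a batch; a permutation draw
    per larger deficit).  Within a phase deletions of different neurons touch
    disjoint rows/columns, so they are applied in one batch at the end; the
    bound-count vectors ``ba``/``bd`` are kept in step.
    """
    ids = np.flatnonzero(deficits < 0)
    if ids.size == 0:
        return
    perm = rng.permutation(ids)
    d = (-deficits[perm]).astype(np.int64)
    m = (ba if axis == 0 else bd)[perm]
    if np.any(d > m):
        raise LedgerError("deletion deficit exceeds bound synapse count")
    u = rng.random(int((d == 1).sum()))
    pos_chunks = []
    offsets = np.zeros(perm.size + 1, np.int64)
    k1 = 0
    for k in range(perm.size):
        if d[k] == 1:
            pos_chunks.append(np.array([int(u[k1] * m[k])], np.int64))
            k1 += 1
        else:
            pos_chunks.append(np.sort(sample_without_replacement(
                int(m[k]), int(d[k]), rng)).astype(np.int64))
        offsets[k + 1] = offsets[k] + d[k]
    pos_flat = np.concatenate(pos_chunks)
    out = np.full(pos_flat.size, -1, np.int64)
    _victims_from_positions(AT if axis == 0 else A, perm.astype(np.int64),
                            pos_flat, offsets, out)
    if (out < 0).any():
        raise LedgerError("victim lookup ran past the synapse multiset")
    owners = np.repeat(perm, d)
    if axis == 0:                      # owners are presynaptic
        post, pre = out, owners
    else:
        post, pre = owners, out
    np.add.at(A, (post, pre), -1)
    np.add.at(AT, (pre, post), -1)
    np.add.at(ba, pre, -1)
    np.add.at(bd, post, -1)
    deleted.extend(zip(post.tolist(), pre.tolist()))


def rewire(A: np.ndarray, ledger: ElementLedger, rng: np.random.Generator,
           check: bool = False, bound=None, AT=None):
    """One structural update: delete deficits, then pair free elements.

    Deletion: axonal deficits are processed before dendritic ones, neurons in
    random order; victims are drawn uniformly over the neuron's bound-synapse
    multiset, and each removed synapse returns its counterpart element to the
    partner's free pool.

    Formation: all free axons and free spines are pooled, both pools are
    shuffled and paired positionally until the shorter pool is exhausted;
    a self-pairing is resolved by swapping with the first later spine that
    avoids it (skipped if no valid swap exists).

    ``bound`` may carry cached (bound_axon, bound_dend) vectors and ``AT`` a
    cached transposed count matrix; both are updated in place so a caller can
    avoid recomputing matrix sums and transposes every structural interval.

    Returns ``(formed, deleted)`` event lists of (post, pre) index pairs.
    """
    n_E = A.shape[0]
    deleted: list = []
    ba, bd = ledger.bound_counts(A) if bound is None else bound
    if AT is None:
        AT = np.ascontiguousarray(A.T)
    za = np.floor(ledger.z_axon).astype(np.int64)
    zd = np.floor(ledger.z_dend).astype(np.int64)
    _delete_deficits(A, AT, za - ba, 0, rng, deleted, ba, bd)
    # axon deletions may have freed spines; recheck dendritic deficits
    _delete_deficits(A, AT, zd - bd, 1, rng, deleted, ba, bd)
    free_axon = za - ba
    free_dend = zd - bd
    if check and ((free_axon < 0).any() or (free_dend < 0).any()):
        raise LedgerError("negative free counts after deletion phase")

    axon_pool = np.repeat(np.arange(n_E), np.maximum(free_axon, 0))
    dend_pool = np.repeat(np.arange(n_E), np.maximum(free_dend, 0))
    rng.shuffle(axon_pool)
    rng.shuffle(dend_pool)
    n_pairs = min(axon_pool.size, dend_pool.size)
    # resolve self-pairings: swap with the first later spine belonging to
    # another neuron (which must also not create an autapse at position l);
    # swaps never create new conflicts, so one pass over the conflict
    # positions suffices
    for k in np.flatnonzero(axon_pool[:n_pairs] == dend_pool[:n_pairs]):
        a = axon_pool[k]
        if dend_pool[k] != a:
            continue  # resolved by an earlier swap
        for l in range(k + 1, dend_pool.size):
            if dend_pool[l] != a and (l >= n_pairs or axon_pool[l] != dend_pool[k]):
                dend_pool[k], dend_pool[l] = dend_pool[l], dend_pool[k]
                break
        # unresolvable self-pairings stay in place and are filtered below
    sel = axon_pool[:n_pairs] != dend_pool[:n_pairs]
    ii = dend_pool[:n_pairs][sel].astype(np.int64)
    jj = axon_pool[:n_pairs][sel].astype(np.int64)
    formed = list(zip(ii.tolist(), jj.tolist()))
    if formed:
        np.add.at(A, (ii, jj), 1)
        np.add.at(AT, (jj, ii), 1)
        np.add.at(ba, jj, 1)
        np.add.at(bd, ii, 1)
    if check:
        fa, fd = ledger.free_counts(A)
        if (fa < 0).any() or (fd < 0).any():
            raise LedgerError("free counts negative after formation")
        if (A < 0).any() or A.trace() != 0:
            raise LedgerError("A left with negative entries or autapses")
    return formed, deleted


# ---------------------------------------------------------------------------
# per-chunk driver used by the simulator

class StructuralEngine:
    """Couples the growth rule and rewiring to a running simulation."""

    #: cadence (in structural steps) of the cached-bound-count verification
    VERIFY_EVERY = 200

    def __init__(self, cfg, rng: np.random.Generator, log_events: bool = False):
        self.rule = GrowthRule(nu_g=cfg.nu_g, epsilon=cfg.epsilon_hz)
        self.ledger = ElementLedger.zeros(cfg.n_E)
        self.rng = rng
        self.log_events = log_events
        self.events: list = []        # (t, "form"/"delete", pre, post)
        self._bound = (np.zeros(cfg.n_E, np.int64), np.zeros(cfg.n_E, np.int64))
        self._AT = None                  # transposed count matrix, kept in step
        self._n_steps = 0

    def step(self, sim, dt_struct_s: float):
        if self._AT is None:
            self._AT = np.ascontiguousarray(sim.conn.A.T)
        grow_elements(self.ledger, sim.state.Ca, dt_struct_s, self.rule)
        formed, removed = rewire(sim.conn.A, self.ledger, self.rng,
                                 bound=self._bound, AT=self._AT)
        sim.conn.apply_rewiring(formed, removed)
        self._n_steps += 1
        if self._n_steps % self.VERIFY_EVERY == 0:
            ba, bd = self.ledger.bound_counts(sim.conn.A)
            if (not np.array_equal(ba, self._bound[0])
                    or not np.array_equal(bd, self._bound[1])
                    or not np.array_equal(self._AT, sim.conn.A.T)):
                raise LedgerError("cached bound counts diverged from A")
        if self.log_events:
            t = sim.state.t
            self.events.extend((t, "form", j, i) for i, j in formed)
            self.events.extend((t, "delete", j, i) for i, j in removed)
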