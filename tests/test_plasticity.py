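"""Structural plasticity mechanics: calcium trace, growth rule, rewiring.

The rewiring engine is checked against an independent brute-force
bookkeeping oracle on tiny networks: the oracle stores every synapse as an
explicit (pre, post) instance in per-neuron lists and re-derives all bound
and free counts from that store, replaying the same documented random-choice
protocol (deficit neurons in permuted order, victims drawn uniformly from
the bound multiset, then both free-element pools shuffled and paired).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hspsim.plasticity import (CalciumParams, ElementLedger, GrowthRule,
                               LedgerError, grow_elements, rewire,
                               update_calcium)


def draw_without_replacement(m, d, rng):
    """Oracle-side uniform draw, replaying the shared permutation protocol."""
    return list(rng.permutation(m)[:d])

CA = CalciumParams(tau_ca_s=10.0, beta=0.1)


class TestCalcium:
    def test_pure_decay_closed_form(self):
        ca = update_calcium(np.array([5.0]), np.array([0]), 3.0, CA)
        assert ca[0] == pytest.approx(5.0 * np.exp(-0.3))

    def test_single_spike_increments_by_beta(self):
        ca0 = np.array([0.0])
        ca = update_calcium(ca0, np.array([1]), 1e-9, CA)
        assert ca[0] == pytest.approx(CA.beta, rel=1e-6)

    def test_stationary_poisson_mean_is_beta_tau_rate(self):
        """Long-run trace mean under Poisson spiking equals beta*tau*rate.

        Brute-force trace simulation at 1 ms resolution against the
        shot-noise closed form, rate 8 Hz -> mean 8 (calcium in Hz units).
        """
        rng = np.random.default_rng(0)
        rate, dt, t_total = 8.0, 1e-3, 2000.0
        n_steps = int(t_total / dt)
        ca, acc = 0.0, []
        decay = np.exp(-dt / CA.tau_ca_s)
        spikes = rng.poisson(rate * dt, size=n_steps)
        for k in spikes:
            ca = ca * decay + CA.beta * k
            acc.append(ca)
        trace_mean = np.mean(acc[n_steps // 4:])
        assert trace_mean == pytest.approx(CA.beta * CA.tau_ca_s * rate,
                                           rel=0.05)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            update_calcium(np.zeros(1), np.zeros(1), 0.0, CA)


class TestGrowthRule:
    RULE = GrowthRule(nu_g=2.0, epsilon=8.0)

    @pytest.mark.parametrize("ca,expected_dz", [
        (8.0, 0.0),          # at the setpoint: no growth
        (0.0, 2.0),          # silent: maximal growth nu_g * dt
        (16.0, -2.0),        # twice the setpoint: maximal shrinkage
        (4.0, 1.0),          # linear in between
    ])
    def test_linear_rule_values(self, ca, expected_dz):
        led = ElementLedger(np.array([5.0]), np.array([5.0]))
        grow_elements(led, np.array([ca]), 1.0, self.RULE)
        assert led.z_axon[0] == pytest.approx(5.0 + expected_dz)
        assert led.z_dend[0] == pytest.approx(5.0 + expected_dz)

    def test_clip_at_zero(self):
        led = ElementLedger(np.array([0.5]), np.array([0.5]))
        grow_elements(led, np.array([80.0]), 1.0, self.RULE)
        assert led.z_axon[0] == 0.0 and led.z_dend[0] == 0.0

    def test_monotone_under_clamped_calcium(self):
        """Below the setpoint z strictly grows; above it shrinks until clipped."""
        led = ElementLedger(np.array([3.0, 3.0]), np.array([3.0, 3.0]))
        ca = np.array([4.0, 12.0])
        prev_lo, prev_hi = 3.0, 3.0
        for _ in range(20):
            grow_elements(led, ca, 0.1, self.RULE)
            assert led.z_axon[0] > prev_lo
            assert led.z_axon[1] < prev_hi or led.z_axon[1] == 0.0
            prev_lo, prev_hi = led.z_axon[0], led.z_axon[1]


# ---------------------------------------------------------------------------
# brute-force oracle

class OracleNet:
    """Synapse-instance bookkeeping with the same random-choice protocol."""

    def __init__(self, n, z_axon, z_dend):
        self.n = n
        self.syn = []                      # list of (pre, post) instances
        self.z_axon = list(z_axon)
        self.z_dend = list(z_dend)

    # independent re-derivations ------------------------------------------
    def bound_axon(self, j):
        return sum(1 for pre, _ in self.syn if pre == j)

    def bound_dend(self, i):
        return sum(1 for _, post in self.syn if post == i)

    def matrix(self):
        A = np.zeros((self.n, self.n), np.int64)
        for pre, post in self.syn:
            A[post, pre] += 1
        return A

    # the rewiring protocol -----------------------------------------------
    def rewire(self, rng):
        for phase in ("axon", "dend"):
            if phase == "axon":
                deficits = {j: int(np.floor(self.z_axon[j])) - self.bound_axon(j)
                            for j in range(self.n)}
            else:
                deficits = {i: int(np.floor(self.z_dend[i])) - self.bound_dend(i)
                            for i in range(self.n)}
            ids = np.array([k for k in range(self.n) if deficits[k] < 0],
                           dtype=np.int64)
            if ids.size == 0:
                continue
            perm = rng.permutation(ids)
            # per-neuron victim positions over the phase-start multiset: one
            # batched uniform per single-deficit neuron, then one permutation
            # draw per larger deficit, all in processing order
            snapshot, m = {}, {}
            for j in perm:
                if phase == "axon":
                    snapshot[j] = sorted(post for pre, post in self.syn
                                         if pre == j)
                else:
                    snapshot[j] = sorted(pre for pre, post in self.syn
                                         if post == j)
                m[j] = len(snapshot[j])
            singles = [j for j in perm if -deficits[j] == 1]
            u = rng.random(len(singles))
            positions = {}
            k1 = 0
            for j in perm:
                d = -deficits[j]
                if d == 1:
                    positions[j] = [int(u[k1] * m[j])]
                    k1 += 1
                else:
                    positions[j] = sorted(
                        draw_without_replacement(m[j], d, rng))
            for j in perm:
                for p in [snapshot[j][q] for q in positions[j]]:
                    if phase == "axon":
                        self.syn.remove((j, p))
                    else:
                        self.syn.remove((p, j))
        free_a, free_d = [], []
        for k in range(self.n):
            free_a += [k] * max(0, int(np.floor(self.z_axon[k])) - self.bound_axon(k))
            free_d += [k] * max(0, int(np.floor(self.z_dend[k])) - self.bound_dend(k))
        axon_pool = np.array(free_a, dtype=np.int64)
        dend_pool = np.array(free_d, dtype=np.int64)
        rng.shuffle(axon_pool)
        rng.shuffle(dend_pool)
        n_pairs = min(axon_pool.size, dend_pool.size)
        for k in range(n_pairs):
            a = axon_pool[k]
            if dend_pool[k] == a:
                for l in range(k + 1, dend_pool.size):
                    if dend_pool[l] != a and (l >= n_pairs
                                              or axon_pool[l] != dend_pool[k]):
                        dend_pool[k], dend_pool[l] = dend_pool[l], dend_pool[k]
                        break
                else:
                    continue
            self.syn.append((int(a), int(dend_pool[k])))


class TestRewireOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_trajectory_matches_bruteforce(self, seed):
        """Grow + rewire on a 5-neuron net matches the oracle state-for-state."""
        n = 5
        master = np.random.default_rng(seed)
        z0a = master.uniform(0, 4, n)
        z0d = master.uniform(0, 4, n)
        led = ElementLedger(z0a.copy(), z0d.copy())
        oracle = OracleNet(n, z0a, z0d)
        A = np.zeros((n, n), np.int32)
        rng_impl = np.random.default_rng(1000 + seed)
        rng_oracle = np.random.default_rng(1000 + seed)
        for step in range(25):
            # scripted calcium trace drives growth up and down
            ca = master.uniform(0, 16, n)
            rule = GrowthRule(nu_g=3.0, epsilon=8.0)
            grow_elements(led, ca, 0.5, rule)
            oracle.z_axon = list(np.maximum(
                np.array(oracle.z_axon) + 3.0 * (1 - ca / 8.0) * 0.5, 0.0))
            oracle.z_dend = list(np.maximum(
                np.array(oracle.z_dend) + 3.0 * (1 - ca / 8.0) * 0.5, 0.0))
            rewire(A, led, rng_impl, check=True)
            oracle.rewire(rng_oracle)
            assert np.array_equal(A, oracle.matrix()), f"diverged at step {step}"
            assert np.all(np.diag(A) == 0)

    def test_formation_count_is_min_of_pools(self):
        """free axons {a:2}, free spines {b:1, c:1} -> exactly a->b and a->c."""
        n = 3
        A = np.zeros((n, n), np.int32)
        led = ElementLedger(np.array([2.0, 0.0, 0.0]), np.array([0.0, 1.0, 1.0]))
        formed, deleted = rewire(A, led, np.random.default_rng(0), check=True)
        assert not deleted
        assert len(formed) == 2
        assert A[:, 0].sum() == 2 and A[1, 0] == 1 and A[2, 0] == 1

    def test_no_autapse_when_only_self_pairing_possible(self):
        """A neuron holding the only free axon and spine forms nothing."""
        n = 3
        A = np.zeros((n, n), np.int32)
        led = ElementLedger(np.array([1.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))
        formed, _ = rewire(A, led, np.random.default_rng(0), check=True)
        assert formed == []
        assert A.sum() == 0

    def test_deletion_uniform_over_multiset_and_bookkeeping(self):
        """An axonal deficit of 1 among 3 synapses deletes each with p=1/3.

        Also checks the counterpart bookkeeping: the removed synapse frees
        one dendritic element of the postsynaptic partner.
        """
        hits = {1: 0, 2: 0, 3: 0}
        trials = 1500
        for s in range(trials):
            n = 4
            A = np.zeros((n, n), np.int32)
            A[1, 0] = A[2, 0] = A[3, 0] = 1
            led = ElementLedger(np.array([2.0, 0, 0, 0.0]),
                                np.array([0.0, 1, 1, 1.0]))
            formed, deleted = rewire(A, led, np.random.default_rng(s),
                                     check=True)
            assert len(deleted) == 1 and not formed
            (post, pre), = deleted
            assert pre == 0
            hits[post] += 1
            # partner's spine is free again: z_dend unchanged, bound reduced
            fa, fd = led.free_counts(A)
            assert fd[post] == 1 and fa[0] == 0
        for k in hits:
            assert hits[k] / trials == pytest.approx(1 / 3, abs=0.05)

    def test_inconsistent_ledger_raises(self):
        """A deficit larger than the bound synapse count is a hard error."""
        n = 3
        A = np.zeros((n, n), np.int32)
        A[1, 0] = 2
        # corrupted ledger: deficit of 3 but only 2 bound synapses exist
        bad = ElementLedger(np.array([-3.0, 0.0, 0.0]), np.array([0.0, 2.0, 0.0]))
        with pytest.raises(LedgerError):
            rewire(A, bad, np.random.default_rng(0), check=True)


class TestConservation:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bound_counts_equal_matrix_sums_after_every_rewire(self, seed):
        """After rewiring, floor(z) >= bound and the ledger matches A exactly."""
        rng = np.random.default_rng(seed)
        n = 6
        A = np.zeros((n, n), np.int32)
        led = ElementLedger(rng.uniform(0, 5, n), rng.uniform(0, 5, n))
        for _ in range(10):
            ca = rng.uniform(0, 16, n)
            grow_elements(led, ca, 0.3, GrowthRule(nu_g=4.0, epsilon=8.0))
            rewire(A, led, rng, check=True)
            ba, bd = led.bound_counts(A)
            assert np.array_equal(ba, A.sum(axis=0))
            assert np.array_equal(bd, A.sum(axis=1))
            assert np.all(np.floor(led.z_axon).astype(int) >= ba)
            assert np.all(np.floor(led.z_dend).astype(int) >= bd)
            assert np.all(A >= 0) and A.trace() == 0
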