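# Model and methods

## The network

`hspsim` simulates a cortical patch (motor cortex in the intended
application) as an inhibition-dominated random recurrent network of leaky
integrate-and-fire (LIF) neurons: `n_E` excitatory and `n_I = n_E / 4`
inhibitory cells.  Synapses are delta pulses: a presynaptic spike deflects
the postsynaptic membrane by `J = 0.1 mV` (excitatory) or `-g·J` with
`g = 8` (inhibitory) exactly one transmission delay (1 ms) later.  The
subthreshold dynamics of each neuron are

    tau_m dV/dt = -V + input pulses + DC,

with `tau_m = 10 ms`; a threshold crossing at `V_theta = 20 mV` emits a
spike, resets the membrane to `V_reset = 10 mV`, and opens a 2 ms absolute
refractory period during which inputs are shunted.  Every neuron receives
an independent Poisson background spike train of rate `nu_ext` at weight
`J` — input is delivered as spikes, not as an equivalent mean current.

Connections involving inhibitory neurons (E→I, I→E, I→I) are static
Erdős–Rényi graphs at probability 0.1.  Excitatory-to-excitatory (E-E)
connectivity is an integer synapse-count matrix `A` (`A[i, j]` = number of
synapses from `j` onto `i`; multiple synapses per pair allowed, self-synapses
forbidden) that is empty at the start and entirely produced by the
structural-plasticity rule below.

## Homeostatic structural plasticity

Each excitatory neuron tracks its own activity with a calcium trace:
exponential decay with `tau_Ca = 10 s` and an increment `beta = 1/tau_Ca`
per spike, so the stationary trace numerically equals the firing rate in
Hz.  Two continuous element counts per neuron — axonal boutons (`z_axon`)
and dendritic spines (`z_dend`) — follow the same linear homeostatic rule

    dz/dt = nu_g (1 - Ca / epsilon),      z >= 0 (clipped),

with setpoint `epsilon = 8` (Hz units) and maximal growth rate `nu_g`.
Every structural interval (`dt_struct = 100 ms`) the integer part of each
element count is reconciled with `A`:

* **Deletion.** A neuron whose integer element count fell below its number
  of bound synapses removes the deficit: victims are drawn uniformly
  without replacement over its bound-synapse multiset (so a double synapse
  is twice as likely to lose one instance).  Axonal deficits are processed
  before dendritic ones and neurons in random order; the partner of each
  removed synapse keeps its element, which returns to the free pool.
  Within one phase the deletions of different neurons touch disjoint
  rows/columns of `A` and therefore commute; the implementation exploits
  this by drawing all victim positions first (one batched uniform per
  single-deficit neuron, then one permutation draw per larger deficit, in
  processing order) and applying the removals in bulk.
* **Formation.** All free boutons and all free spines are pooled, both
  pools are shuffled, and entries are paired positionally until the shorter
  pool is exhausted.  A self-pairing is resolved by swapping with the first
  later spine that avoids it, or skipped when no valid swap exists.

The random-choice protocol above is deliberately simple and fully
documented because the test suite replays it in an independent brute-force
bookkeeping oracle and requires state-for-state agreement on small
networks.

The calcium trace is advanced once per structural interval from the spike
counts of that interval.  For `tau_Ca = 10 s` the within-interval decay
misordering is below 1 % of a single spike increment and has no measurable
effect at the 100 ms interval used.

Grown under background input alone, the network self-organizes: element
counts rise while activity is below the setpoint, synapses form, recurrent
excitation and (via the static E→I loop) recurrent inhibition build up,
and the excitatory population settles into asynchronous-irregular firing
at the 8 Hz setpoint.  `nu_ext` is the only free knob in this balance and
was calibrated per profile by a one-dimensional search so that the
equilibrium E-E connection probability lands where intended (next section);
it is stored in the configuration, never hard-coded.

## Stimulation model

* **Motor learning** is an extra Poisson input at 1.5 kHz / 0.1 mV to an
  engram subpopulation of 10 % of the excitatory neurons for `learn_s`
  seconds, producing a stationary mean depolarization of
  `nu·tau_m·J = 1.50 mV`.
* **tDCS** is modeled as somatic polarization: a constant term in the
  membrane equation calibrated so the threshold-free stationary deflection
  equals `delta_Vm` exactly (anodal > 0, cathodal < 0).  Weak stimulation
  spans ±0.6 mV; a strong variant (±2.8 mV, beyond the learning input's
  1.5 mV) requires an explicit `allow_strong` opt-in.
* **Montages**: `uniform` polarizes all excitatory neurons, `targeted`
  exactly the engram, `unfocused` half the engram plus an equal number of
  randomly chosen non-engram excitatory neurons.
* **Timing**: DC is applied immediately before, during, or immediately
  after learning (zero gap).  Every run ends at the same fixed horizon
  `growth + learn_s + dc_s + relax_s` regardless of timing, mirroring the
  fixed measurement time of the full-scale timeline (1200 s), so that
  conditions are compared at equal elapsed time under equal amounts of
  ongoing synaptic turnover.

The main readout is the engram connectivity `Γ = (1/n²) Σ_ij A_ij` over
the engram ids (diagonal included in the denominator, as in the printed
formula; `A_ii = 0` structurally).  Block connectivities between ordered
group pairs use the analogous `(1/|P||Q|) Σ` normalization.  Final values
are the mean of the last ten recorded connectivity readouts, to suppress
turnover fluctuations.  Sweep comparisons across seeds use one-sided
Mann–Whitney rank tests at α = 0.05.

## Parameter profiles and scale

The full-scale configuration (`full` profile) is 10000 E + 2500 I
neurons, 750 s growth and 150 s phases.  Desk-scale work uses smaller
networks with the same neuron and coupling parameters; only the population
sizes (one scale factor, 4:1 ratio and 10 % engram preserved) and the
structural timeline (larger `nu_g`, shorter phases, relaxation kept at a
comparable multiple of the structural time constant) shrink.  The
homeostatic setpoint, not the size, fixes the firing rates.

One quantity does **not** scale: the number of synapses a neuron must shed
to re-reach the setpoint under the fixed-amplitude learning input is
approximately `μ_learn / (J · tau_m · ν) ≈ 190` synapses regardless of
network size.  Whether that demand exceeds the equilibrium in-degree
decides the qualitative regime:

* `desk` — scale 0.2, `nu_ext = 19.5 kHz`, `nu_g = 5`, 300 s growth,
  0.1 ms step.  Calibrated to the headline equilibrium (8 Hz, ~9 % E-E
  connectivity; in-degree ≈ 180).  Used for the equilibrium measurements.
* `test` — scale 0.05, `nu_ext = 18 kHz` (equilibrium connectivity ≈ 0.10),
  `nu_g = 5`, 150 s growth, 60 s phases, 0.5 ms step.  Here the learning
  input transiently removes essentially **all** engram synapses; the
  engram still forms through the synchronized rebound.  This cheap profile
  carries the comparisons that rest on gross engram turnover (engram
  formation and uniform-montage weakening).  A larger growth rate was
  rejected for this profile because it makes the rebound overshoot grow
  with stimulation intensity, inverting the intensity ordering of uniform
  cathodal stimulation.
* `dense` — scale 0.2, `nu_ext = 16.8 kHz`, which moves the stable
  equilibrium to ~15 % connectivity (in-degree ≈ 300 > 190), `nu_g = 5`,
  250 s growth, 45 s phases, 0.5 ms step.  Only in this partial-deletion
  regime does weak DC modulate *how many* synapses are lost or rebuilt,
  which is what carries the polarity- and overlap-dependent effects
  (targeted anodal/cathodal asymmetries, unfocused overlap asymmetry).
  At small scale this regime cannot be reached by lowering `nu_ext`
  further: below a scale-dependent background level the inhibition-
  dominated growth loop has no stable dense equilibrium and runs away to
  full connectivity with a silent excitatory population.

The strength of the isolated-stimulation cell assembly (no learning) also
depends on this regime: in the dense profile, depolarizing DC must be
strong enough that the post-stimulation rebound dominates ongoing
background turnover.  The package uses ±1.2 mV — below the 1.5 mV learning
input, consistent with stimulation being the weaker drive — for that
demonstration; hyperpolarizing DC forms its assembly already at ±0.4 mV
because the assembly wires up *during* stimulation, when the stimulated
group is the only population below the setpoint.

## Numerics and determinism

* Exponential-Euler integration of the linear LIF equation on a fixed grid
  (`dt = 0.1 ms` default; 0.5 ms in the accelerated profiles, always
  ≤ the 1 ms delay).  Subthreshold integration is exact for delta-pulse
  input batched on the grid; delays and the refractory period are integer
  grid multiples.
* Poisson inputs are sampled by inverse CDF: uniforms are drawn in bulk
  per structural interval from a PCG64 generator and converted to event
  counts through a cumulative table with a guide index (rates are
  piecewise constant per drive segment).
* Spike delivery streams one contiguous row of the transposed weight
  matrix; the E-E block of that matrix always equals `J·A` and is updated
  incrementally by rewiring events (a consistency check can verify this at
  any time, and the engine revalidates its cached bound counts every 200
  structural steps).
* One master seed per run spawns independent child streams (kernel noise,
  static wiring, structural rewiring, montage construction) via numpy's
  `SeedSequence`.  Identical configuration and seed reproduce spike
  records and connectivity matrices bit for bit; cloning a grown network
  into several stimulation conditions preserves this.
* Non-finite membrane potentials abort the run with a diagnostic rather
  than propagating.

## What the generated data do and do not show

All inputs are synthetic by construction (Poisson background, Poisson
learning drive, constant DC), which is faithful to the modeling study this
package implements — there is no external data.  Passing tests show that
the *model* reproduces the claimed phenomena at reduced scale: homeostatic
equilibrium, engram formation, and the montage/polarity/timing interaction
pattern.  They do not show that biological tissue behaves this way, and
the accelerated profiles additionally compress the structural timeline:
assemblies decay faster relative to phase durations than at full scale, so
absolute connectivity values at reduced scale are not comparable to
full-scale ones — only orderings across conditions at a fixed horizon are.

## Known limitations

* The weight matrix is dense (`O(n²)` float64), which is comfortable to
  scale 0.2 (~50 MB) but makes the full-scale configuration memory-hungry
  (~1.2 GB) and slow on one core; large runs are expected to use the
  reduced-scale profiles.
* Only excitatory neurons are plastic and polarized by DC; inhibitory
  structural plasticity, conductance-based neurons, spatial electric-field
  geometry, STDP and synaptic scaling are out of scope.
* The linear growth rule is the only growth curve implemented (no
  Gaussian/biphasic variants).
* Free synaptic elements persist indefinitely (no element decay).
* In the `test` profile the learning input saturates engram turnover
  (complete transient disconnection), which removes the weak-DC polarity
  sensitivity there — the reason the polarity, overlap and
  strong-distortion comparisons run on the `dense` profile instead.
  Conversely, the dense profile's large shed fraction (~60 % of the
  in-degree, vs ~20 % at full scale) amplifies the anodal rebound so much
  that uniform anodal stimulation helps rather than hinders there; the
  uniform-montage comparisons therefore run on the `test` profile.  No
  affordable network size matches both full-scale ratios at once.
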