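"""Run configuration: parameter defaults, validation, file round-trip, profiles.

All model and protocol parameters live in one flat :class:`RunConfig`.  The
``full`` profile holds the full-scale values (10000 E + 2500 I neurons,
750 s growth, 150 s learning/DC phases).  Smaller profiles keep the neuron
and coupling parameters fixed and shrink only the population sizes (single
scale factor, 4:1 E:I ratio and 10 % engram preserved) and the structural
timeline (larger element growth rate, shorter phases) — the homeostatic
setpoint, not the network size, fixes the firing rates.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

log = logging.getLogger("hspsim")

#: polarization range used for weak stimulation (mV); larger values need
#: an explicit opt-in (``allow_strong``).
WEAK_DVM_LIMIT = 0.6

VALID_TIMINGS = ("before", "during", "after", "none")
VALID_MONTAGES = ("uniform", "targeted", "unfocused")


@dataclass
class RunConfig:
    """Flat configuration for one simulation run.

    Units are embedded in the field names (``_ms``, ``_s``, ``_mV``, ``_hz``).
    """

    # -- network size ------------------------------------------------------
    n_E: int = 10000              #: excitatory population size
    n_I: int = 2500               #: inhibitory population size (n_E / 4)
    engram_fraction: float = 0.10  #: fraction of E neurons receiving learning input
    scale: float = 1.0            #: multiplies n_E / n_I / engram at load time

    # -- LIF neuron --------------------------------------------------------
    tau_m_ms: float = 10.0        #: membrane time constant
    V_theta_mV: float = 20.0      #: spike threshold
    V_reset_mV: float = 10.0      #: reset potential
    t_ref_ms: float = 2.0         #: absolute refractory period
    delay_ms: float = 1.0         #: synaptic transmission delay
    dt_ms: float = 0.1            #: simulation step

    # -- couplings ---------------------------------------------------------
    J_mV: float = 0.1             #: EPSP amplitude of a single synapse
    g: float = 8.0                #: relative inhibitory strength (IPSP = -g*J)
    nu_ext_hz: float = 19500.0    #: background Poisson rate per neuron
    p_static: float = 0.1         #: connection probability of static E-I/I-E/I-I links

    # -- calcium trace / growth rule --------------------------------------
    tau_ca_s: float = 10.0        #: calcium decay time constant
    beta_ca: float = 0.1          #: per-spike calcium increment (1/tau_ca, so
                                  #: the stationary trace equals the rate in Hz)
    epsilon_hz: float = 8.0       #: homeostatic setpoint (calcium units = Hz)
    nu_g: float = 2.0             #: maximal element growth rate (elements/s)
    dt_struct_ms: float = 100.0   #: structural update interval

    # -- protocol ----------------------------------------------------------
    growth_s: float = 750.0       #: initial growth period
    learn_s: float = 150.0        #: motor-learning duration
    dc_s: float = 150.0           #: DC stimulation duration
    relax_s: float = 150.0        #: relaxation recorded after the last phase
    learn_rate_hz: float = 1500.0  #: learning Poisson rate onto the engram
    learn_J_mV: float = 0.1       #: weight of learning input spikes
    delta_Vm_mV: float = 0.0      #: DC polarization target (anodal > 0)
    timing: str = "none"          #: DC timing relative to learning
    montage: str = "targeted"     #: electrode montage scenario
    allow_strong: bool = False    #: accept |delta_Vm| above the weak range

    # -- measurement -------------------------------------------------------
    rate_window_s: float = 5.0    #: firing-rate recording window
    gamma_stride_s: float = 1.0   #: interval between connectivity readouts
    snapshot_times_s: list = field(default_factory=list)  #: extra full-matrix snapshots

    # -- bookkeeping -------------------------------------------------------
    seed: int = 1
    out_dir: str = "runs"
    log_level: str = "INFO"
    record_spikes: bool = False   #: keep full (id, t) spike streams in memory

    # ------------------------------------------------------------------
    @property
    def n_total(self) -> int:
        return self.n_E + self.n_I

    @property
    def n_engram(self) -> int:
        return int(round(self.engram_fraction * self.n_E))

    def validate(self) -> "RunConfig":
        """Check invariants; raise :class:`ConfigError` on violation."""
        c = self
        checks = [
            (c.tau_m_ms > 0, "tau_m_ms must be positive"),
            (c.V_theta_mV > c.V_reset_mV >= 0, "require V_theta > V_reset >= 0"),
            (c.t_ref_ms >= 0, "t_ref_ms must be non-negative"),
            (c.delay_ms >= c.dt_ms, "synaptic delay must be at least one step (dt_ms)"),
            (c.J_mV > 0, "J_mV must be positive"),
            (c.g > 0, "g must be positive"),
            (c.nu_ext_hz >= 0, "nu_ext_hz must be non-negative"),
            (0 <= c.p_static <= 1, "p_static must be a probability"),
            (c.tau_ca_s > 0 and c.beta_ca > 0, "calcium parameters must be positive"),
            (c.nu_g > 0 and c.epsilon_hz > 0, "growth-rule parameters must be positive"),
            (c.dt_struct_ms >= c.dt_ms, "dt_struct_ms must be at least dt_ms"),
            (c.n_E > 0 and c.n_I > 0, "population sizes must be positive"),
            (0 < c.engram_fraction < 1, "engram_fraction must be in (0, 1)"),
            (c.timing in VALID_TIMINGS, f"timing must be one of {VALID_TIMINGS}"),
            (c.montage in VALID_MONTAGES, f"montage must be one of {VALID_MONTAGES}"),
            (c.learn_rate_hz >= 0, "learn_rate_hz must be non-negative"),
            (c.rate_window_s > 0, "rate_window_s must be positive"),
            (c.growth_s >= 0 and c.learn_s >= 0 and c.dc_s >= 0 and c.relax_s >= 0,
             "phase durations must be non-negative"),
            (0 <= c.seed < 2**31, "seed must fit in a signed 32-bit integer"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        if abs(c.delta_Vm_mV) > WEAK_DVM_LIMIT + 1e-12 and not c.allow_strong:
            raise ConfigError(
                f"|delta_Vm_mV| = {abs(c.delta_Vm_mV):g} exceeds the weak-stimulation "
                f"range [-{WEAK_DVM_LIMIT}, {WEAK_DVM_LIMIT}] mV; set allow_strong "
                "to use strong stimulation"
            )
        return self

    # ------------------------------------------------------------------
    def apply_scale(self) -> "RunConfig":
        """Resolve the ``scale`` factor into integer population sizes."""
        if self.scale != 1.0:
            self.n_E = int(round(self.n_E * self.scale))
            self.n_I = int(round(self.n_I * self.scale))
            self.scale = 1.0
        # keep engram_fraction * n_E integral (at least one engram neuron)
        n_eng = max(1, int(round(self.engram_fraction * self.n_E)))
        self.engram_fraction = n_eng / self.n_E
        return self

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range configuration values."""


_FIELD_NAMES = {f.name for f in fields(RunConfig)}


def load_config(path_or_stream, overrides: dict | None = None,
                profile: str | None = None) -> RunConfig:
    """Load a YAML config file; unknown keys are rejected.

    An empty file yields the full default (full-scale) configuration.
    ``overrides`` (e.g. CLI flags) take precedence over file keys, which take
    precedence over profile defaults.
    """
    if isinstance(path_or_stream, (str, Path)):
        raw = Path(path_or_stream).read_text()
    else:
        raw = path_or_stream.read()
    data = yaml.safe_load(io.StringIO(raw)) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping of key: value pairs")
    base = default_config(profile) if profile else RunConfig()
    merged = base.to_dict()
    for src in (data, overrides or {}):
        for key, value in src.items():
            if key not in _FIELD_NAMES:
                raise ConfigError(f"unknown configuration key: {key!r}")
            merged[key] = value
    cfg = RunConfig(**merged)
    cfg.apply_scale()
    cfg.validate()
    log.debug("loaded config:\n%s", cfg.dump())
    return cfg


# ---------------------------------------------------------------------------
# profiles

def default_config(profile: str = "full") -> RunConfig:
    """Named parameter profiles.

    ``full``
        Full scale, full timeline.
    ``desk``
        Scale 0.2 (2000 E + 500 I) with an accelerated growth phase
        (nu_g = 5 elements/s, 300 s growth) at the default 0.1 ms step;
        background rate calibrated so the grown network settles at the 8 Hz
        setpoint with ~9 % E-E connectivity.  Used for desk-scale
        equilibrium measurements.
    ``test``
        Scale 0.05 (500 E + 125 I), accelerated structural timeline
        (nu_g = 5, 150 s growth, 60 s phases) at a 0.5 ms step; the cheap
        profile for protocol-grid comparisons that do not hinge on partial
        synapse deletion.
    ``dense``
        Scale 0.2 at a 0.5 ms step with the background rate lowered so the
        equilibrium in-degree (~300 synapses) comfortably exceeds the number
        of synapses the fixed-amplitude learning input forces a neuron to
        shed (~190); in this regime stimulation modulates *partial* synapse
        loss, which carries the polarity-dependent effects.
    """
    if profile == "full":
        return RunConfig()
    if profile == "desk":
        return RunConfig(scale=0.2, nu_g=5.0, growth_s=300.0).apply_scale()
    if profile == "test":
        return RunConfig(
            scale=0.05, nu_g=5.0, growth_s=150.0,
            learn_s=60.0, dc_s=60.0, relax_s=60.0,
            dt_ms=0.5, nu_ext_hz=18000.0,
        ).apply_scale()
    if profile == "dense":
        return RunConfig(
            scale=0.2, nu_g=5.0, growth_s=250.0,
            learn_s=45.0, dc_s=45.0, relax_s=60.0,
            dt_ms=0.5, nu_ext_hz=16800.0, gamma_stride_s=2.0,
        ).apply_scale()
    raise ConfigError(
        f"unknown profile: {profile!r} (expected full/desk/test/dense)")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
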