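"""Named experiment presets covering the study's main simulation sets.

Each preset returns the list of :class:`RunConfig` objects reproducing one
results figure at the requested profile/scale:

fig1  — control: motor learning alone, no DC.
fig2  — weak cell assembly from targeted DC alone, both polarities.
fig3  — uniform DC before/during/after learning, both polarities, intensity grid.
fig4  — targeted DC before/during/after learning, both polarities, intensity grid.
fig5  — unfocused depolarizing DC before or after learning.
fig6  — unfocused DC, full timing x polarity x intensity grid.
fig7  — strong unfocused DC (+-2.8 mV) before or after learning.
fig8  — the full montage x timing x intensity summary sweep.
"""

from __future__ import annotations

from .config import ConfigError, RunConfig, default_config

__all__ = ["preset", "PRESET_NAMES"]

_WEAK_GRID = (0.2, 0.4, 0.6)


def _runs(base: RunConfig, combos):
    out = []
    for montage, timing, dvm in combos:
        out.append(base.replace(
            montage=montage, timing=timing, delta_Vm_mV=float(dvm),
            allow_strong=abs(dvm) > 0.6))
    return out


def preset(name: str, profile: str = "full") -> list[RunConfig]:
    """Return the simulation configs reproducing one figure."""
    base = default_config(profile)
    grids = {}
    grids["fig1"] = [("targeted", "none", 0.0)]
    grids["fig2"] = [("targeted", "during", s * 1.2) for s in (1, -1)]
    grids["fig3"] = [("uniform", t, s * a) for t in ("before", "during", "after")
                     for s in (1, -1) for a in _WEAK_GRID]
    grids["fig4"] = [("targeted", t, s * a) for t in ("before", "during", "after")
                     for s in (1, -1) for a in _WEAK_GRID]
    grids["fig5"] = [("unfocused", t, 0.4) for t in ("after", "before")]
    grids["fig6"] = [("unfocused", t, s * a) for t in ("before", "during", "after")
                     for s in (1, -1) for a in _WEAK_GRID]
    grids["fig7"] = [("unfocused", t, s * 2.8) for t in ("before", "after")
                     for s in (1, -1)]
    grids["fig8"] = [(m, t, s * a) for m in ("uniform", "targeted", "unfocused")
                     for t in ("before", "during", "after")
                     for s in (1, -1) for a in _WEAK_GRID]
    if name not in grids:
        raise ConfigError(
            f"unknown preset {name!r}; valid names: {', '.join(sorted(grids))}")
    runs = _runs(base, grids[name])
    if name == "fig2":
        # DC alone: disable the learning input
        runs = [c.replace(learn_s=0.0) for c in runs]
    return runs


PRESET_NAMES = tuple(f"fig{i}" for i in range(1, 9))
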