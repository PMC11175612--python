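"""Genotype presets for the synthetic-recording generator.

A preset bundles the phenomenological parameters of one genotype's movement
ontogeny: when movement starts (~16 hAEL), when it becomes rhythmic
(~18 hAEL), when the larva hatches (~21 hAEL), the rate and size of the early
disorganised ("myogenic") events, the period/duration/amplitude of the
rhythmic ("neurogenic") activity bouts, developmental baseline events
(tracheal gas-filling step, hatching discontinuity) and sensor noise.

Built-in presets
----------------
``wild_type``  — both phases present; 180-s bout period, 60-s bouts.
``silenced``   — neural silencing (Kir): myogenic phase unchanged, rhythmic
                 bouts abolished (``bout_amplitude = 0``).
``mutant``     — reduced movement: all amplitudes halved, bouts at a higher
                 frequency (120-s period) and shorter (30 s).

Amplitudes are in the same arbitrary linear intensity units as the MGV traces;
the 0.01 noise threshold of the analysis pipeline is far below the default
event amplitudes, as it is for real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml

__all__ = ["GenotypePreset", "CohortSpec", "PRESETS", "get_preset", "load_cohort_config"]


@dataclass(frozen=True)
class GenotypePreset:
    name: str
    movement_onset: float = 16.0     # hAEL; myogenic phase begins
    rhythmic_onset: float = 18.0     # hAEL; neurogenic phase begins
    hatch_time: float = 21.0         # hAEL
    myogenic_event_rate: float = 2.0         # events / min
    myogenic_event_amplitude: tuple[float, float] = (0.5, 0.5)  # (mean, cv) intensity units
    myogenic_event_duration: float = 1.0     # s, one full oscillation cycle
    bout_period: float = 180.0       # s between bout starts
    bout_duration: float = 60.0      # s
    bout_amplitude: float = 1.0      # intensity units
    bout_jitter: float = 0.0         # s, sd of bout-start jitter (0 = strictly periodic)
    within_bout_freq: float = 60.0 / 61.0   # Hz, ~1-s individual movements; a
                                     # null of the 61-sample baseline boxcar at 4 fps

    noise_sd: float = 0.005          # intensity units, additive sensor noise
    drift_slope: float = 0.5         # intensity units / hour, developmental drift
    gasfill_time: float = 19.5       # hAEL, tracheal gas-filling
    gasfill_step: float = 2.0        # intensity units, smooth sigmoidal step
    gasfill_rise: float = 30.0       # s, sigmoid time constant (~2-min 10-90% rise)
    hatch_step: float = -1.0         # intensity units, discontinuity at hatching

    def __post_init__(self) -> None:
        if not (self.movement_onset < self.rhythmic_onset < self.hatch_time):
            raise ValueError("need movement_onset < rhythmic_onset < hatch_time")
        for attr in ("myogenic_event_rate", "myogenic_event_duration", "bout_period",
                     "bout_duration", "bout_amplitude", "bout_jitter",
                     "within_bout_freq", "noise_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.bout_amplitude > 0 and not self.bout_duration < self.bout_period:
            raise ValueError("bout_duration must be shorter than bout_period")

    def with_overrides(self, **kwargs) -> "GenotypePreset":
        if "myogenic_event_amplitude" in kwargs:
            kwargs["myogenic_event_amplitude"] = tuple(kwargs["myogenic_event_amplitude"])
        return replace(self, **kwargs)


WILD_TYPE = GenotypePreset(name="wild_type")
SILENCED = WILD_TYPE.with_overrides(name="silenced", bout_amplitude=0.0)
MUTANT = WILD_TYPE.with_overrides(
    name="mutant",
    myogenic_event_amplitude=(0.25, 0.5),
    bout_amplitude=0.5,
    bout_period=120.0,
    bout_duration=30.0,
)

PRESETS: dict[str, GenotypePreset] = {p.name: p for p in (WILD_TYPE, SILENCED, MUTANT)}


def get_preset(name: str, **overrides) -> GenotypePreset:
    """Look up a built-in preset by name, optionally overriding fields."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    if overrides:
        new_name = overrides.pop("name", base.name)
        return base.with_overrides(name=new_name, **overrides)
    return base


@dataclass(frozen=True)
class CohortSpec:
    """A multi-embryo recording plan: presets with group sizes plus the shared timebase."""

    presets: tuple[tuple[GenotypePreset, int], ...]
    frame_rate: float = 4.0        # Hz
    record_start: float = 14.0     # hAEL
    record_duration: float = 7.5   # hours
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.presets:
            raise ValueError("cohort needs at least one preset")
        for preset, n in self.presets:
            if n < 1:
                raise ValueError(f"preset {preset.name!r}: n_embryos must be >= 1")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.record_duration > 0:
            raise ValueError("record_duration must be positive")

    @property
    def n_embryos(self) -> int:
        return sum(n for _, n in self.presets)


def load_cohort_config(path: str | Path, seed: int | None = None) -> CohortSpec:
    """Build a :class:`CohortSpec` from a YAML config.

    Example::

        frame_rate: 4.0
        record_start: 14.0
        record_duration: 7.0
        seed: 1
        cohort:
          - preset: wild_type
            n: 12
          - preset: silenced
            n: 12
            overrides: {noise_sd: 0.01}
    """
    cfg = yaml.safe_load(Path(path).read_text())
    groups = []
    for entry in cfg["cohort"]:
        overrides = dict(entry.get("overrides", {}))
        groups.append((get_preset(entry["preset"], **overrides), int(entry["n"])))
    return CohortSpec(
        presets=tuple(groups),
        frame_rate=float(cfg.get("frame_rate", 4.0)),
        record_start=float(cfg.get("record_start", 14.0)),
        record_duration=float(cfg.get("record_duration", 7.5)),
        seed=int(seed if seed is not None else cfg.get("seed", 0)),
    )
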