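"""Demographic scenarios and life history.

A :class:`Scenario` is a burn-in for a large mainland source population
followed by a time-ordered list of demographic events (in calendar years
before present): exactly one ``found_from_mainland`` event that creates the
island population by drawing founders from the mainland, and any number of
``set_capacity`` events that change a population's carrying capacity.

:class:`LifeHistory` holds the reindeer-like age structure: females first
give birth when turning two, both sexes reproduce through age 13, only a
random half of age-eligible males sire offspring each year (harem system),
litter sizes range 1-8 with declining probabilities, and age-specific
mortality is 0.2 for calves, 0.05 through age 14, 0.74 at 15 and 1.0 at 16.

:class:`ScalingPolicy` implements standard population rescaling for
desk-scale runs: carrying capacities are multiplied by λ while mutation,
inter-gene recombination and selection coefficients are divided by λ.  By
default event times and the burn-in are also multiplied by λ so that drift
(t/2Ne), diversity (4·Ne·μ) and selection (Ne·s) are all preserved relative
to the full-scale model; life-history constants are never rescaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

from .dfe import DfeSpec
from .genome import GenomeArchitecture

__all__ = [
    "LifeHistory",
    "DemographicEvent",
    "Scenario",
    "ScalingPolicy",
    "load_scenario",
    "apply_scaling",
    "founder_scenario",
    "null_scenario",
    "scenario_library",
]


def _default_litter_probs() -> Tuple[float, ...]:
    """Single calf per female per year (reindeer bear one young).

    The declining 1-8 distribution of annual reproductive output then
    emerges for males through harem mating: a breeding male sires one calf
    per female that chooses him.  A per-female multi-calf distribution can
    still be configured via ``litter_probs``.
    """
    return (1.0,) + (0.0,) * 7


@dataclass(frozen=True)
class LifeHistory:
    first_repro_age: int = 1
    max_repro_age: int = 13
    male_breeding_fraction: float = 0.5
    litter_probs: Tuple[float, ...] = field(default_factory=_default_litter_probs)
    max_longevity: int = 16
    # mortality per age class: index 0 = calves, 1..14, 15, 16
    age_mortality: Tuple[float, ...] = (0.2,) + (0.05,) * 14 + (0.74, 1.0)
    generation_time: float = 6.0  # reporting conversions only

    def __post_init__(self) -> None:
        errors = []
        lp = np.asarray(self.litter_probs, dtype=float)
        if not np.isclose(lp.sum(), 1.0):
            errors.append("litter_probs must sum to 1")
        if np.any(np.diff(lp) > 1e-12):
            errors.append("litter_probs must be non-increasing in litter size")
        if np.any(lp < 0) or np.any(lp > 1):
            errors.append("litter_probs must lie in [0, 1]")
        am = np.asarray(self.age_mortality, dtype=float)
        if len(am) != self.max_longevity + 1:
            errors.append("age_mortality must cover ages 0..max_longevity")
        elif am[-1] != 1.0:
            errors.append("age_mortality at max_longevity must be 1.0")
        if np.any(am < 0) or np.any(am > 1):
            errors.append("age_mortality entries must lie in [0, 1]")
        if not 0.0 <= self.male_breeding_fraction <= 1.0:
            errors.append("male_breeding_fraction must lie in [0, 1]")
        if not (self.first_repro_age < self.max_repro_age < self.max_longevity):
            errors.append("need first_repro_age < max_repro_age < max_longevity")
        if errors:
            raise ValueError("invalid life history: " + "; ".join(errors))

    @property
    def mean_litter(self) -> float:
        return float(np.dot(np.arange(1, len(self.litter_probs) + 1), self.litter_probs))


FOUND = "found_from_mainland"
SET_CAPACITY = "set_capacity"


@dataclass(frozen=True)
class DemographicEvent:
    time: int  # years before present; larger = older
    population: str
    carrying_capacity: int
    kind: str  # found_from_mainland | set_capacity

    def __post_init__(self) -> None:
        if self.kind not in (FOUND, SET_CAPACITY):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.carrying_capacity < 2:
            raise ValueError("carrying_capacity must be >= 2")
        if self.time < 0:
            raise ValueError("event time (years BP) must be >= 0")


@dataclass(frozen=True)
class Scenario:
    label: str
    burnin_years: int
    mainland_capacity: int
    events: Tuple[DemographicEvent, ...]
    life_history: LifeHistory = field(default_factory=LifeHistory)

    def __post_init__(self) -> None:
        errors = []
        if self.burnin_years <= 0:
            errors.append("burnin_years must be > 0")
        if self.mainland_capacity < 2:
            errors.append("mainland_capacity must be >= 2")
        times = [e.time for e in self.events]
        if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
            errors.append("event times must be strictly decreasing (older first)")
        n_found = sum(e.kind == FOUND for e in self.events)
        if n_found != 1:
            errors.append(f"expected exactly one {FOUND} event, got {n_found}")
        if errors:
            raise ValueError(f"invalid scenario {self.label!r}: " + "; ".join(errors))

    @property
    def founding_event(self) -> DemographicEvent:
        return next(e for e in self.events if e.kind == FOUND)

    @property
    def start_year_bp(self) -> int:
        """Oldest event time; the simulation starts burnin_years before it."""
        return self.events[0].time

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "burnin_years": self.burnin_years,
            "mainland_capacity": self.mainland_capacity,
            "events": [
                {
                    "time": e.time,
                    "population": e.population,
                    "carrying_capacity": e.carrying_capacity,
                    "kind": e.kind,
                }
                for e in self.events
            ],
            "life_history": {
                "first_repro_age": self.life_history.first_repro_age,
                "max_repro_age": self.life_history.max_repro_age,
                "male_breeding_fraction": self.life_history.male_breeding_fraction,
                "litter_probs": [float(x) for x in self.life_history.litter_probs],
                "max_longevity": self.life_history.max_longevity,
                "age_mortality": list(self.life_history.age_mortality),
                "generation_time": self.life_history.generation_time,
            },
        }

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_SCENARIO_KEYS = {"label", "burnin_years", "mainland_capacity", "events", "life_history"}
_EVENT_KEYS = {"time", "population", "carrying_capacity", "kind"}
_LH_KEYS = {
    "first_repro_age",
    "max_repro_age",
    "male_breeding_fraction",
    "litter_probs",
    "max_longevity",
    "age_mortality",
    "generation_time",
}


def _scenario_from_dict(doc: dict, default_label: str) -> Scenario:
    if not isinstance(doc, dict):
        raise ValueError("scenario file must contain a mapping")
    unknown = set(doc) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    events = []
    for i, ev in enumerate(doc.get("events", [])):
        bad = set(ev) - _EVENT_KEYS
        if bad:
            raise ValueError(f"unknown keys in event {i}: {sorted(bad)}")
        events.append(
            DemographicEvent(
                time=int(ev["time"]),
                population=str(ev.get("population", "island")),
                carrying_capacity=int(ev["carrying_capacity"]),
                kind=str(ev.get("kind", SET_CAPACITY)),
            )
        )
    lh_doc = doc.get("life_history")
    if lh_doc is None:
        lh = LifeHistory()
    else:
        bad = set(lh_doc) - _LH_KEYS
        if bad:
            raise ValueError(f"unknown life_history keys: {sorted(bad)}")
        if "litter_probs" in lh_doc:
            lh_doc = dict(lh_doc, litter_probs=tuple(lh_doc["litter_probs"]))
        if "age_mortality" in lh_doc:
            lh_doc = dict(lh_doc, age_mortality=tuple(lh_doc["age_mortality"]))
        lh = LifeHistory(**lh_doc)
    return Scenario(
        label=str(doc.get("label", default_label)),
        burnin_years=int(doc["burnin_years"]),
        mainland_capacity=int(doc["mainland_capacity"]),
        events=tuple(events),
        life_history=lh,
    )


def load_scenario(path: str | Path) -> Scenario:
    """Parse and validate a scenario config file (YAML; JSON accepted)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return _scenario_from_dict(doc, default_label=path.stem)


@dataclass(frozen=True)
class ScalingPolicy:
    """Population-rescaling policy (λ = 1 is the identity).

    ``rescale_times`` multiplies event times and burn-in by λ as well, the
    standard forward-simulation rescaling that preserves t/(2Ne), 4·Ne·μ and
    Ne·s and hence the full model's transient dynamics.  With
    ``rescale_times=False`` only capacities and rates are rescaled and event
    times stay in calendar years (drift then runs 1/λ-fold fast relative to
    the demography; see docs/methods.md).
    """

    lam: float = 1.0
    rescale_times: bool = True
    burnin_override: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lambda must lie in (0, 1]")


#: smallest rescaled carrying capacity: two breeding pairs.  A two-sex,
#: age-structured population below this is demographically meaningless
#: (a single pair cannot absorb one death and goes extinct with certainty
#: under density regulation).
MIN_SCALED_CAPACITY = 4


def _scale_capacity(k: int, lam: float) -> int:
    return max(MIN_SCALED_CAPACITY, round(k * lam))


def apply_scaling(
    scenario: Scenario,
    arch: GenomeArchitecture,
    dfe: DfeSpec,
    policy: ScalingPolicy,
) -> tuple[Scenario, GenomeArchitecture, DfeSpec]:
    """Rescale a scenario, genome architecture and DFE by ``policy.lam``.

    Capacities are multiplied by λ (rounded, floor 2); mutation and
    inter-gene recombination rates and selection coefficients are divided by
    λ (s re-clamped at -1 at draw time).  Life history is never rescaled.
    """
    lam = policy.lam
    if lam == 1.0 and policy.burnin_override is None:
        return scenario, arch, dfe

    def scale_time(t: int) -> int:
        return max(1, round(t * lam)) if policy.rescale_times else t

    events = tuple(
        replace(
            e,
            carrying_capacity=_scale_capacity(e.carrying_capacity, lam),
            time=scale_time(e.time),
        )
        for e in scenario.events
    )
    times = [e.time for e in events]
    if len(set(times)) != len(times):
        raise ValueError("time rescaling collapsed two events onto the same year; "
                         "use a larger lambda or rescale_times=False")
    burnin = scenario.burnin_years
    if policy.burnin_override is not None:
        burnin = policy.burnin_override
    elif policy.rescale_times:
        burnin = max(1, round(burnin * lam))
    scaled_scenario = replace(
        scenario,
        label=f"{scenario.label}@{lam:g}",
        burnin_years=burnin,
        mainland_capacity=_scale_capacity(scenario.mainland_capacity, lam),
        events=events,
    )
    return scaled_scenario, arch.scaled(lam), dfe.scaled(lam)


# ---------------------------------------------------------------------------
# scenario library: founder sizes x recovery sizes from the study design
# ---------------------------------------------------------------------------

FOUNDER_SIZES = (25, 50, 100, 250, 500)
RECOVERY_SIZES = (1_000, 2_000, 5_000)


def founder_scenario(
    k_founder: int,
    k_recovery: int,
    *,
    k_source: int = 50_000,
    k_hist: int = 20_000,
    k_bottleneck: int = 1_800,
    k_modern: int = 20_000,
    burnin_years: int = 500_000,
    life_history: Optional[LifeHistory] = None,
) -> Scenario:
    """Island founding at 7,000 BP, recovery at 6,900 BP, historical increase
    at 1,200 BP, overharvest bottleneck at 200 BP, modern recovery at 100 BP."""
    return Scenario(
        label=f"founder{k_founder}_rec{k_recovery}",
        burnin_years=burnin_years,
        mainland_capacity=k_source,
        events=(
            DemographicEvent(7_000, "island", k_founder, FOUND),
            DemographicEvent(6_900, "island", k_recovery, SET_CAPACITY),
            DemographicEvent(1_200, "island", k_hist, SET_CAPACITY),
            DemographicEvent(200, "island", k_bottleneck, SET_CAPACITY),
            DemographicEvent(100, "island", k_modern, SET_CAPACITY),
        ),
        life_history=life_history or LifeHistory(),
    )


def null_scenario(
    *,
    k_founder: int = 20_000,
    k_source: int = 50_000,
    k_bottleneck: int = 1_800,
    k_modern: int = 20_000,
    burnin_years: int = 500_000,
    life_history: Optional[LifeHistory] = None,
) -> Scenario:
    """Large stable island population; only the recent bottleneck/recovery."""
    return Scenario(
        label="null20000",
        burnin_years=burnin_years,
        mainland_capacity=k_source,
        events=(
            DemographicEvent(7_000, "island", k_founder, FOUND),
            DemographicEvent(200, "island", k_bottleneck, SET_CAPACITY),
            DemographicEvent(100, "island", k_modern, SET_CAPACITY),
        ),
        life_history=life_history or LifeHistory(),
    )


def scenario_library() -> dict[str, Scenario]:
    """All founder-size x recovery-size variants plus the null scenario."""
    lib = {
        s.label: s
        for kf in FOUNDER_SIZES
        for kr in RECOVERY_SIZES
        for s in [founder_scenario(kf, kr)]
    }
    null = null_scenario()
    lib[null.label] = null
    return lib


def write_scenario_library(out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, sc in scenario_library().items():
        p = out / f"{label}.yaml"
        sc.dump(p)
        paths.append(p)
    return paths
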