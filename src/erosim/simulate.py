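"""Scenario runner: replicated forward simulations with decennial sampling.

Each replicate seeds its own engine (seed = base_seed + replicate), starts
the mainland population either from the analytic mutation-drift equilibrium
(default; followed by a short relaxation) or from an empty genome with the
scenario's full burn-in, then iterates calendar years down to year 0,
applying demographic events and recording summary statistics from a uniform
sample of up to 30 individuals per population on a fixed year grid
(every 10 years at full scale; every ``max(1, round(10*lambda))`` years in
time-rescaled runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .dfe import DfeSpec
from .engine import Engine, Population
from .genome import GenomeArchitecture
from .scenarios import (
    FOUND,
    LifeHistory,
    ScalingPolicy,
    Scenario,
    apply_scaling,
)
from .summaries import TIMESERIES_COLUMNS, summary_row

__all__ = ["ReplicateResult", "SimulationResult", "ForwardSimulator", "run_scenario"]

MAINLAND = "mainland"
SAMPLE_SIZE = 30


@dataclass
class ReplicateResult:
    replicate: int
    seed: int
    records: pd.DataFrame
    extinctions: Dict[str, int] = field(default_factory=dict)


@dataclass
class SimulationResult:
    """Tidy time series over replicates plus extinction bookkeeping."""

    timeseries: pd.DataFrame
    extinctions: Dict[int, Dict[str, int]]
    scenario: Scenario

    def pooled(self) -> pd.DataFrame:
        """Mean and 95% normal CI of each statistic per (year, population)."""
        value_cols = [c for c in TIMESERIES_COLUMNS if c not in ("replicate", "year_bp", "population")]
        g = self.timeseries.groupby(["year_bp", "population"])[value_cols]
        mean = g.mean()
        se = g.sem()
        out = mean.copy()
        for c in value_cols:
            out[f"{c}_lo"] = mean[c] - 1.96 * se[c]
            out[f"{c}_hi"] = mean[c] + 1.96 * se[c]
        return out.reset_index()


def _snapshot_population(pop: Population, year: int, n_rows: int) -> dict:
    return {
        "year": year,
        "n_rows": n_rows,
        "label": pop.label,
        "k": pop.k,
        "n": pop.n,
        "hap_start": pop.hap_start[: pop.n].copy(),
        "hap_len": pop.hap_len[: pop.n].copy(),
        "age": pop.age[: pop.n].copy(),
        "is_female": pop.is_female[: pop.n].copy(),
        "logw": pop.logw[: pop.n].copy(),
        "pool": pop.pool[: pop.pool_used].copy(),
        "fixed_logw": pop.fixed_logw,
        "fixed_cat": pop.fixed_cat.copy(),
        "max_hap_len": pop.max_hap_len,
    }


def _restore_population(snap: dict) -> Population:
    pop = Population(snap["label"], snap["k"], ind_capacity=max(64, snap["n"]),
                     pool_capacity=max(1024, snap["pool"].size))
    n = snap["n"]
    pop.n = n
    pop.hap_start[:n] = snap["hap_start"]
    pop.hap_len[:n] = snap["hap_len"]
    pop.age[:n] = snap["age"]
    pop.is_female[:n] = snap["is_female"]
    pop.logw[:n] = snap["logw"]
    pop.pool[: snap["pool"].size] = snap["pool"]
    pop.pool_used = snap["pool"].size
    pop.fixed_logw = snap["fixed_logw"]
    pop.fixed_cat = snap["fixed_cat"].copy()
    pop.max_hap_len = snap["max_hap_len"]
    return pop


class ForwardSimulator:
    """Configured simulator for one (possibly rescaled) scenario."""

    def __init__(
        self,
        scenario: Scenario,
        arch: Optional[GenomeArchitecture] = None,
        dfe: Optional[DfeSpec] = None,
        policy: Optional[ScalingPolicy] = None,
        init: str = "equilibrium",
        relax_years: int = 100,
        ne_ratio: Optional[float] = None,
        sample_size: int = SAMPLE_SIZE,
        record_interval: Optional[int] = None,
        stop_year: int = 0,
        stop_when_extinct: Optional[str] = None,
        founding_retries: int = 0,
    ):
        arch = arch or GenomeArchitecture()
        dfe = dfe or DfeSpec()
        policy = policy or ScalingPolicy()
        self.policy = policy
        self.scenario, self.arch, self.dfe = apply_scaling(scenario, arch, dfe, policy)
        if init not in ("equilibrium", "empty"):
            raise ValueError("init must be 'equilibrium' or 'empty'")
        self.init = init
        self.relax_years = relax_years
        self.ne_ratio = ne_ratio
        self.sample_size = sample_size
        self.stop_year = stop_year
        self.stop_when_extinct = stop_when_extinct
        self.founding_retries = founding_retries
        if record_interval is None:
            record_interval = max(1, round(10 * policy.lam)) if policy.rescale_times else 10
        self.record_interval = record_interval
        # keep the ROH threshold at 0.1 Mb in full-scale map units: the
        # rescaled genetic map is 1/lambda-fold denser per bp
        self.froh_min_len = 100_000.0 * policy.lam

    # -- single replicate ----------------------------------------------------

    def run_replicate(self, replicate: int, seed: int) -> ReplicateResult:
        sc = self.scenario
        lh = sc.life_history
        engine = Engine(self.arch, self.dfe, lh, seed)
        sample_rng = np.random.default_rng((seed, 0xE0))

        mainland = engine.new_population(MAINLAND, sc.mainland_capacity)
        if self.init == "equilibrium":
            engine.init_equilibrium(mainland, theta_ratio=self.ne_ratio)
            burnin = self.relax_years
        else:
            engine.init_empty(mainland)
            burnin = sc.burnin_years

        pops: List[Population] = [mainland]
        events = {e.time: e for e in sc.events}
        found_label = sc.founding_event.population
        start_year = sc.start_year_bp + burnin
        rows: List[dict] = []
        extinct: Dict[str, int] = {}
        snapshot = None
        retries_left = self.founding_retries

        year = start_year
        skip_step = False
        while year >= self.stop_year:
            if not skip_step:
                engine.year = year
                engine.step_year(pops)
            skip_step = False
            for pop in pops:
                if pop.extinct and pop.label not in extinct:
                    extinct[pop.label] = year
            pops = [p for p in pops if not p.extinct]
            # optional survivor conditioning: rewind to the founding year and
            # redraw founders when the island population dies out
            if found_label in extinct and retries_left > 0 and snapshot is not None:
                retries_left -= 1
                mainland = _restore_population(snapshot)
                pops = [mainland]
                del rows[snapshot["n_rows"] :]
                del extinct[found_label]
                year = snapshot["year"]
                engine.year = year
                skip_step = True
                continue
            ev = events.get(year)
            if ev is not None:
                if ev.kind == FOUND:
                    if mainland.extinct:
                        extinct.setdefault(ev.population, year)
                    else:
                        if self.founding_retries > 0:
                            snapshot = _snapshot_population(mainland, year, len(rows))
                        island = engine.found(mainland, ev.population, ev.carrying_capacity)
                        pops.append(island)
                else:
                    for p in pops:
                        if p.label == ev.population:
                            p.k = ev.carrying_capacity
            if year <= sc.start_year_bp and year % self.record_interval == 0:
                for p in pops:
                    smp = engine.sample(p, self.sample_size, sample_rng)
                    rows.append(
                        summary_row(smp, replicate, year, p.label, p.n,
                                    froh_min_len=self.froh_min_len)
                    )
            if not pops:
                break
            if self.stop_when_extinct is not None and self.stop_when_extinct in extinct:
                break
            year -= 1
        records = pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
        return ReplicateResult(replicate, seed, records, extinct)

    # -- replicated run ------------------------------------------------------

    def run(self, n_replicates: int, base_seed: int) -> SimulationResult:
        frames = []
        extinctions: Dict[int, Dict[str, int]] = {}
        for r in range(n_replicates):
            res = self.run_replicate(r, base_seed + r)
            frames.append(res.records)
            if res.extinctions:
                extinctions[r] = res.extinctions
        ts = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TIMESERIES_COLUMNS)
        return SimulationResult(ts, extinctions, self.scenario)


def run_scenario(
    scenario: Scenario,
    arch: Optional[GenomeArchitecture] = None,
    dfe: Optional[DfeSpec] = None,
    life_history: Optional[LifeHistory] = None,
    policy: Optional[ScalingPolicy] = None,
    n_replicates: int = 30,
    base_seed: int = 1,
    **kwargs,
) -> SimulationResult:
    """Run ``n_replicates`` forward simulations of a scenario.

    Replicate r uses seed ``base_seed + r``.  Keyword arguments are passed
    to :class:`ForwardSimulator` (init mode, relaxation length, sample size,
    recording interval, early stop year).
    """
    if life_history is not None:
        from dataclasses import replace

        scenario = replace(scenario, life_history=life_history)
    sim = ForwardSimulator(scenario, arch=arch, dfe=dfe, policy=policy, **kwargs)
    return sim.run(n_replicates, base_seed)
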