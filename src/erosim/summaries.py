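"""Per-sample summary statistics of simulated populations.

All statistics operate on a :class:`~erosim.engine.PopulationSample` (a
resolved sample of diploid genotypes): heterozygosity per kb, the genomic
inbreeding coefficient F_ROH over tracts longer than a threshold, realized
and masked genetic load, and per-DFE-category derived-allele counts.

ROH in simulated samples are defined against the sites segregating in the
sample: for one individual, tracts are the intervals of the physical map
delimited by that individual's heterozygous sites and by chromosome ends
(a monomorphic or homozygous stretch never breaks a tract), with tract
length the bp distance between consecutive delimiters.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

from .dfe import CATEGORIES
from .engine import PopulationSample

__all__ = [
    "sim_heterozygosity",
    "sim_froh",
    "realized_load",
    "masked_load",
    "category_counts",
    "TIMESERIES_COLUMNS",
    "summary_row",
]

TIMESERIES_COLUMNS = [
    "replicate",
    "year_bp",
    "population",
    "N",
    "het_per_kb",
    "f_roh_0.1Mb",
    "realized_load",
    "masked_load",
    "n_weak",
    "n_moderate",
    "n_strong",
    "n_very_strong",
]


def _require_nonempty(sample: PopulationSample) -> None:
    if sample.n == 0:
        raise ValueError("empty sample")


def sim_heterozygosity(sample: PopulationSample) -> float:
    """Mean heterozygous sites per 1,000 bp of simulated sequence."""
    _require_nonempty(sample)
    per_ind = [ids.size for ids in sample.het_ids]
    return float(np.mean(per_ind)) / sample.arch.total_bp * 1_000.0


def _froh_individual(het_pos: np.ndarray, arch, min_len: float) -> float:
    bounds = np.arange(arch.n_chromosomes + 1, dtype=np.int64) * arch.chromosome_bp
    edges = np.sort(np.concatenate([bounds, het_pos]))
    runs = np.diff(edges)
    return float(runs[runs >= min_len].sum()) / arch.total_bp


def sim_froh(sample: PopulationSample, min_len: float = 100_000.0) -> float:
    """Mean F_ROH over homozygous tracts of at least ``min_len`` bp."""
    _require_nonempty(sample)
    vals = [
        _froh_individual(sample.reg_pos[ids], sample.arch, min_len)
        for ids in sample.het_ids
    ]
    return float(np.mean(vals))


def realized_load(sample: PopulationSample) -> float:
    """1 - mean multiplicative fitness, segregating plus fixed deleterious
    mutations included."""
    _require_nonempty(sample)
    w = np.exp(np.minimum(sample.logw + sample.fixed_logw, 0.0))
    return float(1.0 - w.mean())


def masked_load(sample: PopulationSample) -> float:
    """Additional fitness loss if every heterozygous deleterious site were
    made homozygous: 1 - mean over individuals of
    prod_het (1+s)/(1+h*s)."""
    _require_nonempty(sample)
    ws = []
    for ids in sample.het_ids:
        s = sample.reg_s[ids]
        deleterious = s != 0.0
        s = s[deleterious]
        h = sample.reg_h[ids][deleterious]
        ws.append(np.prod((1.0 + s) / (1.0 + h * s)) if s.size else 1.0)
    return float(1.0 - np.mean(ws))


def category_counts(sample: PopulationSample) -> pd.Series:
    """Mean derived-allele count per individual per DFE bin (homozygous
    sites count 2, heterozygous 1; population-fixed alleles included)."""
    _require_nonempty(sample)
    totals = np.zeros(5)
    for hom, het in zip(sample.hom_ids, sample.het_ids):
        totals += 2 * np.bincount(sample.reg_cat[hom], minlength=5)
        totals += np.bincount(sample.reg_cat[het], minlength=5)
    totals /= sample.n
    totals += 2 * sample.fixed_cat
    return pd.Series(totals, index=list(CATEGORIES))


def category_wide_export(
    timeseries: pd.DataFrame,
    years_bp: Sequence[int] = (6_800, 6_000, 200, 0),
) -> pd.DataFrame:
    """Wide per-category allele-count table at selected time points
    (population x year columns), for founder-effect comparisons."""
    sub = timeseries[timeseries.year_bp.isin(years_bp)]
    long = sub.melt(
        id_vars=["replicate", "year_bp", "population"],
        value_vars=["n_weak", "n_moderate", "n_strong", "n_very_strong"],
        var_name="category",
        value_name="alleles_per_individual",
    )
    return long.pivot_table(
        index=["replicate", "category"],
        columns=["population", "year_bp"],
        values="alleles_per_individual",
    )


def summary_row(
    sample: PopulationSample,
    replicate: int,
    year_bp: int,
    population: str,
    n_census: int,
    froh_min_len: float = 100_000.0,
) -> dict:
    """One tidy time-series row.  ``froh_min_len`` is the ROH length
    threshold in bp of the simulated map; population-rescaled runs pass
    100 kb x lambda so the threshold stays 0.1 Mb in full-scale map units
    (physical tract lengths shrink with the compressed genetic map)."""
    cats = category_counts(sample)
    return {
        "replicate": replicate,
        "year_bp": year_bp,
        "population": population,
        "N": n_census,
        "het_per_kb": sim_heterozygosity(sample),
        "f_roh_0.1Mb": sim_froh(sample, froh_min_len),
        "realized_load": realized_load(sample),
        "masked_load": masked_load(sample),
        "n_weak": cats["weak"],
        "n_moderate": cats["moderate"],
        "n_strong": cats["strong"],
        "n_very_strong": cats["very_strong"],
    }
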