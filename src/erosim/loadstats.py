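"""Genetic-load accounting on annotated variant tables.

Sites are polarized so that ALT is the derived allele and each carries one
impact category (HIGH, MODERATE, SYNONYMOUS or INTERGENIC; intergenic sites
are retained solely to standardize R_xy).  Genotypes are derived-allele
dosages 0/1/2 with -1 for missing.

The statistics are per-individual homozygous/heterozygous variant counts,
deleterious:synonymous ratios, and the two-population R_xy statistic
standardized by randomly drawn intergenic sites, with a delete-one
block-jackknife standard error over contiguous genomic blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "VariantTable",
    "RxyResult",
    "count_load",
    "load_ratio",
    "rxy",
    "filter_variants",
]

CATEGORIES = ("HIGH", "MODERATE", "SYNONYMOUS", "INTERGENIC")
MISSING = -1


@dataclass
class VariantTable:
    """Sites x samples derived-allele dosage table with impact annotation.

    ``genotypes`` is ``(n_sites, n_samples)`` int8 with values {0, 1, 2, -1}.
    Optional per-genotype auxiliary matrices (``depth``, ``ad_ref``) and
    per-site fields (``qual``, ``is_indel``) support the hard filters.
    """

    chrom: np.ndarray
    pos: np.ndarray
    category: np.ndarray
    genotypes: np.ndarray
    samples: list
    populations: np.ndarray
    qual: Optional[np.ndarray] = None
    depth: Optional[np.ndarray] = None
    ad_ref: Optional[np.ndarray] = None
    is_indel: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n_sites, n_samples = self.genotypes.shape
        if not (len(self.chrom) == len(self.pos) == len(self.category) == n_sites):
            raise ValueError("per-site arrays must match genotype rows")
        if len(self.samples) != n_samples or len(self.populations) != n_samples:
            raise ValueError("per-sample arrays must match genotype columns")
        bad = set(np.unique(self.category)) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown impact categories: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise ValueError(f"unknown population {population!r}")
        return idx

    def category_mask(self, category: str) -> np.ndarray:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return self.category == category

    def derived_freq(self, population: str) -> np.ndarray:
        """Per-site derived-allele frequency from non-missing genotypes;
        NaN where every genotype is missing."""
        g = self.genotypes[:, self.sample_indices(population)].astype(float)
        g[g == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(g, axis=1) / 2.0

    def fixed_everywhere(self) -> np.ndarray:
        """Sites with genotype 2 in every non-missing individual overall."""
        g = self.genotypes
        non_missing = g != MISSING
        return np.logical_and(
            non_missing.any(axis=1), ((g == 2) | ~non_missing).all(axis=1)
        )

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        opt = lambda a: None if a is None else a[mask]  # noqa: E731
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            category=self.category[mask],
            genotypes=self.genotypes[mask],
            samples=list(self.samples),
            populations=self.populations,
            qual=opt(self.qual),
            depth=opt(self.depth),
            ad_ref=opt(self.ad_ref),
            is_indel=opt(self.is_indel),
        )

    def sort_by_position(self) -> "VariantTable":
        order = np.lexsort((self.pos, self.chrom))
        return self.subset_sites(order)


def count_load(
    table: VariantTable,
    population: str,
    category: str,
    drop_fixed: bool = False,
) -> pd.DataFrame:
    """Per-individual derived-variant counts for one impact category.

    Returns a DataFrame indexed by sample with columns ``n_hom`` (dosage-2
    sites), ``n_het`` (dosage-1), ``n_total_variants`` (hom + het) and
    ``n_alleles`` (2*hom + het).  With ``drop_fixed``, sites that are
    homozygous-derived in every non-missing individual across all
    populations are excluded first.
    """
    mask = table.category_mask(category)
    if drop_fixed:
        mask &= ~table.fixed_everywhere()
    idx = table.sample_indices(population)
    g = table.genotypes[mask][:, idx]
    n_hom = (g == 2).sum(axis=0)
    n_het = (g == 1).sum(axis=0)
    return pd.DataFrame(
        {
            "n_hom": n_hom,
            "n_het": n_het,
            "n_total_variants": n_hom + n_het,
            "n_alleles": 2 * n_hom + n_het,
        },
        index=pd.Index([table.samples[i] for i in idx], name="sample"),
    )


def load_ratio(
    table: VariantTable,
    population: str,
    category: str,
    drop_fixed: bool = False,
) -> pd.Series:
    """Per-individual ratio of deleterious to synonymous variant counts.

    ``category`` must be HIGH or MODERATE.  Individuals without any
    synonymous variant get NaN (with a warning).
    """
    if category not in ("HIGH", "MODERATE"):
        raise ValueError("load_ratio is defined for HIGH or MODERATE impact")
    num = count_load(table, population, category, drop_fixed)["n_total_variants"]
    den = count_load(table, population, "SYNONYMOUS", drop_fixed)["n_total_variants"]
    zero = den == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} individual(s) with zero synonymous variants; "
            "ratio reported as missing"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den.replace(0, np.nan)
    ratio.name = f"{category.lower()}_to_syn"
    return ratio


@dataclass(frozen=True)
class RxyResult:
    category: str
    pop_x: str
    pop_y: str
    point_estimate: float
    jackknife_se: float
    blocks: int


def _l_sum(fx: np.ndarray, fy: np.ndarray) -> float:
    """L_{x not y} = sum_i f_i^x (1 - f_i^y) over sites with data in both."""
    ok = ~(np.isnan(fx) | np.isnan(fy))
    return float(np.sum(fx[ok] * (1.0 - fy[ok])))


def _rxy_point(fx, fy, cat_idx, std_idx) -> float:
    num = _l_sum(fx[cat_idx], fy[cat_idx]) / _l_sum(fx[std_idx], fy[std_idx])
    den = _l_sum(fy[cat_idx], fx[cat_idx]) / _l_sum(fy[std_idx], fx[std_idx])
    return num / den


def rxy(
    table: VariantTable,
    pop_x: str,
    pop_y: str,
    category: str,
    n_blocks: int = 50,
    seed: int = 0,
) -> RxyResult:
    """Derived-allele frequency ratio statistic between two populations.

    R_xy compares the summed derived-allele burden of an impact category in
    population x against y, standardized by an equally sized random set of
    intergenic sites: values below 1 indicate a relative deficit of that
    category in x.  The variance is a delete-one jackknife over
    ``n_blocks`` contiguous genomic blocks applied jointly to the category
    and standardization sites.
    """
    if category not in ("HIGH", "MODERATE", "SYNONYMOUS"):
        raise ValueError("rxy is defined for HIGH, MODERATE or SYNONYMOUS sites")
    t = table.sort_by_position()
    fx = t.derived_freq(pop_x)
    fy = t.derived_freq(pop_y)
    cat_idx = np.flatnonzero(t.category_mask(category))
    inter_idx = np.flatnonzero(t.category_mask("INTERGENIC"))
    if cat_idx.size == 0:
        raise ValueError(f"no {category} sites in table")
    if inter_idx.size < cat_idx.size:
        raise ValueError(
            f"only {inter_idx.size} intergenic sites for {cat_idx.size} "
            f"{category} sites; refusing to compute R_xy without "
            "equal-size intergenic standardization"
        )
    rng = np.random.default_rng(seed)
    std_idx = np.sort(rng.choice(inter_idx, size=cat_idx.size, replace=False))

    point = _rxy_point(fx, fy, cat_idx, std_idx)

    # contiguous equal-site-count blocks over the union of both site sets
    used = np.sort(np.concatenate([cat_idx, std_idx]))
    block_of_used = np.minimum((np.arange(used.size) * n_blocks) // used.size, n_blocks - 1)
    block_lookup = dict(zip(used.tolist(), block_of_used.tolist()))
    cat_block = np.array([block_lookup[i] for i in cat_idx])
    std_block = np.array([block_lookup[i] for i in std_idx])

    estimates = []
    for b in range(n_blocks):
        ci = cat_idx[cat_block != b]
        si = std_idx[std_block != b]
        if ci.size == 0 or si.size == 0:
            warnings.warn(f"jackknife block {b} leaves an empty site set; dropped")
            continue
        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                est = _rxy_point(fx, fy, ci, si)
        except ZeroDivisionError:
            est = np.nan
        if not np.isfinite(est):
            warnings.warn(f"jackknife replicate {b} had a zero L term; dropped")
            continue
        estimates.append(est)
    estimates = np.asarray(estimates)
    b_eff = estimates.size
    if b_eff > 1:
        se = float(np.sqrt((b_eff - 1) / b_eff * np.sum((estimates - estimates.mean()) ** 2)))
    else:
        se = float("nan")
    return RxyResult(category, pop_x, pop_y, float(point), se, int(b_eff))


def filter_variants(
    table: VariantTable,
    mean_depth: Optional[Sequence[float]] = None,
    min_qual: float = 30.0,
    depth_lower_frac: float = 1.0 / 3.0,
    depth_upper_mult: float = 2.0,
    balance_range: tuple = (0.2, 0.8),
    indel_proximity_bp: int = 5,
    complete_cases: bool = False,
) -> VariantTable:
    """Apply the hard genotype/site filters used before load estimation.

    Genotypes with depth below ``depth_lower_frac`` x the sample's mean
    depth or above ``depth_upper_mult`` x it become missing, as do
    heterozygous genotypes whose reference-allele balance (ref reads /
    depth) falls outside ``balance_range``.  Sites with quality below
    ``min_qual``, indels, SNPs within ``indel_proximity_bp`` of an indel,
    and (with ``complete_cases``) sites with any missing genotype are
    dropped.  Sites left with no non-missing genotype are always dropped.
    """
    for name in ("qual", "depth", "ad_ref", "is_indel"):
        if getattr(table, name) is None:
            raise ValueError(f"filter_variants requires the {name!r} field")
    if mean_depth is None:
        d = table.depth.astype(float).copy()
        d[table.genotypes == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_depth = np.nanmean(d, axis=0)
    mean_depth = np.asarray(mean_depth, dtype=float)
    if mean_depth.shape != (table.n_samples,):
        raise ValueError("mean_depth must give one value per sample")

    g = table.genotypes.copy()
    depth = table.depth
    low = depth < depth_lower_frac * mean_depth[None, :]
    high = depth > depth_upper_mult * mean_depth[None, :]
    g[low | high] = MISSING

    with np.errstate(divide="ignore", invalid="ignore"):
        balance = np.where(depth > 0, table.ad_ref / np.maximum(depth, 1), np.nan)
    het = g == 1
    bad_balance = het & ((balance < balance_range[0]) | (balance > balance_range[1]))
    g[bad_balance] = MISSING

    keep = np.asarray(table.qual, dtype=float) >= min_qual
    indel = np.asarray(table.is_indel, dtype=bool)
    keep &= ~indel
    # SNPs within indel_proximity_bp of any indel on the same chromosome
    for c in np.unique(table.chrom[indel]):
        on_c = table.chrom == c
        indel_pos = table.pos[on_c & indel]
        snp = on_c & ~indel
        near = np.zeros(table.n_sites, dtype=bool)
        if indel_pos.size:
            p = table.pos[snp]
            dist = np.min(np.abs(p[:, None] - indel_pos[None, :]), axis=1)
            near[np.flatnonzero(snp)] = dist <= indel_proximity_bp
        keep &= ~near

    non_missing = (g != MISSING).sum(axis=1)
    keep &= non_missing > 0
    if complete_cases:
        keep &= (g != MISSING).all(axis=1)

    out = table.subset_sites(keep)
    out.genotypes = g[keep]
    return out
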