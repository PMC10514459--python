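"""Synthetic multi-population genotype fixtures.

Generates annotated variant tables with known truth so the empirical-side
toolkits (ROH detection, load counting, R_xy, hard filters) can be tested
without any sequencing data: category-labelled sites placed uniformly along
chromosomes, Hardy-Weinberg genotypes at per-category Beta-distributed
derived-allele frequencies, an optional multiplicative frequency deficit in
one population (to plant a directional R_xy signal), forced-homozygous
tracts (planted ROH), and a per-genotype depth/allelic-balance error model
for exercising the filters.

Frequencies are drawn once per site and shared across populations (so a
null fixture is exchangeable between populations); supplying per-population
Beta parameters makes the draw independent for that population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .loadstats import CATEGORIES, VariantTable
from .vcfio import write_vcf

__all__ = ["RohTract", "SynthSpec", "generate_table", "write_fixture"]


@dataclass(frozen=True)
class RohTract:
    sample: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    state: str = "ancestral"  # forced genotype inside: ancestral=0 / derived=2

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise ValueError("tract needs 1 <= start <= end")
        if self.state not in ("ancestral", "derived"):
            raise ValueError("tract state must be 'ancestral' or 'derived'")


def _default_site_counts() -> Dict[str, int]:
    return {"HIGH": 100, "MODERATE": 400, "SYNONYMOUS": 500, "INTERGENIC": 3000}


def _default_freq_params() -> Dict[str, Tuple[float, float]]:
    # U-shaped neutral-like spectra; deleterious categories skewed rare
    return {
        "HIGH": (0.3, 1.7),
        "MODERATE": (0.4, 1.6),
        "SYNONYMOUS": (0.5, 1.5),
        "INTERGENIC": (0.5, 1.5),
    }


@dataclass
class SynthSpec:
    n_pops: int = 2
    samples_per_pop: int = 10
    n_chromosomes: int = 2
    chromosome_bp: int = 5_000_000
    site_counts: Dict[str, int] = field(default_factory=_default_site_counts)
    freq_params: Dict[str, Tuple[float, float]] = field(default_factory=_default_freq_params)
    pop_freq_params: Dict[str, Dict[str, Tuple[float, float]]] = field(default_factory=dict)
    rxy_deficit: Dict[str, float] = field(default_factory=dict)
    deficit_pop: int = 0
    roh_plan: List[RohTract] = field(default_factory=list)
    missingness: float = 0.0
    depth_mean: float = 20.0
    depth_overdispersion: float = 10.0  # NB size parameter; larger = tighter
    balance_beta: Tuple[float, float] = (50.0, 50.0)
    site_qual: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_pops <= 5:
            raise ValueError("n_pops must be between 2 and 5")
        bad = set(self.site_counts) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories in site_counts: {sorted(bad)}")
        total = sum(self.site_counts.values())
        if total > self.n_chromosomes * self.chromosome_bp:
            raise ValueError("more sites requested than available base pairs")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")
        for t in self.roh_plan:
            if t.end > self.chromosome_bp:
                raise ValueError(f"tract {t} extends beyond chromosome length")

    @property
    def populations(self) -> List[str]:
        return [f"pop{i}" for i in range(self.n_pops)]

    @property
    def samples(self) -> List[str]:
        return [f"pop{i}_s{j}" for i in range(self.n_pops) for j in range(self.samples_per_pop)]


def generate_table(spec: SynthSpec) -> Tuple[VariantTable, dict]:
    """Generate a VariantTable plus a truth record (frequencies, tracts).

    Deterministic for a given spec (all randomness from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{c + 1}" for c in range(spec.n_chromosomes)]

    # --- site placement: uniform positions, unique within chromosome -----
    chroms: List[str] = []
    poss: List[int] = []
    cats: List[str] = []
    for cat in CATEGORIES:
        n_cat = spec.site_counts.get(cat, 0)
        for k in range(n_cat):
            chroms.append(chrom_names[int(rng.integers(spec.n_chromosomes))])
            poss.append(int(rng.integers(1, spec.chromosome_bp + 1)))
            cats.append(cat)
    chrom_arr = np.asarray(chroms, dtype=object)
    pos_arr = np.asarray(poss, dtype=np.int64)
    cat_arr = np.asarray(cats, dtype=object)
    # de-duplicate collisions by nudging (keeps counts exact)
    for c in chrom_names:
        on_c = np.flatnonzero(chrom_arr == c)
        seen = set()
        for i in on_c:
            p = int(pos_arr[i])
            while p in seen:
                p = p % spec.chromosome_bp + 1
            seen.add(p)
            pos_arr[i] = p
    order = np.lexsort((pos_arr, chrom_arr))
    chrom_arr, pos_arr, cat_arr = chrom_arr[order], pos_arr[order], cat_arr[order]
    n_sites = len(pos_arr)

    # --- per-population derived-allele frequencies -----------------------
    freqs = np.empty((n_sites, spec.n_pops))
    base = np.empty(n_sites)
    for cat in CATEGORIES:
        m = cat_arr == cat
        if not m.any():
            continue
        a, b = spec.freq_params[cat]
        base[m] = rng.beta(a, b, size=int(m.sum()))
    for p_i, pop in enumerate(spec.populations):
        freqs[:, p_i] = base
        for cat in CATEGORIES:
            override = spec.pop_freq_params.get(cat, {}).get(pop)
            if override is not None:
                m = cat_arr == cat
                freqs[m, p_i] = rng.beta(*override, size=int(m.sum()))
    for cat, factor in spec.rxy_deficit.items():
        m = cat_arr == cat
        freqs[m, spec.deficit_pop] = np.clip(freqs[m, spec.deficit_pop] * factor, 0.0, 1.0)

    # --- Hardy-Weinberg genotypes ----------------------------------------
    samples = spec.samples
    n_samples = len(samples)
    gt = np.empty((n_sites, n_samples), dtype=np.int8)
    for p_i in range(spec.n_pops):
        cols = slice(p_i * spec.samples_per_pop, (p_i + 1) * spec.samples_per_pop)
        gt[:, cols] = rng.binomial(2, freqs[:, p_i][:, None], size=(n_sites, spec.samples_per_pop))

    # --- planted homozygous tracts ---------------------------------------
    sample_index = {s: j for j, s in enumerate(samples)}
    for tract in spec.roh_plan:
        j = sample_index[tract.sample]
        m = (chrom_arr == tract.chromosome) & (pos_arr >= tract.start) & (pos_arr <= tract.end)
        gt[m, j] = 2 if tract.state == "derived" else 0

    # --- error model: depth, allelic balance, missingness ----------------
    size = spec.depth_overdispersion
    p_nb = size / (size + spec.depth_mean)
    depth = rng.negative_binomial(size, p_nb, size=(n_sites, n_samples)).astype(np.int32)
    balance = rng.beta(*spec.balance_beta, size=(n_sites, n_samples))
    ad_ref = np.where(
        gt == 1,
        rng.binomial(np.maximum(depth, 0), balance),
        np.where(gt == 2, 0, depth),
    ).astype(np.int32)
    if spec.missingness > 0.0:
        gt[rng.random((n_sites, n_samples)) < spec.missingness] = -1

    table = VariantTable(
        chrom=chrom_arr,
        pos=pos_arr,
        category=cat_arr,
        genotypes=gt,
        samples=samples,
        populations=np.asarray(
            [p for p in spec.populations for _ in range(spec.samples_per_pop)], dtype=object
        ),
        qual=np.full(n_sites, spec.site_qual),
        depth=depth,
        ad_ref=ad_ref,
        is_indel=np.zeros(n_sites, dtype=bool),
    )
    truth = {
        "seed": spec.seed,
        "populations": spec.populations,
        "chromosome_bp": spec.chromosome_bp,
        "sites": {
            "chrom": chrom_arr.tolist(),
            "pos": pos_arr.tolist(),
            "category": cat_arr.tolist(),
        },
        "frequencies": {pop: freqs[:, i].tolist() for i, pop in enumerate(spec.populations)},
        "tracts": [
            {
                "sample": t.sample,
                "chromosome": t.chromosome,
                "start": t.start,
                "end": t.end,
                "state": t.state,
            }
            for t in spec.roh_plan
        ],
    }
    return table, truth


def write_fixture(table: VariantTable, truth: dict, out_dir: str | Path) -> Dict[str, Path]:
    """Write VCF + annotation TSV + popmap TSV + truth JSON into out_dir."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "synthetic.vcf",
            "annotation": out / "annotation.tsv",
            "popmap": out / "popmap.tsv",
            "truth": out / "truth.json",
        }
        contigs = {c: int(truth["chromosome_bp"]) for c in dict.fromkeys(table.chrom)}
        write_vcf(table, paths["vcf"], contig_lengths=contigs)
        with open(paths["annotation"], "w") as fh:
            fh.write("chrom\tpos\tcategory\n")
            for c, p, cat in zip(table.chrom, table.pos, table.category):
                fh.write(f"{c}\t{p}\t{cat}\n")
        with open(paths["popmap"], "w") as fh:
            fh.write("sample\tpopulation\n")
            for s, p in zip(table.samples, table.populations):
                fh.write(f"{s}\t{p}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh)
        return paths
    except OSError as exc:
        raise OSError(f"failed writing fixture into {out}: {exc}") from exc
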